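"""Synthetic walking sessions: gait timelines, wearable-sensor traces, and
field potentials with gait-locked spectral structure.

The generator emulates the structure of an overground-walking recording:
gait cycles of roughly 1–1.3 s with timing jitter and optional turn
segments; FSR loading/unloading curves whose 5% crossings fall at the true
events; 1/f-background field potentials carrying band-limited oscillations
whose envelopes are gated by gait phase (lateralized windows offset by half
a cycle between hemispheres); optional shared band-limited components
between channel pairs to create coherence; and a constant clock offset
between the neural and kinematic streams marked by tap-like acceleration
peaks on both systems.

Everything is deterministic under a single master seed; per-channel child
seeds are spawned from it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .gait_events import GaitCycle, GaitEvent, build_cycles
from .io_sync import RecordingBundle, SignalTrace

DEFAULT_LFP_FS = 500.0  # Hz, neural sampling rate
DEFAULT_ACCEL_FS_NEURAL = 64.0  # Hz, implanted-device accelerometer
DEFAULT_KIN_FS = 148.148  # Hz, FSR-adapter rate
PAD_S = 2.0  # quiet standing before the first and after the last heel-strike

# FSR curve shape constants (seconds / stance fractions); chosen so the 5%
# crossings land exactly on the planted events (see simulate_fsr docstring).
_RISE_S = 0.04
_FALL_S = 0.08
_HEEL_UNLOAD = (0.55, 0.80)  # heel unloads over this fraction of stance
_TOE_LOAD = (0.15, 0.35)  # forefoot loads over this fraction of stance


@dataclass
class GaitTimelineSpec:
    """Parameters of a synthetic gait timeline.

    Defaults describe unimpaired overground walking: 1.1 s cycles with 50 ms
    timing jitter, 60% stance, 10% double support.
    """

    n_cycles: int = 100
    mean_cycle_s: float = 1.1
    cycle_jitter_sd: float = 0.05
    stance_fraction: float = 0.6
    double_support_fraction: float = 0.1
    turn_intervals: tuple[tuple[float, float], ...] = ()
    seed: int = 0

    def validate(self) -> None:
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.mean_cycle_s <= 0:
            raise ValueError("mean_cycle_s must be positive")
        if not 0.5 < self.stance_fraction < 1:
            raise ValueError("stance_fraction must lie in (0.5, 1)")
        if not 0 < self.double_support_fraction < 0.5:
            raise ValueError("double_support_fraction must lie in (0, 0.5)")
        if self.cycle_jitter_sd < 0:
            raise ValueError("cycle_jitter_sd must be >= 0")


@dataclass
class ModulationSpec:
    """One gait-phase-gated band-limited component on one channel.

    ``gain`` multiplies the component's envelope inside ``phase_window``
    (percent of the LHS-anchored cycle): envelope = 1 + gain there, 1
    elsewhere, with raised-cosine ramps of 5% cycle width at the edges.
    ``gain=0`` leaves the channel statistically stationary.
    """

    channel: str
    band_lo: float
    band_hi: float
    phase_window: tuple[float, float] = (0.0, 100.0)
    gain: float = 0.0
    background_exponent: float = 1.5
    background_scale: float = 10.0  # µV RMS of the 1/f background
    #: component RMS relative to the in-band background RMS; 2.5 puts the
    #: baseline spectral peak ~7x above the 1/f floor, comparable to a
    #: prominent subthalamic theta/alpha/beta peak
    snr: float = 2.5

    def validate(self, fs: float) -> None:
        lo, hi = self.phase_window
        if not 0 <= lo < hi <= 100:
            raise ValueError(f"phase_window must satisfy 0 <= lo < hi <= 100, got {self.phase_window}")
        if not 0 < self.band_lo < self.band_hi:
            raise ValueError("need 0 < band_lo < band_hi")
        if self.band_hi >= fs / 2:
            raise ValueError(f"band_hi={self.band_hi} is at or above Nyquist ({fs/2})")
        if self.gain < 0:
            raise ValueError("gain must be >= 0")


@dataclass
class SyncSpec:
    """Synchronization taps and the planted clock offset.

    ``offset_s`` is the neural clock minus the kinematic clock: a physical
    tap at time *t* on the kinematic clock appears at ``t + offset_s`` on the
    neural stream.
    """

    offset_s: float = 0.0
    n_taps: int = 3
    tap_amplitude: float = 2.0  # g
    tap_width_s: float = 0.03
    first_tap_s: float = 1.0
    tap_spacing_s: float = 1.5
    noise_g: float = 0.02


@dataclass
class GaitTimeline:
    """Ground-truth events and cycles of one synthetic walk."""

    events: list[GaitEvent]
    cycles: list[GaitCycle]
    t_start: float
    t_end: float
    spec: GaitTimelineSpec | None = None

    @property
    def included_cycles(self) -> list[GaitCycle]:
        return [c for c in self.cycles if not c.excluded]

    def event_times(self, kind: str) -> np.ndarray:
        return np.array([e.time_s for e in self.events if e.kind == kind])


def mirror_modulation(mod: ModulationSpec, channel: str | None = None) -> list[ModulationSpec]:
    """Mirror a modulation spec to the opposite hemisphere (+50% cycle).

    Returns one spec, or two when the shifted window wraps past 100%.
    """
    lo = (mod.phase_window[0] + 50.0) % 100.0
    hi = (mod.phase_window[1] + 50.0) % 100.0
    ch = channel if channel is not None else mod.channel
    if lo < hi:
        return [replace(mod, channel=ch, phase_window=(lo, hi))]
    out = []
    if lo < 100.0:
        out.append(replace(mod, channel=ch, phase_window=(lo, 100.0)))
    if hi > 0.0:
        out.append(replace(mod, channel=ch, phase_window=(0.0, hi)))
    return out


def simulate_timeline(spec: GaitTimelineSpec) -> GaitTimeline:
    """Generate ground-truth gait events and validated cycles.

    Within each cycle of duration *d*: RTO at ``double_support_fraction*d``
    after LHS, RHS at ``0.5*d``, LTO at ``(0.5+double_support_fraction)*d``.
    Cycle durations are jittered i.i.d. normal (truncated at 30% of the
    mean).  Cycles overlapping ``turn_intervals`` are flagged excluded.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    dsf = spec.double_support_fraction
    t = PAD_S
    events: list[GaitEvent] = []
    for _ in range(spec.n_cycles):
        d = spec.mean_cycle_s + rng.normal(0.0, spec.cycle_jitter_sd)
        d = max(d, 0.3 * spec.mean_cycle_s)
        events.append(GaitEvent(t, "LHS"))
        events.append(GaitEvent(t + dsf * d, "RTO"))
        events.append(GaitEvent(t + 0.5 * d, "RHS"))
        events.append(GaitEvent(t + (0.5 + dsf) * d, "LTO"))
        t += d
    events.append(GaitEvent(t, "LHS"))
    cycles = build_cycles(sorted(events), spec.turn_intervals,
                          duration_bounds=(0.0, np.inf))
    return GaitTimeline(sorted(events), cycles, 0.0, t + PAD_S, spec=spec)


# ---------------------------------------------------------------------------
# Kinematic sensors
# ---------------------------------------------------------------------------

def _stance_intervals(timeline: GaitTimeline, foot: str) -> list[tuple[float, float]]:
    """Foot-contact intervals, including the partial stances at the recording
    boundaries (standing before the first toe-off / after the last
    heel-strike), so every planted event produces a threshold crossing."""
    hs_kind, to_kind = ("LHS", "LTO") if foot == "left" else ("RHS", "RTO")
    hs = timeline.event_times(hs_kind)
    to = timeline.event_times(to_kind)
    out = []
    if to.size and (hs.size == 0 or to[0] < hs[0]):
        # loaded from before t=0: no positive crossing at the recording start
        out.append((-1.0, to[0]))
    for h in hs:
        later = to[to > h]
        if later.size:
            out.append((h, later[0]))
        else:
            # final stance: loads at the last heel-strike, never unloads
            out.append((h, timeline.t_end + 1.0))
    return out


def _ramp(t: np.ndarray, t_start: float, width: float) -> np.ndarray:
    """Linear 0→1 ramp starting at t_start, clipped."""
    return np.clip((t - t_start) / width, 0.0, 1.0)


def _fsr_curves(t: np.ndarray, stances: list[tuple[float, float]]):
    """Heel (calcaneus/5MT) and toe (hallux/1MT) load curves for one foot.

    The heel curve crosses 5% of full load exactly at heel-strike (the linear
    loading ramp starts ``0.05*_RISE_S`` before contact); the toe curve
    crosses 5% downward exactly at toe-off (the unloading ramp ends
    ``0.05*_FALL_S`` after it).
    """
    heel = np.zeros_like(t)
    toe = np.zeros_like(t)
    for hs, to in stances:
        L = to - hs
        up = _ramp(t, hs - 0.05 * _RISE_S, _RISE_S)
        down = 1.0 - _ramp(t, hs + _HEEL_UNLOAD[0] * L,
                           (_HEEL_UNLOAD[1] - _HEEL_UNLOAD[0]) * L)
        heel = np.maximum(heel, up * down)
        t_load = hs + _TOE_LOAD[0] * L
        load = _ramp(t, t_load, (_TOE_LOAD[1] - _TOE_LOAD[0]) * L)
        unload = 1.0 - _ramp(t, to - 0.95 * _FALL_S, _FALL_S)
        toe = np.maximum(toe, load * unload)
    return heel, toe


def simulate_fsr(
    timeline: GaitTimeline,
    fs: float = DEFAULT_KIN_FS,
    noise_sd: float = 0.01,
    seed: int | None = None,
) -> RecordingBundle:
    """Synthesize the 8 FSR channels and 2 ankle-velocity channels.

    Per foot: calcaneus and 5MT rise through 5% of full load within one
    sample of that foot's heel-strike (the 5MT 20 ms later, so the earlier
    calcaneus crossing defines the merged event); hallux and 1MT fall through
    5% within one sample of toe-off (the 1MT 30 ms earlier, so the later
    hallux crossing defines it).  Ankle velocity (plantarflexion positive)
    peaks at toe-off and has its sharpest transient — the "impulse" — at
    heel-strike.  ``noise_sd`` is additive Gaussian noise in force-fraction
    units (FSRs) and scaled ×50 deg/s on the velocity channels.
    """
    if fs < 100:
        raise ValueError(f"fs={fs} Hz cannot resolve the double-support phase; need >= 100 Hz")
    rng = np.random.default_rng(np.random.SeedSequence(0 if seed is None else seed))
    n = int(round(timeline.t_end * fs)) + 1
    t = np.arange(n) / fs
    traces = []
    for foot, prefix in (("left", "L"), ("right", "R")):
        stances = _stance_intervals(timeline, foot)
        heel, toe = _fsr_curves(t, stances)
        # calcaneus leads 5MT at loading; 1MT leads hallux at unloading
        heel_late, _ = _fsr_curves(t - 0.02, stances)
        _, toe_early = _fsr_curves(t + 0.03, stances)
        chans = {
            f"{prefix}_calcaneus": heel,
            f"{prefix}_5MT": heel_late,
            f"{prefix}_hallux": toe,
            f"{prefix}_1MT": toe_early,
        }
        for label, x in chans.items():
            x = x + rng.normal(0.0, noise_sd, n) if noise_sd > 0 else x.copy()
            traces.append(SignalTrace(x, fs=fs, label=label, units="fraction"))
        # ankle angular velocity: raised-cosine plantarflexion burst peaking
        # at toe-off + a sharp braking transient at heel-strike
        v = np.zeros(n)
        hs_kind, to_kind = ("LHS", "LTO") if foot == "left" else ("RHS", "RTO")
        for to_t in timeline.event_times(to_kind):
            w = 0.30
            m = np.abs(t - to_t) < w / 2
            v[m] += 350.0 * 0.5 * (1 + np.cos(2 * np.pi * (t[m] - to_t) / w))
        for hs_t in timeline.event_times(hs_kind):
            v -= 80.0 * 0.5 * (1 + np.tanh((t - hs_t) / 0.012))
            v += 80.0 * 0.5 * (1 + np.tanh((t - hs_t - 0.25) / 0.08))
        if noise_sd > 0:
            v = v + rng.normal(0.0, 50.0 * noise_sd, n)
        traces.append(SignalTrace(v, fs=fs, label=f"{prefix}_ankle_vel", units="deg/s"))
    return RecordingBundle(traces, clock_id="kinematic",
                           metadata={"generator": "simulate_fsr", "noise_sd": noise_sd})


# ---------------------------------------------------------------------------
# Neural field potentials
# ---------------------------------------------------------------------------

def _one_over_f_noise(n: int, fs: float, exponent: float, scale: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Gaussian 1/f^beta noise by spectral shaping, RMS-normalized to *scale*."""
    w = rng.standard_normal(n)
    W = np.fft.rfft(w)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(W * shape, n=n)
    sd = x.std()
    return x * (scale / sd) if sd > 0 else x


def _inband_background_rms(fs: float, exponent: float, scale: float,
                           band: tuple[float, float], n: int) -> float:
    """RMS of the shaped background falling inside *band* (from the shaping filter)."""
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    p = np.zeros_like(f)
    p[1:] = f[1:] ** (-exponent)
    total = p.sum()
    inband = p[(f >= band[0]) & (f <= band[1])].sum()
    return scale * math.sqrt(inband / total) if total > 0 else 0.0


def _band_noise(n: int, fs: float, band: tuple[float, float],
                rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise (4th-order zero-phase Butterworth)."""
    sos = signal.butter(4, [band[0], band[1]], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    return x / x.std()


def _phase_gate(t: np.ndarray, timeline: GaitTimeline,
                window: tuple[float, float], ramp_pct: float = 5.0) -> np.ndarray:
    """Indicator of gait phase in *window* with raised-cosine edges.

    Returns g(t) in [0, 1]; zero outside gait cycles.
    """
    g = np.zeros_like(t)
    lo, hi = window
    for cyc in timeline.cycles:
        m = (t >= cyc.start) & (t < cyc.end)
        if not m.any():
            continue
        pct = cyc.percent(t[m])
        gm = np.zeros(pct.size)
        core = (pct >= lo) & (pct <= hi)
        gm[core] = 1.0
        if lo > 0:
            edge = (pct >= lo - ramp_pct) & (pct < lo)
            gm[edge] = 0.5 * (1 + np.cos(np.pi * (lo - pct[edge]) / ramp_pct))
        if hi < 100:
            edge = (pct > hi) & (pct <= hi + ramp_pct)
            gm[edge] = 0.5 * (1 + np.cos(np.pi * (pct[edge] - hi) / ramp_pct))
        g[m] = gm
    return g


def simulate_lfp(
    timeline: GaitTimeline,
    mods: list[ModulationSpec],
    fs: float = DEFAULT_LFP_FS,
    seed: int = 0,
    extra_channels: tuple[str, ...] = (),
) -> RecordingBundle:
    """Synthesize LFP channels: 1/f background + gait-gated band components.

    Each :class:`ModulationSpec` adds a band-pass-filtered Gaussian component
    to its channel, scaled so its RMS is ``snr`` times the background RMS in
    that band, with envelope ``1 + gain * gate(phase)``.  Channels named only
    in ``extra_channels`` carry background alone.  Child seeds are spawned
    per channel from the master seed, so channels are independent and the
    whole bundle is reproducible.
    """
    for mod in mods:
        mod.validate(fs)
    n = int(round(timeline.t_end * fs)) + 1
    t = np.arange(n) / fs
    channels: dict[str, list[ModulationSpec]] = {}
    for mod in mods:
        channels.setdefault(mod.channel, []).append(mod)
    for ch in extra_channels:
        channels.setdefault(ch, [])
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(channels))
    traces = []
    for child, (ch, chmods) in zip(children, sorted(channels.items())):
        rng = np.random.default_rng(child)
        bg_exp = chmods[0].background_exponent if chmods else 1.5
        bg_scale = chmods[0].background_scale if chmods else 10.0
        x = _one_over_f_noise(n, fs, bg_exp, bg_scale, rng)
        for mod in chmods:
            comp = _band_noise(n, fs, (mod.band_lo, mod.band_hi), rng)
            amp = mod.snr * _inband_background_rms(fs, mod.background_exponent,
                                                   mod.background_scale,
                                                   (mod.band_lo, mod.band_hi), n)
            env = 1.0 + mod.gain * _phase_gate(t, timeline, mod.phase_window)
            x = x + amp * env * comp
        traces.append(SignalTrace(x, fs=fs, label=ch, units="uV"))
    return RecordingBundle(traces, clock_id="neural",
                           metadata={"generator": "simulate_lfp", "seed": seed})


def simulate_coherent_pair(
    timeline: GaitTimeline,
    band: tuple[float, float],
    phase_window: tuple[float, float],
    mixing: float,
    fs: float = DEFAULT_LFP_FS,
    seed: int = 0,
    labels: tuple[str, str] = ("stn", "m1"),
    snr: float = 5.0,
    background_exponent: float = 1.5,
    background_scale: float = 10.0,
) -> RecordingBundle:
    """Two LFP channels sharing a gait-gated band-limited component.

    In-band content of channel *i* is ``sqrt(mixing)*gate*s +
    sqrt(1-mixing)*n_i`` where *s* is shared and the *n_i* are independent;
    ``mixing=0`` yields fully independent traces, ``mixing=1`` with a
    whole-cycle window makes the in-band content identical (coherence
    limited only by the background floor).
    """
    if not 0 <= mixing <= 1:
        raise ValueError("mixing must lie in [0, 1]")
    probe = ModulationSpec(labels[0], band[0], band[1], phase_window,
                           background_exponent=background_exponent,
                           background_scale=background_scale)
    probe.validate(fs)
    n = int(round(timeline.t_end * fs)) + 1
    t = np.arange(n) / fs
    ss = np.random.SeedSequence(seed)
    rng_s, rng_a, rng_b = (np.random.default_rng(c) for c in ss.spawn(3))
    shared = _band_noise(n, fs, band, rng_s)
    gate = _phase_gate(t, timeline, phase_window)
    amp = snr * _inband_background_rms(fs, background_exponent, background_scale, band, n)
    traces = []
    for label, rng in zip(labels, (rng_a, rng_b)):
        bg = _one_over_f_noise(n, fs, background_exponent, background_scale, rng)
        indep = _band_noise(n, fs, band, rng)
        x = bg + amp * (math.sqrt(mixing) * gate * shared
                        + math.sqrt(1.0 - mixing) * indep)
        traces.append(SignalTrace(x, fs=fs, label=label, units="uV"))
    return RecordingBundle(traces, clock_id="neural",
                           metadata={"generator": "simulate_coherent_pair",
                                     "mixing": mixing, "seed": seed})


# ---------------------------------------------------------------------------
# Clock-offset planting
# ---------------------------------------------------------------------------

def _tap_trace(n: int, fs: float, tap_times: np.ndarray, sync: SyncSpec,
               rng: np.random.Generator, label: str) -> SignalTrace:
    t = np.arange(n) / fs
    x = rng.normal(0.0, sync.noise_g, n)
    for tk in tap_times:
        x += sync.tap_amplitude * np.exp(-0.5 * ((t - tk) / sync.tap_width_s) ** 2)
    return SignalTrace(x, fs=fs, label=label, units="g")


def plant_offset(
    neural: RecordingBundle,
    kinematic: RecordingBundle,
    sync: SyncSpec,
    accel_fs_neural: float = DEFAULT_ACCEL_FS_NEURAL,
    accel_fs_kin: float = DEFAULT_KIN_FS,
    seed: int = 0,
) -> tuple[RecordingBundle, RecordingBundle]:
    """Add synchronization-tap accelerometer channels to both bundles.

    Taps occur at shared physical times.  The returned neural bundle is
    re-expressed on its own clock, which runs ``sync.offset_s`` ahead of the
    kinematic clock: a tap at *t* on the kinematic accel channel peaks at
    ``t + sync.offset_s`` on the neural-system accel channel (the LFP traces
    are shifted consistently).  The neural accelerometer runs at 64 Hz.
    """
    if sync.n_taps < 1:
        raise ValueError("need at least one tap to make alignment possible")
    kin_len = kinematic.span[1]
    neu_len = neural.span[1]
    if abs(sync.offset_s) >= min(kin_len, neu_len):
        raise ValueError("offset exceeds the recording length")
    taps = sync.first_tap_s + sync.tap_spacing_s * np.arange(sync.n_taps)
    if taps[-1] >= neu_len or taps[-1] >= kin_len:
        raise ValueError("taps fall outside one of the recordings")
    ss = np.random.SeedSequence(seed)
    rng_n, rng_k = (np.random.default_rng(c) for c in ss.spawn(2))
    n_neu = int(round(neu_len * accel_fs_neural)) + 1
    n_kin = int(round(kin_len * accel_fs_kin)) + 1
    from .io_sync import apply_offset

    neural_out = apply_offset(
        RecordingBundle(
            neural.traces + [_tap_trace(n_neu, accel_fs_neural, taps, sync,
                                        rng_n, "accel")],
            clock_id=neural.clock_id, metadata=dict(neural.metadata)),
        sync.offset_s,
    )
    kin_out = RecordingBundle(
        kinematic.traces + [_tap_trace(n_kin, accel_fs_kin, taps, sync,
                                       rng_k, "accel")],
        clock_id=kinematic.clock_id, metadata=dict(kinematic.metadata))
    return neural_out, kin_out
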