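"""Gait-event detection from FSR and ankle-velocity traces, and cycle building.

Heel-strike is called when the calcaneus *or* fifth-metatarsal FSR crosses a
5% (of normalized range) threshold in the positive direction; toe-off when
the hallux *or* first-metatarsal FSR crosses the threshold in the negative
direction.  The IMU route defines toe-off as the peak of ankle plantarflexion
velocity and heel-strike as the ankle-velocity impulse, read here as the peak
absolute time-derivative of velocity between toe-offs.  Gait cycles span
consecutive left heel-strikes (LHS anchored at 0% of the cycle); cycles that
overlap annotated turns, fall outside duration bounds, or violate the
LHS < RTO < RHS < LTO < LHS ordering are flagged excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage, signal

from .io_sync import SignalTrace

EVENT_KINDS = ("LHS", "RTO", "RHS", "LTO")

#: default detector settings; the merge window arbitrates the two-channel OR
#: rule and the refractory period suppresses threshold chatter re-triggering
DEFAULT_THRESHOLD = 0.05
DEFAULT_MERGE_WINDOW_S = 0.08
DEFAULT_REFRACTORY_S = 0.2
DEFAULT_DURATION_BOUNDS = (0.6, 2.5)


@dataclass(frozen=True, order=True)
class GaitEvent:
    """One kinematic landmark on the common clock."""

    time_s: float
    kind: str  # LHS | RHS | LTO | RTO
    source: str = "fsr"  # fsr | imu | manual
    quality: str = "auto"  # auto | corrected

    def __post_init__(self):
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass
class GaitCycle:
    """One validated left-heel-strike-to-left-heel-strike cycle."""

    start: float  # LHS
    rto: float
    rhs: float
    lto: float
    end: float  # next LHS
    excluded: bool = False
    reason: str | None = None  # turn | duration | sequence

    @property
    def duration(self) -> float:
        return self.end - self.start

    def percent(self, t: float | np.ndarray) -> np.ndarray:
        """Map time(s) to percent of this cycle (0% at LHS)."""
        return 100.0 * (np.asarray(t) - self.start) / self.duration


def normalize_fsr(trace: SignalTrace) -> SignalTrace:
    """Rescale an FSR trace to the [0, 1] force-fraction range.

    The baseline (5th percentile) is subtracted and the result divided by the
    99.5th-percentile amplitude, then clipped to [0, 1.05].  Percentiles make
    the mapping robust to spikes and give the 5% detection threshold a
    well-defined referent on uncalibrated sensors; the result is invariant to
    positive affine transforms of the input.
    """
    x = trace.samples
    lo = np.percentile(x, 5)
    hi = np.percentile(x, 99.5)
    if hi - lo <= 0 or np.ptp(x) == 0:
        raise ValueError(f"trace {trace.label!r} has no dynamic range")
    y = np.clip((x - lo) / (hi - lo), 0.0, 1.05)
    return replace(trace, samples=y, units="fraction")


#: a crossing only counts as a contact transition when the trace comes *from*
#: the opposite load state and *confirms* the new one shortly afterwards:
#: heel-strike must rise from a released foot (< 0.5x threshold within the
#: preceding window) to solid load (>= 4x threshold within the following
#: window), toe-off symmetrically.  Bare crossings from sensor noise riding
#: a slow ramp are rejected.
CONFIRM_WINDOW_S = 0.1
PRESTATE_WINDOW_S = 0.3
CONFIRM_LOAD_FACTOR = 4.0
CONFIRM_RELEASE_FACTOR = 0.5


def _confirmed_crossings(trace: SignalTrace, threshold: float,
                         direction: int) -> np.ndarray:
    x = trace.samples
    if direction > 0:
        idx = np.flatnonzero((x[:-1] < threshold) & (x[1:] >= threshold)) + 1
    else:
        idx = np.flatnonzero((x[:-1] >= threshold) & (x[1:] < threshold)) + 1
    w_post = max(int(CONFIRM_WINDOW_S * trace.fs), 1)
    w_pre = max(int(PRESTATE_WINDOW_S * trace.fs), 1)
    load = CONFIRM_LOAD_FACTOR * threshold
    release = CONFIRM_RELEASE_FACTOR * threshold
    keep = []
    for i in idx:
        pre = x[max(i - w_pre, 0):i]
        post = x[i:i + w_post]
        if direction > 0:
            ok = (pre.size == 0 or pre.min() <= release) and post.max() >= load
        else:
            ok = (pre.size == 0 or pre.max() >= load) and post.min() <= release
        if ok:
            keep.append(i)
    return trace.t0 + np.asarray(keep, dtype=float) / trace.fs


def _positive_crossings(trace: SignalTrace, threshold: float) -> np.ndarray:
    return _confirmed_crossings(trace, threshold, +1)


def _negative_crossings(trace: SignalTrace, threshold: float) -> np.ndarray:
    return _confirmed_crossings(trace, threshold, -1)


def _merge_two_channel(
    times_a: np.ndarray, times_b: np.ndarray, merge_window_s: float, take: str
) -> np.ndarray:
    """Cluster crossings from two channels; keep one time per cluster."""
    times = np.sort(np.concatenate([times_a, times_b]))
    if times.size == 0:
        return times
    out = []
    cluster = [times[0]]
    for t in times[1:]:
        if t - cluster[-1] <= merge_window_s:
            cluster.append(t)
        else:
            out.append(min(cluster) if take == "earliest" else max(cluster))
            cluster = [t]
    out.append(min(cluster) if take == "earliest" else max(cluster))
    return np.asarray(out)


def _apply_refractory(times: np.ndarray, refractory_s: float) -> np.ndarray:
    """Chained refractory: a crossing within the refractory period of the
    previous crossing (accepted or not) is suppressed, so threshold chatter
    yields a single event."""
    accepted = []
    last = -np.inf
    for t in times:
        if t - last >= refractory_s:
            accepted.append(t)
        last = t
    return np.asarray(accepted)


def detect_heel_strikes(
    calcaneus: SignalTrace,
    fifth_mt: SignalTrace,
    side: str = "left",
    threshold: float = DEFAULT_THRESHOLD,
    merge_window_s: float = DEFAULT_MERGE_WINDOW_S,
    refractory_s: float = DEFAULT_REFRACTORY_S,
) -> list[GaitEvent]:
    """Heel-strikes: positive threshold crossings on calcaneus or 5MT.

    When both channels cross within the merge window the *earlier* crossing
    wins (first ground contact).  Traces must already be normalized.
    """
    if calcaneus.fs != fifth_mt.fs:
        raise ValueError("calcaneus and 5MT traces must share a sampling rate")
    merged = _merge_two_channel(
        _positive_crossings(calcaneus, threshold),
        _positive_crossings(fifth_mt, threshold),
        merge_window_s,
        take="earliest",
    )
    kind = "LHS" if side == "left" else "RHS"
    return [GaitEvent(t, kind, source="fsr") for t in _apply_refractory(merged, refractory_s)]


def detect_toe_offs(
    hallux: SignalTrace,
    first_mt: SignalTrace,
    side: str = "left",
    threshold: float = DEFAULT_THRESHOLD,
    merge_window_s: float = DEFAULT_MERGE_WINDOW_S,
    refractory_s: float = DEFAULT_REFRACTORY_S,
) -> list[GaitEvent]:
    """Toe-offs: negative threshold crossings on hallux or 1MT.

    When both channels unload within the merge window the *later* crossing
    wins (the toe is only off once the last sensor unloads).
    """
    if hallux.fs != first_mt.fs:
        raise ValueError("hallux and 1MT traces must share a sampling rate")
    merged = _merge_two_channel(
        _negative_crossings(hallux, threshold),
        _negative_crossings(first_mt, threshold),
        merge_window_s,
        take="latest",
    )
    kind = "LTO" if side == "left" else "RTO"
    return [GaitEvent(t, kind, source="fsr") for t in _apply_refractory(merged, refractory_s)]


def detect_events_velocity(
    ankle_velocity: SignalTrace,
    side: str = "left",
    prominence_frac: float = 0.4,
    min_spacing_s: float = 0.5,
    smooth_s: float = 0.02,
    hs_margin_s: float = 0.15,
    heel_strike_strategy: str = "impulse",
) -> list[GaitEvent]:
    """Detect toe-off and heel-strike from ankle angular velocity (IMU route).

    Toe-off is the time of peak plantarflexion velocity (positive sign
    convention).  Heel-strike follows the "velocity impulse" reading: the peak
    absolute time-derivative of velocity within each inter-toe-off interval
    (``heel_strike_strategy='impulse'``, the only strategy currently
    implemented; the switch isolates this interpretation).
    """
    if heel_strike_strategy != "impulse":
        raise ValueError(f"unknown heel-strike strategy {heel_strike_strategy!r}")
    v = ankle_velocity.samples
    if smooth_s > 0:
        v = ndimage.gaussian_filter1d(v, sigma=max(smooth_s * ankle_velocity.fs, 1e-9))
    vmax = v.max()
    if vmax <= 0 or np.ptp(v) == 0:
        return []
    peaks, _ = signal.find_peaks(
        v,
        prominence=prominence_frac * vmax,
        distance=max(int(min_spacing_s * ankle_velocity.fs), 1),
    )
    to_kind = "LTO" if side == "left" else "RTO"
    hs_kind = "LHS" if side == "left" else "RHS"
    times = ankle_velocity.times
    events = [GaitEvent(times[p], to_kind, source="imu") for p in peaks]
    dv = np.abs(np.gradient(v) * ankle_velocity.fs)
    margin = int(hs_margin_s * ankle_velocity.fs)
    for p0, p1 in zip(peaks[:-1], peaks[1:]):
        i0, i1 = p0 + margin, p1 - margin
        if i1 - i0 < 2:
            continue
        ihs = i0 + int(np.argmax(dv[i0:i1]))
        events.append(GaitEvent(times[ihs], hs_kind, source="imu"))
    return sorted(events)


def build_cycles(
    events: Sequence[GaitEvent],
    turn_intervals: Iterable[tuple[float, float]] = (),
    duration_bounds: tuple[float, float] = DEFAULT_DURATION_BOUNDS,
) -> list[GaitCycle]:
    """Form gait cycles from consecutive LHS pairs and validate each one.

    A cycle is excluded (with a reason) if it overlaps a declared turn
    interval, if its duration falls outside ``duration_bounds``, or if its
    interior does not contain exactly one RTO, RHS, and LTO in that order.
    Manually corrected event lists are revalidated by simply calling this
    again.
    """
    times = [e.time_s for e in events]
    if any(b < a for a, b in zip(times[:-1], times[1:])):
        raise ValueError("events must be sorted by time")
    turns = list(turn_intervals)
    lhs = [e.time_s for e in events if e.kind == "LHS"]
    cycles: list[GaitCycle] = []
    for start, end in zip(lhs[:-1], lhs[1:]):
        interior = [e for e in events if start < e.time_s < end and e.kind != "LHS"]
        by_kind = {k: [e.time_s for e in interior if e.kind == k] for k in ("RTO", "RHS", "LTO")}
        seq_ok = all(len(v) == 1 for v in by_kind.values())
        rto = by_kind["RTO"][0] if by_kind["RTO"] else np.nan
        rhs = by_kind["RHS"][0] if by_kind["RHS"] else np.nan
        lto = by_kind["LTO"][0] if by_kind["LTO"] else np.nan
        if seq_ok:
            seq_ok = start < rto < rhs < lto < end
        cyc = GaitCycle(start, rto, rhs, lto, end)
        if any(start < t_hi and end > t_lo for t_lo, t_hi in turns):
            cyc.excluded, cyc.reason = True, "turn"
        elif not (duration_bounds[0] <= cyc.duration <= duration_bounds[1]):
            cyc.excluded, cyc.reason = True, "duration"
        elif not seq_ok:
            cyc.excluded, cyc.reason = True, "sequence"
        cycles.append(cyc)
    return cycles


def included(cycles: Iterable[GaitCycle]) -> list[GaitCycle]:
    return [c for c in cycles if not c.excluded]


# -- event table serialization ------------------------------------------------

def events_to_table(events: Sequence[GaitEvent]):
    import pandas as pd

    return pd.DataFrame(
        {
            "kind": [e.kind for e in events],
            "time_s": [e.time_s for e in events],
            "source": [e.source for e in events],
            "quality": [e.quality for e in events],
        }
    )


def events_from_table(df) -> list[GaitEvent]:
    return sorted(
        GaitEvent(float(r.time_s), r.kind, r.source, r.quality)
        for r in df.itertuples(index=False)
    )
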