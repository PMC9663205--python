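"""Recording containers, delimited-text IO, and clock synchronization.

A walking session is recorded on two independent systems — the implanted
neural device (LFP channels at 500 Hz, on-board accelerometer at 64 Hz) and
the wearable kinematic sensors (FSRs, ankle angular velocity, accelerometer).
Each system has its own clock.  This module defines the in-memory containers
(:class:`SignalTrace`, :class:`RecordingBundle`), a plain-text container
format (one CSV per sampling-rate group plus a JSON sidecar), and constant
clock-offset estimation by cross-correlating the accelerometer envelopes of
the synchronization taps performed on both devices at the start of a session.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal


class AlignmentError(RuntimeError):
    """Raised when no trustworthy cross-correlation peak can be found."""


@dataclass
class SignalTrace:
    """One uniformly sampled channel.

    Parameters
    ----------
    samples : ndarray
        Amplitudes (µV for LFP, normalized force fraction for FSR, deg/s for
        ankle velocity, g for accelerometry).
    fs : float
        Sampling rate in Hz.
    label : str
        Unique channel name within a bundle.
    units : str
        Physical units of ``samples``.
    t0 : float
        Time of the first sample, in seconds on the bundle's clock.
    """

    samples: np.ndarray
    fs: float
    label: str
    units: str = ""
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("samples must be a 1-d array with length >= 2")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(f"trace {self.label!r} contains non-finite samples")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs

    @property
    def t_end(self) -> float:
        return self.t0 + (self.n - 1) / self.fs

    def shifted(self, offset_s: float) -> "SignalTrace":
        return replace(self, t0=self.t0 + offset_s)


@dataclass
class RecordingBundle:
    """A set of traces sharing one clock (one recording system)."""

    traces: list[SignalTrace]
    clock_id: str = "default"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = [t.label for t in self.traces]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate trace labels in bundle: {labels}")

    def __getitem__(self, label: str) -> SignalTrace:
        for t in self.traces:
            if t.label == label:
                return t
        raise KeyError(f"no trace labelled {label!r} in bundle {self.clock_id!r}")

    @property
    def labels(self) -> list[str]:
        return [t.label for t in self.traces]

    @property
    def span(self) -> tuple[float, float]:
        """Interval covered by *every* trace in the bundle."""
        return (max(t.t0 for t in self.traces), min(t.t_end for t in self.traces))


# ---------------------------------------------------------------------------
# Plain-text container: one CSV per (fs, t0, length) group + JSON sidecar.
# ---------------------------------------------------------------------------

_SIDECAR = "bundle.json"


def write_bundle(bundle: RecordingBundle, path: str | Path) -> Path:
    """Write a bundle to *path* (a directory, created if needed).

    Samples are serialized with 17 significant digits so that a write→read
    round trip is bit exact for float64.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    groups: dict[tuple, list[SignalTrace]] = {}
    for tr in bundle.traces:
        groups.setdefault((tr.fs, tr.t0, tr.n), []).append(tr)
    sidecar: dict = {
        "clock_id": bundle.clock_id,
        "metadata": bundle.metadata,
        "groups": [],
    }
    for gi, (key, traces) in enumerate(sorted(groups.items())):
        fs, t0, n = key
        fname = f"signals_{gi}.csv"
        data = np.column_stack([t.samples for t in traces])
        np.savetxt(path / fname, data, delimiter=",", fmt="%.17g")
        sidecar["groups"].append(
            {
                "file": fname,
                "fs": fs,
                "t0": t0,
                "n_samples": int(n),
                "labels": [t.label for t in traces],
                "units": [t.units for t in traces],
            }
        )
    (path / _SIDECAR).write_text(json.dumps(sidecar, indent=1))
    return path


def read_bundle(path: str | Path) -> RecordingBundle:
    """Read a bundle written by :func:`write_bundle`."""
    path = Path(path)
    sc_path = path / _SIDECAR
    if not sc_path.exists():
        raise FileNotFoundError(f"no {_SIDECAR} sidecar under {path}")
    try:
        sidecar = json.loads(sc_path.read_text())
    except json.JSONDecodeError as e:
        raise ValueError(f"malformed sidecar {sc_path}: {e}") from e
    traces = []
    for group in sidecar["groups"]:
        fs = float(group["fs"])
        if fs <= 0:
            raise ValueError(f"sidecar declares non-positive fs={fs}")
        fpath = path / group["file"]
        if not fpath.exists():
            raise FileNotFoundError(f"missing channel file {fpath}")
        data = np.loadtxt(fpath, delimiter=",", ndmin=2)
        if data.shape != (group["n_samples"], len(group["labels"])):
            raise ValueError(
                f"{fpath}: expected shape {(group['n_samples'], len(group['labels']))}, "
                f"got {data.shape}"
            )
        for ci, (label, units) in enumerate(zip(group["labels"], group["units"])):
            traces.append(
                SignalTrace(data[:, ci], fs=fs, label=label, units=units,
                            t0=float(group["t0"]))
            )
    return RecordingBundle(traces, clock_id=sidecar["clock_id"],
                           metadata=sidecar["metadata"])


# ---------------------------------------------------------------------------
# Clock alignment by accelerometer tap cross-correlation.
# ---------------------------------------------------------------------------

def _tap_envelope(trace: SignalTrace, smooth_hz: float) -> np.ndarray:
    """Rectified, low-pass-smoothed, mean-removed accel envelope."""
    x = np.abs(trace.samples - np.median(trace.samples))
    nyq = trace.fs / 2
    if smooth_hz < nyq:
        sos = signal.butter(4, smooth_hz / nyq, output="sos")
        x = signal.sosfiltfilt(sos, x)
    return x - x.mean()


def align_streams(
    neural_accel: SignalTrace,
    kin_accel: SignalTrace,
    smooth_hz: float = 5.0,
    min_peak_corr: float = 0.5,
) -> float:
    """Estimate the constant clock offset between the two recording systems.

    Both accelerometer channels capture the same physical taps.  The offset is
    the lag maximizing the normalized cross-correlation of the rectified,
    5 Hz-low-passed envelopes, evaluated on the coarser of the two sampling
    grids and refined to sub-sample precision by parabolic interpolation of
    the correlation peak.

    Returns
    -------
    float
        ``offset_s`` such that an event at time *t* on the kinematic clock
        appears at ``t + offset_s`` on the neural clock.  Shifting the
        kinematic bundle by ``+offset_s`` (or the neural bundle by
        ``-offset_s``) co-registers the streams.

    Raises
    ------
    AlignmentError
        If the normalized correlation peak is below ``min_peak_corr`` —
        typically because no common taps are present.
    """
    fs = min(neural_accel.fs, kin_accel.fs)

    def _resampled(tr: SignalTrace) -> tuple[np.ndarray, float]:
        env = _tap_envelope(tr, smooth_hz)
        if tr.fs == fs:
            return env, tr.t0
        n_out = int(math.floor((tr.n - 1) * fs / tr.fs)) + 1
        t_out = np.arange(n_out) / fs
        return np.interp(t_out, np.arange(tr.n) / tr.fs, env), tr.t0

    en, t0n = _resampled(neural_accel)
    ek, t0k = _resampled(kin_accel)
    c = signal.correlate(en, ek, mode="full")
    norm = np.sqrt(np.sum(en**2) * np.sum(ek**2))
    if norm == 0:
        raise AlignmentError("flat accelerometer envelope; no taps to align")
    c = c / norm
    ipk = int(np.argmax(c))
    if c[ipk] < min_peak_corr:
        raise AlignmentError(
            f"correlation peak {c[ipk]:.3f} below threshold {min_peak_corr}; "
            "streams share no detectable tap events"
        )
    lag = ipk - (ek.size - 1)
    # parabolic sub-sample refinement; 64 Hz quantization otherwise dominates
    if 0 < ipk < c.size - 1:
        denom = c[ipk - 1] - 2 * c[ipk] + c[ipk + 1]
        if denom < 0:
            lag = lag + 0.5 * (c[ipk - 1] - c[ipk + 1]) / denom
    # lag is the shift of the neural envelope relative to the kinematic one on
    # their own grids; fold in the starting times of each stream.
    return lag / fs + t0n - t0k


def apply_offset(bundle: RecordingBundle, offset_s: float) -> RecordingBundle:
    """Return a copy of *bundle* with every trace's clock shifted by +offset_s."""
    if not np.isfinite(offset_s):
        raise ValueError("offset must be finite")
    return RecordingBundle(
        [t.shifted(offset_s) for t in bundle.traces],
        clock_id=bundle.clock_id,
        metadata=dict(bundle.metadata),
    )


def crop_to_overlap(
    a: RecordingBundle, b: RecordingBundle
) -> tuple[RecordingBundle, RecordingBundle]:
    """Crop both bundles to their common time interval (no resampling)."""
    lo = max(a.span[0], b.span[0])
    hi = min(a.span[1], b.span[1])
    if hi <= lo:
        raise ValueError(f"bundles do not overlap (common span [{lo}, {hi}])")

    def _crop(bundle: RecordingBundle) -> RecordingBundle:
        out = []
        for tr in bundle.traces:
            i0 = int(math.ceil((lo - tr.t0) * tr.fs - 1e-9))
            i1 = int(math.floor((hi - tr.t0) * tr.fs + 1e-9))
            i0 = max(i0, 0)
            i1 = min(i1, tr.n - 1)
            out.append(
                SignalTrace(tr.samples[i0 : i1 + 1], fs=tr.fs, label=tr.label,
                            units=tr.units, t0=tr.t0 + i0 / tr.fs)
            )
        return RecordingBundle(out, clock_id=bundle.clock_id,
                               metadata=dict(bundle.metadata))

    return _crop(a), _crop(b)
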