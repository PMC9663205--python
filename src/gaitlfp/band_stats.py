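"""Frequency-band biomarker statistics.

Three layers of inference operate on cycle-normalized maps and event-locked
power:

* a per-tile linear repeated-measures mixed model (random subject intercept,
  restricted maximum likelihood, F-test of the fixed intercept with
  Satterthwaite denominator degrees of freedom) masking (frequency,
  percent-bin) tiles whose power departs from the whole-walk average;
* an exhaustive scan of all contiguous frequency bands on an elementary grid
  (n bins -> n(n+1)/2 candidate bands), testing instantaneous power at the
  four gait events with a Kruskal-Wallis omnibus and Tukey-HSD-style
  adjusted pairwise comparisons on rank means (Nemenyi procedure); a band is
  flagged a gait-event-modulated biomarker when any adjusted pairwise
  p < alpha;
* Shapiro-Wilk / Levene diagnostics reported alongside the scan (they
  motivate the rank-based omnibus; they do not gate it).

No correction is applied across candidate bands; the scan reports how many
bands were tested so users can post-filter.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .gait_events import EVENT_KINDS, GaitEvent
from .spectral import TimeFrequencyMap

EVENT_PAIRS = list(itertools.combinations(EVENT_KINDS, 2))


@dataclass(frozen=True, order=True)
class FrequencyBand:
    lo: float
    hi: float

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ValueError(f"need lo < hi, got [{self.lo}, {self.hi}]")

    @property
    def width(self) -> float:
        return self.hi - self.lo

    def intersects(self, lo: float, hi: float) -> bool:
        return self.lo < hi and self.hi > lo


def scan_grid_edges(lo: float = 0.0, hi: float = 50.0, step: float = 1.0) -> np.ndarray:
    """Elementary bin edges for the 0-50 Hz biomarker scan (1 Hz default)."""
    return np.arange(lo, hi + step / 2, step)


def decoder_grid_edges(lo: float = 2.5, hi: float = 50.0, n_bins: int = 59) -> np.ndarray:
    """Elementary bin edges for the decoder grid: 59 bins spanning 2.5-50 Hz,
    so that exhaustive enumeration yields 59*60/2 = 1770 candidate bands."""
    return np.linspace(lo, hi, n_bins + 1)


def enumerate_bands(edges: np.ndarray) -> list[FrequencyBand]:
    """All contiguous runs of elementary bins, ordered by (lo, hi)."""
    edges = np.asarray(edges, dtype=float)
    if edges.size < 2:
        raise ValueError("need at least one elementary bin (two edges)")
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    n = edges.size - 1
    return [FrequencyBand(edges[i], edges[j])
            for i in range(n) for j in range(i + 1, n + 1)]


# ---------------------------------------------------------------------------
# Event-locked power extraction
# ---------------------------------------------------------------------------

def _nearest_frames(times: np.ndarray, t_events: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Index of the frame whose center is nearest each event (earlier frame on
    ties); second array flags events farther than half a hop from any frame."""
    idx = np.searchsorted(times, t_events)
    idx = np.clip(idx, 1, times.size - 1)
    d_prev = t_events - times[idx - 1]
    d_next = times[idx] - t_events
    nearest = np.where(d_prev <= d_next, idx - 1, idx)  # tie -> earlier frame
    hop = float(np.median(np.diff(times)))
    ok = np.abs(times[nearest] - t_events) <= hop / 2 + 1e-9
    return nearest, ok


def extract_event_power(
    tfmap: TimeFrequencyMap,
    events: list[GaitEvent],
    band: FrequencyBand | tuple[float, float],
) -> pd.DataFrame:
    """Instantaneous band power at each gait event.

    Power is averaged over the band's frequency rows at the frame whose
    center is nearest the event time (earlier frame on exact ties).  Events
    beyond half a hop from any frame center are dropped with a warning.
    Returns a tidy frame with columns kind, time_s, power, cycle_index.
    """
    lo, hi = (band.lo, band.hi) if isinstance(band, FrequencyBand) else band
    rows = tfmap.band_rows(lo, hi)
    t_events = np.array([e.time_s for e in events])
    kinds = np.array([e.kind for e in events])
    nearest, ok = _nearest_frames(tfmap.times, t_events)
    if not ok.all():
        warnings.warn(f"dropped {int((~ok).sum())} event(s) outside the map's "
                      "frame grid", stacklevel=2)
    power = tfmap.values[np.ix_(rows, nearest[ok])].mean(axis=0)
    return pd.DataFrame({
        "kind": kinds[ok],
        "time_s": t_events[ok],
        "power": power,
        "cycle_index": np.arange(len(events))[ok],
    })


def event_bin_powers(
    tfmap: TimeFrequencyMap,
    events: list[GaitEvent],
    edges: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-event power in each elementary bin of *edges*.

    Returns ``(P, kinds, times)`` where ``P[e, b]`` is the mean power over
    frequency rows inside bin *b* at the frame nearest event *e*.  Band
    powers for any contiguous run of bins are then cumulative-sum averages of
    columns of ``P`` (see :func:`band_powers_from_bins`).
    """
    edges = np.asarray(edges, dtype=float)
    t_events = np.array([e.time_s for e in events])
    kinds = np.array([e.kind for e in events])
    nearest, ok = _nearest_frames(tfmap.times, t_events)
    if not ok.all():
        warnings.warn(f"dropped {int((~ok).sum())} event(s) outside the map's "
                      "frame grid", stacklevel=2)
    frames = tfmap.values[:, nearest[ok]]  # (n_freqs, n_events)
    n_bins = edges.size - 1
    P = np.empty((ok.sum(), n_bins))
    for b in range(n_bins):
        m = (tfmap.freqs >= edges[b]) & (tfmap.freqs < edges[b + 1])
        if b == n_bins - 1:
            m |= tfmap.freqs == edges[-1]
        if not m.any():
            # empty elementary bin: inherit the nearest row so the scan stays
            # defined on coarse maps
            m = np.abs(tfmap.freqs - 0.5 * (edges[b] + edges[b + 1])).argmin()
            P[:, b] = frames[m]
        else:
            P[:, b] = frames[m].mean(axis=0)
    return P, kinds[ok], t_events[ok]


def band_powers_from_bins(P: np.ndarray, i: int, j: int) -> np.ndarray:
    """Mean power over elementary bins i..j-1 for every event (row)."""
    return P[:, i:j].mean(axis=1)


# ---------------------------------------------------------------------------
# Kruskal-Wallis scan with Tukey-HSD-style post hoc on rank means
# ---------------------------------------------------------------------------

def kruskal_wallis_h(groups: list[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and chi-square p-value."""
    all_identical = len({float(v) for g in groups for v in g}) == 1
    if all_identical:
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def _nemenyi_pairwise(groups: dict[str, np.ndarray]) -> dict[tuple[str, str], float]:
    """Tukey-HSD-adjusted pairwise comparisons on rank means (Nemenyi).

    Rank all observations jointly (tie-corrected), compare class mean ranks
    with the studentized-range distribution at k groups and infinite df.
    """
    labels = list(groups)
    values = np.concatenate([groups[k] for k in labels])
    if np.ptp(values) == 0:
        return {pair: 1.0 for pair in itertools.combinations(labels, 2)}
    ranks = stats.rankdata(values)
    n_tot = values.size
    splits = np.cumsum([groups[k].size for k in labels])[:-1]
    mean_ranks = {k: r.mean() for k, r in zip(labels, np.split(ranks, splits))}
    _, counts = np.unique(values, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (n_tot - 1))
    var_base = n_tot * (n_tot + 1) / 12.0 - tie_term
    k = len(labels)
    out = {}
    for a, b in itertools.combinations(labels, 2):
        se = math.sqrt(var_base * (1.0 / groups[a].size + 1.0 / groups[b].size))
        if se == 0:
            out[(a, b)] = 1.0
            continue
        q = abs(mean_ranks[a] - mean_ranks[b]) / se * math.sqrt(2.0)
        out[(a, b)] = float(stats.studentized_range.sf(q, k, 1e6))
    return out


def _tukey_raw_pairwise(groups: dict[str, np.ndarray]) -> dict[tuple[str, str], float]:
    """Alternative post hoc: Tukey HSD on the raw values."""
    labels = list(groups)
    if np.ptp(np.concatenate([groups[k] for k in labels])) == 0:
        return {pair: 1.0 for pair in itertools.combinations(labels, 2)}
    res = stats.tukey_hsd(*[groups[k] for k in labels])
    return {(labels[i], labels[j]): float(res.pvalue[i, j])
            for i, j in itertools.combinations(range(len(labels)), 2)}


def scan_bands(
    P: np.ndarray,
    kinds: np.ndarray,
    edges: np.ndarray,
    alpha: float = 0.05,
    posthoc: str = "rank-nemenyi",
) -> pd.DataFrame:
    """Exhaustive contiguous-band Kruskal-Wallis scan.

    Parameters
    ----------
    P, kinds
        Output of :func:`event_bin_powers`: per-event elementary-bin powers
        and the event kind of each row.
    edges
        Elementary bin edges defining the candidate bands.
    posthoc
        ``'rank-nemenyi'`` (Tukey-HSD adjustment on rank means, default) or
        ``'tukey-raw'`` (Tukey HSD on raw values).

    Returns a table with one row per candidate band: lo, hi, kw_h, kw_p, six
    adjusted pairwise p-values and the significance flag (any adjusted
    pairwise p < alpha, the biomarker designation rule).  Bands where any
    event class has fewer than two samples are skipped with a warning.
    ``result.attrs['n_bands_tested']`` records the multiplicity.
    """
    posthoc_fn = {"rank-nemenyi": _nemenyi_pairwise,
                  "tukey-raw": _tukey_raw_pairwise}[posthoc]
    edges = np.asarray(edges, dtype=float)
    n_bins = edges.size - 1
    class_idx = {k: np.flatnonzero(kinds == k) for k in EVENT_KINDS}
    short = [k for k, idx in class_idx.items() if idx.size < 2]
    if short:
        warnings.warn(f"event class(es) {short} have <2 samples; scan skipped",
                      stacklevel=2)
        return pd.DataFrame()
    csum = np.concatenate([np.zeros((P.shape[0], 1)), np.cumsum(P, axis=1)], axis=1)
    rows = []
    for i in range(n_bins):
        for j in range(i + 1, n_bins + 1):
            vals = (csum[:, j] - csum[:, i]) / (j - i)
            groups = {k: vals[idx] for k, idx in class_idx.items()}
            h, p = kruskal_wallis_h(list(groups.values()))
            padj = posthoc_fn(groups)
            row = {"lo": edges[i], "hi": edges[j], "kw_h": h, "kw_p": p}
            for (a, b), pv in padj.items():
                row[f"p_{a}_{b}"] = pv
            row["significant"] = bool(min(padj.values()) < alpha)
            rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["n_bands_tested"] = len(rows)
    out.attrs["alpha"] = alpha
    out.attrs["posthoc"] = posthoc
    return out


def distribution_diagnostics(samples: pd.DataFrame) -> pd.DataFrame:
    """Shapiro-Wilk per event class and Levene across classes.

    Informational companions to the scan (the rank-based omnibus is justified
    by non-normal but equal-variance classes); they never gate it.
    """
    rows = []
    groups = []
    for kind, sub in samples.groupby("kind"):
        x = sub["power"].to_numpy()
        groups.append(x)
        if x.size < 3:
            rows.append({"test": "shapiro", "class": kind, "p": np.nan})
            continue
        rows.append({"test": "shapiro", "class": kind,
                     "p": float(stats.shapiro(x[:5000]).pvalue)})
    if len(groups) >= 2 and all(g.size >= 2 for g in groups):
        rows.append({"test": "levene", "class": "all",
                     "p": float(stats.levene(*groups, center="median").pvalue)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Per-tile repeated-measures mixed model (random subject intercept, REML)
# ---------------------------------------------------------------------------

@dataclass
class MixedModelResult:
    estimate: float  # fixed intercept (mean departure from whole-walk average)
    se: float
    fstat: float
    df_den: float  # Satterthwaite denominator df
    p: float
    sigma_b2: float  # between-subject variance
    sigma_e2: float  # residual (cycle-to-cycle) variance
    boundary: bool  # True when the between-subject variance hit zero


@dataclass
class SignificanceMask:
    """Boolean mask plus per-tile model summaries on a freqs x bins grid."""

    freqs: np.ndarray
    mask: np.ndarray
    p: np.ndarray
    estimate: np.ndarray
    fstat: np.ndarray
    df_den: np.ndarray
    alpha: float


def _reml_profile(lam: float, ns: np.ndarray, means: np.ndarray,
                  sses: np.ndarray) -> tuple[float, float, float]:
    """Profiled REML criterion for the random-intercept model.

    ``lam`` is the variance ratio sigma_b^2 / sigma_e^2.  Returns the
    criterion (-2 restricted loglik up to a constant), the profiled
    sigma_e^2, and the GLS intercept.
    """
    w = ns / (1.0 + lam * ns)
    sw = w.sum()
    mu = (w * means).sum() / sw
    ss = sses.sum() + (w * (means - mu) ** 2).sum()
    n_tot = ns.sum()
    sigma_e2 = ss / (n_tot - 1)
    crit = ((n_tot - 1) * math.log(sigma_e2)
            + np.log1p(lam * ns).sum() + math.log(sw))
    return crit, sigma_e2, mu


def _neg2_reml(theta: np.ndarray, ns: np.ndarray, means: np.ndarray,
               sses: np.ndarray) -> float:
    """Unprofiled -2 restricted loglik (up to a constant) at
    theta = (sigma_b^2, sigma_e^2); used for the Satterthwaite Hessian."""
    sb2, se2 = theta
    denom = se2 + ns * sb2
    w = ns / denom
    mu = (w * means).sum() / w.sum()
    logdet = ((ns - 1) * math.log(se2)).sum() + np.log(denom).sum()
    quad = (sses / se2).sum() + (w * (means - mu) ** 2).sum()
    return logdet + quad + math.log(w.sum())


def fit_random_intercept(ys: list[np.ndarray]) -> MixedModelResult:
    """Test whether the grand mean differs from zero, with a random subject
    intercept (REML) and a Satterthwaite-df F-test.

    Parameters
    ----------
    ys : list of arrays
        Per-subject replicate values (e.g. one z value per gait cycle).

    Notes
    -----
    With m balanced subjects and positive between-subject variance the
    Satterthwaite df approaches the classical m - 1; when the REML estimate
    of the between-subject variance is zero (boundary), the test reduces to
    the one-sample F over all N observations with df N - 1.
    """
    if len(ys) < 2:
        raise ValueError("need at least two subjects")
    ns = np.array([len(y) for y in ys], dtype=float)
    if np.any(ns < 2):
        raise ValueError("need at least two replicates per subject")
    means = np.array([np.mean(y) for y in ys])
    sses = np.array([np.sum((y - m) ** 2) for y, m in zip(ys, means)])
    n_tot = ns.sum()

    grand = float((ns * means).sum() / n_tot)
    total_ss = sses.sum() + float((ns * (means - grand) ** 2).sum())
    if total_ss <= 1e-30 * max(abs(grand), 1.0):
        # degenerate constant data: no variance to test against
        p = 1.0 if grand == 0.0 else 0.0
        return MixedModelResult(grand, 0.0, np.inf if grand else 0.0,
                                n_tot - 1.0, p, 0.0, 0.0, True)

    crit0 = _reml_profile(0.0, ns, means, sses)[0]
    res = optimize.minimize_scalar(
        lambda t: _reml_profile(10.0**t, ns, means, sses)[0],
        bounds=(-10.0, 6.0), method="bounded",
        options={"xatol": 1e-10},
    )
    if res.fun < crit0 - 1e-12:
        lam = 10.0**res.x
    else:
        lam = 0.0
    _, sigma_e2, mu = _reml_profile(lam, ns, means, sses)
    sigma_b2 = lam * sigma_e2
    var_mu = 1.0 / (ns / (sigma_e2 + ns * sigma_b2)).sum()
    boundary = lam == 0.0
    if boundary:
        df = n_tot - 1.0
    else:
        df = _satterthwaite_df(sigma_b2, sigma_e2, ns, means, sses, var_mu)
        df = float(np.clip(df, 1.0, n_tot - 1.0))
    f = mu**2 / var_mu
    p = float(stats.f.sf(f, 1, df))
    return MixedModelResult(float(mu), math.sqrt(var_mu), float(f), float(df),
                            p, float(sigma_b2), float(sigma_e2), boundary)


def _satterthwaite_df(sb2, se2, ns, means, sses, var_mu) -> float:
    """Delta-method Satterthwaite df: 2 g^2 / (grad' V grad) with V the
    inverse REML information in (sigma_b^2, sigma_e^2)."""
    denom = se2 + ns * sb2
    ds = (ns / denom**2)
    grad = var_mu**2 * np.array([(ns * ds).sum(), ds.sum()])
    h = np.empty((2, 2))
    theta = np.array([sb2, se2])
    steps = 1e-4 * np.maximum(np.abs(theta), 1e-8 * se2)
    f0 = _neg2_reml(theta, ns, means, sses)

    def _f(t):
        t = np.maximum(t, [0.0, 1e-12 * se2])
        return _neg2_reml(t, ns, means, sses)

    for i in range(2):
        for j in range(i, 2):
            ei = np.eye(2)[i] * steps[i]
            ej = np.eye(2)[j] * steps[j]
            if i == j:
                h[i, i] = (_f(theta + ei) - 2 * f0 + _f(theta - ei)) / steps[i] ** 2
            else:
                h[i, j] = h[j, i] = (
                    _f(theta + ei + ej) - _f(theta + ei - ej)
                    - _f(theta - ei + ej) + _f(theta - ei - ej)
                ) / (4 * steps[i] * steps[j])
    try:
        cov = np.linalg.inv(0.5 * h)
    except np.linalg.LinAlgError:
        return len(ns) - 1.0
    var_g = float(grad @ cov @ grad)
    if var_g <= 0:
        return len(ns) - 1.0
    return 2.0 * var_mu**2 / var_g


def fit_cycle_mixed_model(
    subject_cycle_values: list[np.ndarray],
    alpha: float = 0.05,
    freqs: np.ndarray | None = None,
) -> SignificanceMask:
    """Per-tile mixed-model mask over per-cycle z values.

    Parameters
    ----------
    subject_cycle_values : list of arrays
        One array per subject, shaped (n_cycles, n_freqs, n_bins) — the
        ``cycle_values`` of each subject's :class:`CycleNormalizedMap`.
    alpha : float
        Per-tile significance level.

    For each (frequency, bin) tile, fits z ~ intercept + (1 | subject) by
    REML over per-cycle values and tests the intercept against zero (a
    departure from the whole-walk average) with a Satterthwaite-df F-test.
    """
    if len(subject_cycle_values) < 2:
        raise ValueError("need at least two subjects")
    shapes = {a.shape[1:] for a in subject_cycle_values}
    if len(shapes) != 1:
        raise ValueError("subjects are on different freq/bin grids")
    n_f, n_b = shapes.pop()
    p = np.empty((n_f, n_b))
    est = np.empty((n_f, n_b))
    fst = np.empty((n_f, n_b))
    dfs = np.empty((n_f, n_b))
    for fi in range(n_f):
        for bi in range(n_b):
            r = fit_random_intercept([a[:, fi, bi] for a in subject_cycle_values])
            p[fi, bi] = r.p
            est[fi, bi] = r.estimate
            fst[fi, bi] = r.fstat
            dfs[fi, bi] = r.df_den
    if freqs is None:
        freqs = np.arange(n_f, dtype=float)
    return SignificanceMask(np.asarray(freqs, dtype=float), p < alpha, p, est,
                            fst, dfs, alpha)
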