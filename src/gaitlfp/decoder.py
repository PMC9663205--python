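"""Left- vs right-toe-off decoding from band-power (or coherence) features.

The decoding pipeline mirrors an ensemble feature-selection + classification
scheme suited to on-device linear classifiers: instantaneous power (or
magnitude-squared coherence) at every toe-off event is extracted in all
contiguous frequency bands on an elementary grid spanning 2.5-50 Hz (59
elementary bins -> 1770 candidate band features by default); features are
standardized with training-partition statistics; a random forest — with the
number of trees and the per-split feature count tuned by stratified 10-fold
cross-validation — ranks the features by out-of-bag permutation importance;
the top 10 feed a linear discriminant classifier evaluated on a held-out
25% split (accuracy and ROC AUC).  Significance comes from a label
permutation null in which the *entire* pipeline (split, standardization,
selection, training) is re-run per permutation, avoiding selection bias.

Everything is deterministic under the seed passed to each entry point.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from ._importance import oob_permutation_importance
from .band_stats import FrequencyBand, decoder_grid_edges, event_bin_powers
from .gait_events import GaitEvent
from .spectral import TimeFrequencyMap

TOE_OFF_KINDS = ("LTO", "RTO")
DEFAULT_TUNING_GRID = {
    "n_trees": (100, 300, 500, 1000),
    "features_per_split": ("sqrt", "third", "tenth"),
}
N_SELECTED = 10


@dataclass
class FeatureMatrix:
    """Toe-off occurrences x candidate-band features."""

    X: np.ndarray  # (n_events, n_features)
    y: np.ndarray  # 0 = LTO, 1 = RTO
    bands: list[FrequencyBand]
    feature_type: str = "power"  # power | coherence
    column_mean: np.ndarray | None = None  # training-partition statistics
    column_sd: np.ndarray | None = None

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


@dataclass
class DecoderReport:
    selected_bands: list[FrequencyBand]
    rf_hyperparams: tuple[int, str]
    accuracy: float
    auc: float
    permutation_p: float | None
    n_perms: int
    split_seed: int
    feature_type: str = "power"
    provenance: dict = field(default_factory=dict)


@dataclass
class PermutationNull:
    n_perms: int
    permuted_accuracies: np.ndarray
    observed_accuracy: float
    p: float

    @property
    def significant(self) -> bool:
        return self.p < 0.05


def _resolve_max_features(spec: str | int, p: int) -> int:
    if isinstance(spec, (int, np.integer)):
        return max(int(spec), 1)
    return max({"sqrt": round(math.sqrt(p)),
                "third": p // 3,
                "tenth": p // 10}[spec], 1)


def build_features(
    tfmap: TimeFrequencyMap,
    toe_off_events: list[GaitEvent],
    edges: np.ndarray | None = None,
    feature_type: str = "power",
    log_power: bool = True,
) -> FeatureMatrix:
    """One row per toe-off event, one column per enumerated contiguous band.

    ``edges`` defaults to the 59-bin 2.5-50 Hz decoder grid (1770 bands).
    Band values are means of the constituent elementary-bin values at the
    frame nearest the event, computed by cumulative sums.  Power features
    are taken on a log scale (dB-like) before band averaging — power is
    heavily right-skewed and the downstream linear discriminant assumes
    roughly Gaussian features; coherence features stay on their natural
    [0, 1] scale.
    """
    if edges is None:
        edges = decoder_grid_edges()
    toe_offs = [e for e in toe_off_events if e.kind in TOE_OFF_KINDS]
    n_per = {k: sum(e.kind == k for e in toe_offs) for k in TOE_OFF_KINDS}
    if min(n_per.values()) < 2:
        raise ValueError(f"need >= 2 events per toe-off class, got {n_per}")
    P, kinds, _ = event_bin_powers(tfmap, toe_offs, edges)
    if feature_type == "power" and log_power:
        P = np.log10(P + 1e-300)
    n_bins = len(edges) - 1
    csum = np.concatenate([np.zeros((P.shape[0], 1)), np.cumsum(P, axis=1)], axis=1)
    cols, bands = [], []
    for i in range(n_bins):
        for j in range(i + 1, n_bins + 1):
            cols.append((csum[:, j] - csum[:, i]) / (j - i))
            bands.append(FrequencyBand(float(edges[i]), float(edges[j])))
    X = np.column_stack(cols)
    y = (kinds == "RTO").astype(int)
    return FeatureMatrix(X, y, bands, feature_type=feature_type)


def standardize(features: FeatureMatrix, train_idx: np.ndarray) -> FeatureMatrix:
    """Standardize columns to mean 0 / SD 1 using *training rows only*.

    The training statistics are stored and applied to every row, so held-out
    rows see no information from their own distribution (no leakage).
    Columns constant on the training partition are dropped with a warning.
    """
    mu = features.X[train_idx].mean(axis=0)
    sd = features.X[train_idx].std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropped {int((~keep).sum())} constant feature column(s)",
                      stacklevel=2)
    Xs = (features.X[:, keep] - mu[keep]) / sd[keep]
    return FeatureMatrix(
        Xs, features.y, [b for b, k in zip(features.bands, keep) if k],
        feature_type=features.feature_type,
        column_mean=mu[keep], column_sd=sd[keep],
    )


def tune_rf(
    X: np.ndarray,
    y: np.ndarray,
    candidates: dict | None = None,
    n_folds: int = 10,
    seed: int = 0,
) -> tuple[int, str]:
    """Pick (n_trees, features_per_split) by stratified k-fold CV accuracy.

    Ties are broken toward the smallest candidate pair in the declared
    order.  The fold count is reduced with a warning when a class has fewer
    rows than folds.
    """
    candidates = candidates or DEFAULT_TUNING_GRID
    min_class = int(np.bincount(y).min())
    if min_class < n_folds:
        warnings.warn(f"reducing CV folds from {n_folds} to {max(min_class, 2)} "
                      "(too few rows per class to stratify)", stacklevel=2)
        n_folds = max(min_class, 2)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    best = None
    for nt in candidates["n_trees"]:
        for fps in candidates["features_per_split"]:
            accs = []
            for k, (tr, te) in enumerate(splits):
                rf = RandomForestClassifier(
                    n_estimators=nt,
                    max_features=_resolve_max_features(fps, X.shape[1]),
                    random_state=seed + 1000 + k,
                    n_jobs=1,
                )
                rf.fit(X[tr], y[tr])
                accs.append(accuracy_score(y[te], rf.predict(X[te])))
            mean_acc = float(np.mean(accs))
            if best is None or mean_acc > best[0] + 1e-12:
                best = (mean_acc, nt, fps)
    return best[1], best[2]


def select_features(
    X: np.ndarray,
    y: np.ndarray,
    bands: list[FrequencyBand],
    rf_hyperparams: tuple[int, str],
    seed: int = 0,
    n_selected: int = N_SELECTED,
) -> tuple[np.ndarray, np.ndarray]:
    """Rank features by OOB permutation importance; return top indices.

    Ties are broken toward the lower band edge, then the narrower band.
    Returns ``(indices, importances)``; with fewer than ``n_selected``
    features available, all are returned with a warning.
    """
    nt, fps = rf_hyperparams
    rf = RandomForestClassifier(
        n_estimators=nt, max_features=_resolve_max_features(fps, X.shape[1]),
        random_state=seed, n_jobs=1,
    )
    rf.fit(X, y)
    imp = oob_permutation_importance(rf, X, y, seed=seed % (2**31))
    if len(bands) < n_selected:
        warnings.warn(f"only {len(bands)} features available; returning all",
                      stacklevel=2)
        n_selected = len(bands)
    los = np.array([b.lo for b in bands])
    widths = np.array([b.width for b in bands])
    order = np.lexsort((widths, los, -imp))
    return order[:n_selected], imp


def train_eval_lda(
    X_train: np.ndarray, y_train: np.ndarray,
    X_test: np.ndarray, y_test: np.ndarray,
) -> tuple[float, float]:
    """Fit an LDA classifier; return held-out (accuracy, ROC AUC)."""
    lda = LinearDiscriminantAnalysis()
    lda.fit(X_train, y_train)
    acc = accuracy_score(y_test, lda.predict(X_test))
    auc = roc_auc_score(y_test, lda.decision_function(X_test))
    return float(acc), float(auc)


def _run_split_pipeline(
    features: FeatureMatrix,
    y: np.ndarray,
    rf_hyperparams: tuple[int, str],
    split_seed: int,
    test_size: float = 0.25,
    n_selected: int = N_SELECTED,
) -> tuple[float, float, np.ndarray]:
    """One stratified 75/25 split: standardize, select, train, evaluate.

    Everything that learns from data — column statistics, the forest, the
    importance ranking, the discriminant — sees training rows only.
    """
    idx = np.arange(features.X.shape[0])
    tr, te = train_test_split(idx, test_size=test_size, stratify=y,
                              random_state=split_seed)
    std = standardize(FeatureMatrix(features.X, y, features.bands,
                                    features.feature_type), tr)
    sel, _ = select_features(std.X[tr], y[tr], std.bands, rf_hyperparams,
                             seed=split_seed, n_selected=n_selected)
    acc, auc = train_eval_lda(std.X[np.ix_(tr, sel)], y[tr],
                              std.X[np.ix_(te, sel)], y[te])
    return acc, auc, sel


def permutation_significance(
    features: FeatureMatrix,
    rf_hyperparams: tuple[int, str],
    observed_accuracy: float,
    n_perms: int = 1000,
    seed: int = 0,
    test_size: float = 0.25,
    n_selected: int = N_SELECTED,
) -> PermutationNull:
    """Full-pipeline label-permutation null for the decoder.

    Labels are permuted *before* standardization/selection/training and the
    whole split pipeline is re-run with a fresh stratified split per
    permutation; ``p = (1 + #{permuted >= observed}) / (n_perms + 1)``.
    """
    if n_perms < 20:
        raise ValueError("n_perms < 20 gives a p-value floor above 0.05")
    rng = np.random.default_rng(seed)
    accs = np.empty(n_perms)
    for i in range(n_perms):
        y_perm = rng.permutation(features.y)
        split_seed = int(rng.integers(0, 2**31 - 1))
        accs[i], _, _ = _run_split_pipeline(features, y_perm, rf_hyperparams,
                                            split_seed, test_size, n_selected)
    p = (1.0 + np.sum(accs >= observed_accuracy - 1e-12)) / (n_perms + 1.0)
    return PermutationNull(n_perms, accs, observed_accuracy, float(p))


def decode_toe_offs(
    tfmap: TimeFrequencyMap,
    toe_off_events: list[GaitEvent],
    edges: np.ndarray | None = None,
    candidates: dict | None = None,
    n_perms: int = 1000,
    seed: int = 0,
    feature_type: str = "power",
    provenance: dict | None = None,
) -> DecoderReport:
    """End-to-end decoder for one subject/hemisphere/contact.

    Builds the candidate-band features, tunes the forest on the training
    partition, selects the top-10 bands by OOB permutation importance,
    evaluates LDA on the held-out 25%, and (if ``n_perms > 0``) attaches the
    full-pipeline permutation p-value.
    """
    ss = np.random.SeedSequence(seed)
    s_tune, s_split, s_perm = (int(c.generate_state(1)[0] % (2**31))
                               for c in ss.spawn(3))
    features = build_features(tfmap, toe_off_events, edges, feature_type)
    idx = np.arange(features.X.shape[0])
    tr, _ = train_test_split(idx, test_size=0.25, stratify=features.y,
                             random_state=s_split)
    std_tr = standardize(features, tr)
    hyper = tune_rf(std_tr.X[tr], features.y[tr], candidates, seed=s_tune)
    acc, auc, sel = _run_split_pipeline(features, features.y, hyper, s_split)
    perm_p = None
    if n_perms:
        perm_p = permutation_significance(features, hyper, acc, n_perms,
                                          seed=s_perm).p
    std_all = standardize(features, tr)
    return DecoderReport(
        selected_bands=[std_all.bands[i] for i in sel],
        rf_hyperparams=hyper,
        accuracy=acc,
        auc=auc,
        permutation_p=perm_p,
        n_perms=n_perms,
        split_seed=s_split,
        feature_type=feature_type,
        provenance=dict(provenance or {}),
    )


def coherence_variant(
    coherence_map: TimeFrequencyMap,
    toe_off_events: list[GaitEvent],
    **kwargs,
) -> DecoderReport:
    """Identical pipeline with STN-cortex coherence features."""
    if coherence_map.kind != "coherence":
        raise ValueError("coherence_variant expects a coherence map")
    prov = dict(kwargs.pop("provenance", {}) or {})
    prov.setdefault("pair", coherence_map.label)
    return decode_toe_offs(coherence_map, toe_off_events,
                           feature_type="coherence", provenance=prov, **kwargs)
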