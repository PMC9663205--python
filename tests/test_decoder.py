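import numpy as np
import pytest
from sklearn.model_selection import train_test_split

from gaitlfp.band_stats import FrequencyBand
from gaitlfp.decoder import (FeatureMatrix, build_features, coherence_variant,
                             decode_toe_offs, permutation_significance,
                             select_features, standardize, train_eval_lda,
                             tune_rf, _run_split_pipeline)
from gaitlfp.gait_events import GaitEvent
from gaitlfp.spectral import TimeFrequencyMap


def _noise_map(rng, n_freqs=60, n_times=600, hop=0.1):
    times = np.arange(n_times) * hop
    freqs = np.linspace(2.0, 50.0, n_freqs)
    return TimeFrequencyMap(freqs, times,
                            rng.exponential(1.0, (n_freqs, n_times)),
                            kind="stft_power")


def _toe_offs(n_per=40, start=2.0, half=0.55):
    events = []
    t = start
    for _ in range(n_per):
        events.append(GaitEvent(t, "RTO"))
        events.append(GaitEvent(t + half, "LTO"))
        t += 1.1
    return events


def _noise_features(rng, n=80, p=120):
    bands = [FrequencyBand(float(i), float(i + 1)) for i in range(p)]
    return FeatureMatrix(rng.standard_normal((n, p)),
                         rng.permutation(np.repeat([0, 1], n // 2)), bands)


class TestBuildFeatures:
    def test_default_grid_gives_1770_columns(self, rng):
        m = _noise_map(rng)
        feats = build_features(m, _toe_offs())
        assert feats.n_features == 1770
        assert feats.X.shape[0] == 80

    def test_single_bin_single_column(self, rng):
        m = _noise_map(rng)
        feats = build_features(m, _toe_offs(), edges=np.array([5.0, 10.0]))
        assert feats.n_features == 1

    def test_column_count_matches_brute_force_for_ten_bins(self, rng):
        m = _noise_map(rng)
        feats = build_features(m, _toe_offs(), edges=np.linspace(2.5, 50, 11))
        assert feats.n_features == 10 * 11 // 2 == 55

    def test_empty_class_rejected(self, rng):
        m = _noise_map(rng)
        only_rto = [e for e in _toe_offs() if e.kind == "RTO"]
        with pytest.raises(ValueError, match="class"):
            build_features(m, only_rto)


class TestStandardize:
    def test_training_columns_mean0_sd1(self, rng):
        feats = _noise_features(rng)
        tr = np.arange(0, 60)
        std = standardize(feats, tr)
        np.testing.assert_allclose(std.X[tr].mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(std.X[tr].std(axis=0), 1.0, atol=1e-12)

    def test_affine_column_standardizes_identically(self, rng):
        feats = _noise_features(rng)
        feats2 = FeatureMatrix(3.0 * feats.X + 7.0, feats.y, feats.bands)
        tr = np.arange(0, 60)
        np.testing.assert_allclose(standardize(feats, tr).X,
                                   standardize(feats2, tr).X, atol=1e-9)

    def test_heldout_rows_keep_training_statistics(self, rng):
        # shifted held-out rows must NOT come out centered: their transform
        # uses training statistics only, so a shift stays visible
        feats = _noise_features(rng)
        feats.X[60:] += 5.0
        std = standardize(feats, np.arange(0, 60))
        assert std.X[60:].mean() > 3.0

    def test_constant_column_dropped_with_warning(self, rng):
        feats = _noise_features(rng)
        feats.X[:, 5] = 2.0
        with pytest.warns(UserWarning, match="constant"):
            std = standardize(feats, np.arange(0, 60))
        assert std.n_features == feats.n_features - 1


class TestTuneRF:
    def test_single_candidate_returned(self, rng):
        feats = _noise_features(rng, n=60, p=20)
        out = tune_rf(feats.X, feats.y,
                      {"n_trees": (50,), "features_per_split": ("sqrt",)},
                      seed=0)
        assert out == (50, "sqrt")

    def test_separable_data_ties_break_to_smallest_pair(self, rng):
        X = rng.standard_normal((60, 5))
        y = np.repeat([0, 1], 30)
        X[:, 0] = y * 10.0  # perfectly separable
        out = tune_rf(X, y, {"n_trees": (50, 100),
                             "features_per_split": ("sqrt", "third")}, seed=0)
        assert out == (50, "sqrt")

    def test_shuffled_labels_give_chance_cv(self, rng):
        from sklearn.ensemble import RandomForestClassifier
        from sklearn.model_selection import StratifiedKFold, cross_val_score
        feats = _noise_features(rng, n=100, p=30)
        skf = StratifiedKFold(5, shuffle=True, random_state=0)
        accs = cross_val_score(
            RandomForestClassifier(n_estimators=50, random_state=0),
            feats.X, feats.y, cv=skf)
        assert abs(accs.mean() - 0.5) < 1.96 * np.sqrt(0.25 / 100) + 0.05

    def test_small_classes_reduce_folds_with_warning(self, rng):
        feats = _noise_features(rng, n=12, p=10)
        with pytest.warns(UserWarning, match="folds"):
            tune_rf(feats.X, feats.y,
                    {"n_trees": (20,), "features_per_split": ("sqrt",)}, seed=0)


class TestSelectFeatures:
    def test_planted_feature_ranked_first(self, rng):
        feats = _noise_features(rng, n=120, p=60)
        feats.X[:, 17] = feats.y * 4.0 + rng.standard_normal(120) * 0.3
        sel, imp = select_features(feats.X, feats.y, feats.bands, (100, "sqrt"),
                                   seed=0)
        assert sel[0] == 17
        assert len(sel) == 10

    def test_duplicated_informative_feature_both_rank_high(self, rng):
        # collinearity robustness: a duplicated predictive column must not
        # cancel itself out of the ranking
        feats = _noise_features(rng, n=120, p=40)
        signal = feats.y * 3.0 + rng.standard_normal(120) * 0.5
        feats.X[:, 7] = signal
        feats.X[:, 23] = signal + rng.standard_normal(120) * 0.05
        sel, imp = select_features(feats.X, feats.y, feats.bands, (200, "sqrt"),
                                   seed=0)
        assert {7, 23} <= set(sel)

    def test_fewer_than_ten_features_all_returned(self, rng):
        feats = _noise_features(rng, n=40, p=5)
        with pytest.warns(UserWarning, match="available"):
            sel, _ = select_features(feats.X, feats.y, feats.bands,
                                     (50, "sqrt"), seed=0)
        assert len(sel) == 5

    def test_tie_break_prefers_low_then_narrow_bands(self):
        bands = [FrequencyBand(10.0, 20.0), FrequencyBand(5.0, 30.0),
                 FrequencyBand(5.0, 12.0)]
        # equal (zero) importances: order by lo then width
        X = np.ones((20, 3)) + np.random.default_rng(0).normal(0, 1e-9, (20, 3))
        y = np.repeat([0, 1], 10)
        sel, imp = select_features(X, y, bands, (10, "sqrt"), seed=0,
                                   n_selected=3)
        assert list(sel) == [2, 1, 0]


class TestLDA:
    def test_separable_classes_perfect(self, rng):
        X = np.vstack([rng.normal(-5, 0.3, (40, 3)), rng.normal(5, 0.3, (40, 3))])
        y = np.repeat([0, 1], 40)
        acc, auc = train_eval_lda(X[::2], y[::2], X[1::2], y[1::2])
        assert acc == 1.0 and auc == 1.0

    def test_identical_distributions_chance(self, rng):
        X = rng.standard_normal((400, 3))
        y = rng.permutation(np.repeat([0, 1], 200))
        acc, auc = train_eval_lda(X[:300], y[:300], X[300:], y[300:])
        assert abs(acc - 0.5) < 0.15
        assert abs(auc - 0.5) < 0.2


class TestPermutation:
    def test_p_floor_and_n_perms_validated(self, rng):
        feats = _noise_features(rng, n=40, p=20)
        with pytest.raises(ValueError, match="n_perms"):
            permutation_significance(feats, (20, "sqrt"), 0.9, n_perms=5)
        null = permutation_significance(feats, (20, "sqrt"),
                                        observed_accuracy=2.0, n_perms=24,
                                        seed=0)
        assert null.p >= 1.0 / 25

    def test_observed_below_median_gives_large_p(self, rng):
        feats = _noise_features(rng, n=40, p=20)
        null = permutation_significance(feats, (20, "sqrt"),
                                        observed_accuracy=0.0, n_perms=24,
                                        seed=0)
        assert null.p > 0.5


class TestNoLeakage:
    def test_leaky_selection_inflates_null_accuracy(self, rng):
        """On pure-noise data the honest pipeline stays at chance while a
        deliberately leaky variant (selection on all rows including test)
        is visibly inflated -- the guard that would catch a leak."""
        honest, leaky = [], []
        for seed in range(6):
            r = np.random.default_rng(seed)
            feats = _noise_features(r, n=80, p=200)
            idx = np.arange(80)
            tr, te = train_test_split(idx, test_size=0.25, stratify=feats.y,
                                      random_state=seed)
            acc, _, _ = _run_split_pipeline(feats, feats.y, (100, "sqrt"), seed)
            honest.append(acc)
            std_all = standardize(feats, idx)  # leak: stats from all rows
            sel, _ = select_features(std_all.X, feats.y, std_all.bands,
                                     (100, "sqrt"), seed=seed)  # leak: all rows
            lacc, _ = train_eval_lda(std_all.X[np.ix_(tr, sel)], feats.y[tr],
                                     std_all.X[np.ix_(te, sel)], feats.y[te])
            leaky.append(lacc)
        assert abs(np.mean(honest) - 0.5) < 0.12
        assert np.mean(leaky) > np.mean(honest) + 0.1


class TestDecodeEndToEnd:
    def _planted(self, seed=0):
        import gaitlfp as gl
        from gaitlfp.scenarios import planted_subject
        from gaitlfp.spectral import stft_spectrogram
        tl, neural, toe_offs = planted_subject(seed, n_cycles=60)
        return stft_spectrogram(neural["stn_l"]), toe_offs

    def test_report_deterministic_under_seed(self):
        tfmap, toe_offs = self._planted(3)
        kw = dict(edges=np.linspace(2.5, 50, 11),
                  candidates={"n_trees": (50,), "features_per_split": ("sqrt",)},
                  n_perms=30, seed=11)
        a = decode_toe_offs(tfmap, toe_offs, **kw)
        b = decode_toe_offs(tfmap, toe_offs, **kw)
        assert a.accuracy == b.accuracy
        assert a.auc == b.auc
        assert a.permutation_p == b.permutation_p
        assert a.selected_bands == b.selected_bands

    def test_planted_signal_beats_chance(self):
        tfmap, toe_offs = self._planted(5)
        rep = decode_toe_offs(
            tfmap, toe_offs, edges=np.linspace(2.5, 50, 20),
            candidates={"n_trees": (100,), "features_per_split": ("sqrt",)},
            n_perms=49, seed=2)
        assert rep.accuracy > 0.65
        assert rep.permutation_p < 0.05

    def test_coherence_variant_carries_provenance(self, rng):
        m = _noise_map(rng)
        coh = TimeFrequencyMap(m.freqs, m.times,
                               rng.uniform(0, 1, m.values.shape),
                               kind="coherence", label="stn-m1")
        rep = coherence_variant(coh, _toe_offs(),
                                edges=np.linspace(2.5, 50, 8),
                                candidates={"n_trees": (30,),
                                            "features_per_split": ("sqrt",)},
                                n_perms=0, seed=0)
        assert rep.feature_type == "coherence"
        assert rep.provenance["pair"] == "stn-m1"
        with pytest.raises(ValueError, match="coherence"):
            coherence_variant(m, _toe_offs())
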