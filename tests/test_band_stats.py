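import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gaitlfp.band_stats import (FrequencyBand, decoder_grid_edges,
                                distribution_diagnostics, enumerate_bands,
                                event_bin_powers, extract_event_power,
                                fit_cycle_mixed_model, fit_random_intercept,
                                kruskal_wallis_h, scan_bands, scan_grid_edges)
from gaitlfp.gait_events import GaitEvent
from gaitlfp.spectral import TimeFrequencyMap

# ---------------------------------------------------------------------------
# independent brute-force oracle for the Kruskal-Wallis H statistic
# ---------------------------------------------------------------------------

def _brute_force_h(groups):
    """Tie-corrected Kruskal-Wallis H from first principles: average ranks
    by explicit pairwise comparison counting, then the classic formula."""
    values = np.concatenate(groups)
    n = values.size
    ranks = np.empty(n)
    for i, v in enumerate(values):
        smaller = np.sum(values < v)
        equal = np.sum(values == v)
        ranks[i] = smaller + (equal + 1) / 2.0
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(values, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    return h / tie


class TestEnumeration:
    def test_single_bin(self):
        assert len(enumerate_bands(np.array([0.0, 1.0]))) == 1

    def test_five_bins_fifteen_bands(self):
        assert len(enumerate_bands(np.arange(6.0))) == 15

    def test_decoder_grid_count_matches_brute_force(self):
        edges = decoder_grid_edges()  # 59 bins spanning 2.5-50 Hz
        bands = enumerate_bands(edges)
        brute = [(edges[i], edges[j]) for i in range(59)
                 for j in range(i + 1, 60)]
        assert len(bands) == len(brute) == 1770
        assert [(b.lo, b.hi) for b in bands] == sorted(brute)

    def test_scan_grid_default(self):
        assert len(enumerate_bands(scan_grid_edges())) == 50 * 51 // 2

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            enumerate_bands(np.array([1.0]))


def _flat_map(n_freqs=10, n_times=200, value=1.0, hop=0.1):
    times = np.arange(n_times) * hop
    return TimeFrequencyMap(np.arange(n_freqs, dtype=float) + 1.0, times,
                            np.full((n_freqs, n_times), value),
                            kind="stft_power")


class TestExtractEventPower:
    def test_constant_map_returns_constant(self):
        m = _flat_map(value=2.5)
        events = [GaitEvent(3.0, "LHS"), GaitEvent(7.0, "RTO")]
        df = extract_event_power(m, events, FrequencyBand(2.0, 5.0))
        assert np.allclose(df["power"], 2.5)

    def test_midpoint_tie_breaks_to_earlier_frame(self):
        m = _flat_map()
        m.values[:, 30] = 10.0  # frame at 3.00 s
        m.values[:, 31] = 20.0  # frame at 3.10 s
        df = extract_event_power(m, [GaitEvent(3.05, "LHS")],
                                 FrequencyBand(1.0, 10.0))
        assert df["power"].iloc[0] == 10.0

    def test_event_beyond_edge_dropped_with_warning(self):
        m = _flat_map(n_times=50)
        with pytest.warns(UserWarning, match="dropped"):
            df = extract_event_power(m, [GaitEvent(3.0, "LHS"),
                                         GaitEvent(40.0, "RTO")],
                                     FrequencyBand(1.0, 5.0))
        assert len(df) == 1

    def test_planted_burst_separates_event_kinds(self, rng):
        m = _flat_map(n_times=400)
        lhs_times = np.arange(2.0, 38.0, 4.0)
        rto_times = lhs_times + 1.0
        for t in lhs_times:
            m.values[2:5, int(t * 10)] += 5.0
        events = [GaitEvent(t, "LHS") for t in lhs_times] + \
                 [GaitEvent(t, "RTO") for t in rto_times]
        df = extract_event_power(m, events, FrequencyBand(3.0, 5.0))
        assert df[df.kind == "LHS"]["power"].mean() > \
               df[df.kind == "RTO"]["power"].mean()


def _grouped_samples(rng, shift=None, n_per=30, n_bins=4):
    kinds = np.repeat(["LHS", "RTO", "RHS", "LTO"], n_per)
    P = rng.standard_normal((kinds.size, n_bins))
    if shift is not None:
        P[kinds == "LHS", shift[0]] += shift[1]
    return P, kinds


class TestScan:
    edges = np.arange(0.0, 5.0)  # 4 elementary bins -> 10 bands

    def test_h_matches_brute_force_oracle(self, rng):
        for _ in range(30):
            sizes = rng.integers(3, 8, size=4)
            groups = [np.round(rng.standard_normal(s), 1) for s in sizes]
            h, _ = kruskal_wallis_h(groups)
            assert h == pytest.approx(_brute_force_h(groups), abs=1e-10)

    def test_identical_constant_samples_not_significant(self):
        P = np.ones((40, 4))
        kinds = np.repeat(["LHS", "RTO", "RHS", "LTO"], 10)
        out = scan_bands(P, kinds, self.edges)
        assert np.allclose(out["kw_p"], 1.0)
        assert not out["significant"].any()

    def test_planted_separation_detected(self, rng):
        P, kinds = _grouped_samples(rng, shift=(1, 5.0))
        out = scan_bands(P, kinds, self.edges)
        row = out[(out.lo == 1.0) & (out.hi == 2.0)].iloc[0]
        assert row["significant"]
        assert row["kw_p"] < 1e-6

    def test_null_omnibus_rate_calibrated(self, rng):
        hits = 0
        n_rep = 300
        for _ in range(n_rep):
            P, kinds = _grouped_samples(rng, n_bins=1)
            out = scan_bands(P, kinds, np.array([0.0, 1.0]))
            hits += int(out["kw_p"].iloc[0] < 0.05)
        rate = hits / n_rep
        assert abs(rate - 0.05) < 2.6 * np.sqrt(0.05 * 0.95 / n_rep)

    def test_small_class_skipped_with_warning(self, rng):
        P = rng.standard_normal((5, 4))
        kinds = np.array(["LHS", "LHS", "RTO", "RHS", "LTO"])
        with pytest.warns(UserWarning, match="<2"):
            out = scan_bands(P, kinds, self.edges)
        assert out.empty

    def test_raw_tukey_posthoc_variant_agrees_on_strong_effect(self, rng):
        P, kinds = _grouped_samples(rng, shift=(0, 5.0))
        a = scan_bands(P, kinds, self.edges, posthoc="rank-nemenyi")
        b = scan_bands(P, kinds, self.edges, posthoc="tukey-raw")
        assert a[(a.lo == 0) & (a.hi == 1)]["significant"].iloc[0]
        assert b[(b.lo == 0) & (b.hi == 1)]["significant"].iloc[0]

    def test_multiplicity_reported(self, rng):
        P, kinds = _grouped_samples(rng)
        out = scan_bands(P, kinds, self.edges)
        assert out.attrs["n_bands_tested"] == len(out) == 10


class TestDiagnostics:
    def test_gaussian_vs_exponential_shapiro(self, rng):
        gauss = pd.DataFrame({"kind": "LHS", "power": rng.standard_normal(500)})
        expo = pd.DataFrame({"kind": "RTO", "power": rng.exponential(1, 500)})
        out = distribution_diagnostics(pd.concat([gauss, expo]))
        p_gauss = out[(out["test"] == "shapiro") & (out["class"] == "LHS")]["p"].iloc[0]
        p_expo = out[(out["test"] == "shapiro") & (out["class"] == "RTO")]["p"].iloc[0]
        assert p_expo < 1e-10
        assert p_gauss > 0.001

    def test_equal_variances_levene_nonsignificant(self, rng):
        df = pd.DataFrame({
            "kind": np.repeat(["LHS", "RTO", "RHS", "LTO"], 200),
            "power": np.concatenate([rng.standard_normal(200) + mu
                                     for mu in (0, 1, 2, 3)]),
        })
        out = distribution_diagnostics(df)
        assert out[out["test"] == "levene"]["p"].iloc[0] > 0.01


class TestMixedModel:
    def test_all_zero_values_empty_mask(self):
        subs = [np.zeros((10, 2, 3)) for _ in range(3)]
        mask = fit_cycle_mixed_model(subs)
        assert not mask.mask.any()

    def test_balanced_positive_variance_df_is_subjects_minus_one(self, rng):
        ys = [rng.normal(offset, 1.0, 40)
              for offset in (0.0, 0.8, 1.6)]
        r = fit_random_intercept(ys)
        assert r.df_den == pytest.approx(2.0, abs=0.05)

    def test_boundary_reduces_to_classical_one_sample_f(self, rng):
        ys = [rng.normal(0.3, 1.0, 25) for _ in range(4)]
        r = fit_random_intercept(ys)
        if r.boundary:
            y_all = np.concatenate(ys)
            n = y_all.size
            f_classic = n * y_all.mean() ** 2 / y_all.var(ddof=1)
            assert r.df_den == n - 1
            assert r.fstat == pytest.approx(f_classic, rel=1e-6)

    def test_matches_lmerTest_on_unbalanced_data(self, tmp_path):
        rng = np.random.default_rng(42)
        ys = [rng.normal(0.4, 1.0, n) + off
              for n, off in zip((8, 15, 23, 11), (0.2, -0.3, 0.5, 0.0))]
        r = fit_random_intercept(ys)
        rows = [f"{s},{float(v)!r}" for s, y in enumerate(ys) for v in y]
        csv = tmp_path / "mm.csv"
        csv.write_text("subj,y\n" + "\n".join(rows))
        script = textwrap.dedent(f"""
            suppressMessages(library(lmerTest))
            d <- read.csv("{csv}")
            d$subj <- factor(d$subj)
            m <- lmer(y ~ 1 + (1|subj), data=d, REML=TRUE)
            co <- coef(summary(m))
            cat(co[1,"Estimate"], co[1,"Std. Error"], co[1,"df"],
                co[1,"Pr(>|t|)"], sep="\\n")
        """)
        out = subprocess.run(["Rscript", "-"], input=script, text=True,
                             capture_output=True, check=True)
        est, se, df, p = map(float, out.stdout.strip().splitlines())
        assert r.estimate == pytest.approx(est, abs=1e-6)
        assert r.se == pytest.approx(se, abs=1e-6)
        assert r.df_den == pytest.approx(df, abs=1e-3)
        assert r.p == pytest.approx(p, abs=1e-6)

    def test_planted_tile_detected_with_high_power(self, rng):
        detected = 0
        for _ in range(60):
            subs = []
            for _ in range(3):
                a = rng.standard_normal((40, 1, 2))
                a[:, 0, 1] += 1.0  # 1 z-unit effect in tile (0, 1)
                subs.append(a)
            mask = fit_cycle_mixed_model(subs)
            detected += int(mask.mask[0, 1])
        assert detected >= 0.95 * 60

    def test_null_tile_rate_calibrated(self, rng):
        n_tiles = 400
        subs = [rng.standard_normal((40, 1, n_tiles)) for _ in range(3)]
        mask = fit_cycle_mixed_model(subs)
        rate = mask.mask.mean()
        assert abs(rate - 0.05) < 2.6 * np.sqrt(0.05 * 0.95 / n_tiles)

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValueError, match="two subjects"):
            fit_random_intercept([rng.standard_normal(10)])


class TestEventBinPowers:
    def test_band_average_equals_direct_mean(self, rng):
        m = _flat_map(n_freqs=10, n_times=300)
        m.values[:] = rng.uniform(1, 2, m.values.shape)
        events = [GaitEvent(t, "LHS") for t in (3.0, 7.0, 11.0)]
        edges = np.array([1.0, 3.0, 5.0, 8.0])
        P, kinds, _ = event_bin_powers(m, events, edges)
        direct = extract_event_power(m, events, FrequencyBand(1.0, 3.0))
        # bin 0 covers rows with 1 <= f < 3
        rows = (m.freqs >= 1) & (m.freqs < 3)
        idx = [np.abs(m.times - t).argmin() for t in (3.0, 7.0, 11.0)]
        np.testing.assert_allclose(P[:, 0], m.values[rows][:, idx].mean(axis=0))
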