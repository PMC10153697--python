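"""Fourier scoring, AR1 backgrounds, ratio FDR, peak times and clustering."""

import numpy as np
import pandas as pd
import pytest

from dielarray import synth
from dielarray.containers import ExpressionMatrix
from dielarray.design import make_design
from dielarray.diel import (AR1Model, FourierDielModel, cluster_diel_profiles,
                            fdr_fourier, fit_ar1, fourier_score, peak_time,
                            ratio_fdr, replicate_average, simulate_background,
                            standardize_series, trough_time)

T8 = np.arange(0.0, 24.0, 3.0)          # 8-point uniform grid over one cycle


def brute_force_score(x, t, period=24.0):
    """Independent oracle: |sum x_i exp(-i w t_i)| via complex arithmetic."""
    z = np.sum(np.asarray(x) * np.exp(-2j * np.pi * np.asarray(t) / period))
    return abs(z)


class TestStandardize:
    def test_three_point_example(self):
        assert np.allclose(standardize_series([1, 2, 3]), [-1, 0, 1])

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            standardize_series([5.0, 5.0, 5.0])

    def test_output_mean_zero_unit_sd(self, rng):
        x = standardize_series(rng.normal(size=25))
        assert abs(x.mean()) < 1e-12
        assert x.std(ddof=1) == pytest.approx(1.0, abs=1e-12)


class TestFourierScore:
    def test_pure_diel_cosine_scores_sqrt_28(self):
        x = standardize_series(np.cos(2 * np.pi * T8 / 24.0))
        assert fourier_score(x, T8) == pytest.approx(np.sqrt(28), abs=1e-9)

    def test_half_period_cosine_scores_zero(self):
        x = standardize_series(np.cos(2 * np.pi * T8 / 12.0))
        assert fourier_score(x, T8) == pytest.approx(0.0, abs=1e-9)

    def test_matches_complex_exponential_oracle(self, rng):
        for _ in range(20):
            x = rng.normal(size=10)
            t = np.arange(10) * 3.0
            assert fourier_score(x, t) == pytest.approx(
                brute_force_score(x, t), abs=1e-10)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fourier_score([1.0, 2.0], [0.0, 3.0, 6.0])


class TestAR1:
    def test_alternating_series_phi(self):
        assert fit_ar1([1.0, -1.0, 1.0, -1.0]).phi == pytest.approx(-0.75)

    def test_white_noise_phi_near_zero(self):
        rng = np.random.default_rng(0)
        m = fit_ar1(rng.normal(size=5000))
        assert abs(m.phi) < 0.05

    def test_simulation_refit_recovers_phi(self):
        rng = np.random.default_rng(1)
        x = simulate_background(AR1Model(0.6, 1.0), 2000, rng)
        assert fit_ar1(x).phi == pytest.approx(0.6, abs=0.06)

    def test_stationary_start_variance(self):
        rng = np.random.default_rng(2)
        first = [simulate_background(AR1Model(0.8, 1.0), 5, rng)[0]
                 for _ in range(4000)]
        assert np.var(first) == pytest.approx(1 / (1 - 0.64), rel=0.1)


class TestRatioFDR:
    def test_counting_example(self):
        fdr = ratio_fdr([5.0, 1.0], [[1.0, 1.0], [1.0, 1.0]])
        assert fdr[0] == 0.0
        assert fdr[1] == 1.0

    def test_nonincreasing_in_score(self, rng):
        obs = rng.exponential(size=50)
        bg = rng.exponential(size=(20, 50))
        fdr = ratio_fdr(obs, bg)
        order = np.argsort(obs)
        assert (np.diff(fdr[order]) <= 1e-12).all()

    def test_scale_invariance_of_classification(self, rng):
        obs = rng.exponential(size=30)
        bg = rng.exponential(size=(10, 30))
        assert np.allclose(ratio_fdr(obs, bg), ratio_fdr(obs * 7.3, bg * 7.3))


class TestFdrFourier:
    def test_strong_sinusoids_called_diel(self, design10):
        truths = ([synth.GeneTruth(f"d{i}", "A1", "pw", True, (i * 6) % 24,
                                   2.0, 8.0, 0.2) for i in range(10)]
                  + [synth.GeneTruth(f"n{i}", "A1", "pw", False, None, 0.0,
                                     8.0, 0.2) for i in range(40)])
        expr = synth.simulate_expression(design10, truths, 0.4, seed=3)
        res = fdr_fourier(expr, n_background=200, seed=4)
        assert res.loc[[f"d{i}" for i in range(10)], "is_diel"].all()

    def test_deterministic_given_seed(self, design10):
        truths = synth.make_truths(40, seed=5)
        expr = synth.simulate_expression(design10, truths, 0.5, seed=6)
        a = fdr_fourier(expr, n_background=50, seed=9)
        b = fdr_fourier(expr, n_background=50, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_few_backgrounds_warns(self, design10):
        truths = synth.make_truths(5, seed=5)
        expr = synth.simulate_expression(design10, truths, 0.5, seed=6)
        with pytest.warns(UserWarning, match="unstable"):
            fdr_fourier(expr, n_background=5, seed=0)


class TestPeakTimes:
    def _expr_row(self, design, values):
        return pd.Series(values, index=[d.sample_id for d in design])

    def test_noiseless_sinusoid_peaks_at_truth(self, design10):
        # peak at 18:00 = L12
        vals = [8 + np.cos(2 * np.pi * (d.clock_hour - 18.0) / 24.0)
                for d in design10]
        row = self._expr_row(design10, vals)
        assert peak_time(row, design10) == "L12"

    def test_replicate_mean_beats_single_higher_sample(self):
        design = make_design(3, 3, 2, 6, 12)      # L3 L6 L9, duplicates
        vals = {"L3.1": 0.0, "L3.2": 0.0, "L6.1": 3.0, "L6.2": 5.0,
                "L9.1": 4.5, "L9.2": 4.5}
        row = pd.Series([vals[d.sample_id] for d in design],
                        index=[d.sample_id for d in design])
        # mean L6 = 4.0 < 4.5 at L9
        assert peak_time(row, design) == "L9"

    def test_days_merge_on_clock_label(self, design10):
        vals = {d.sample_id: 0.0 for d in design10}
        for sid in vals:
            if sid.startswith("L6") or sid.startswith("2L6"):
                vals[sid] = 9.0
        row = pd.Series([vals[d.sample_id] for d in design10],
                        index=[d.sample_id for d in design10])
        assert peak_time(row, design10) == "L6"

    def test_trough_is_argmin(self, design10):
        vals = [8 - np.cos(2 * np.pi * (d.clock_hour - 18.0) / 24.0)
                for d in design10]
        row = self._expr_row(design10, vals)
        assert trough_time(row, design10) == "L12"


class TestClustering:
    def test_antiphased_groups_split_with_full_support(self):
        t = np.arange(0.0, 30.0, 3.0)
        sun = np.cos(2 * np.pi * t / 24.0)
        moon = -sun
        profiles = pd.DataFrame(
            [sun * (1 + 0.1 * i) for i in range(4)]
            + [moon * (1 + 0.1 * i) for i in range(4)],
            index=[f"s{i}" for i in range(4)] + [f"m{i}" for i in range(4)])
        assign, nodes = cluster_diel_profiles(profiles, n_boot=100, seed=0)
        groups = assign.groupby(assign).groups
        assert len(groups) == 2
        members = {frozenset(v) for v in groups.values()}
        assert members == {frozenset({"s0", "s1", "s2", "s3"}),
                           frozenset({"m0", "m1", "m2", "m3"})}

    def test_identical_profiles_one_cluster(self):
        base = np.sin(np.linspace(0, 6, 10))
        profiles = pd.DataFrame([base] * 5, index=[f"g{i}" for i in range(5)])
        assign, _ = cluster_diel_profiles(profiles, n_boot=50, seed=1)
        assert assign.dropna().nunique() == 1

    def test_supports_deterministic(self):
        rng = np.random.default_rng(3)
        profiles = pd.DataFrame(rng.normal(size=(6, 10)),
                                index=[f"g{i}" for i in range(6)])
        _, a = cluster_diel_profiles(profiles, n_boot=60, seed=4)
        _, b = cluster_diel_profiles(profiles, n_boot=60, seed=4)
        pd.testing.assert_frame_equal(a, b)


class TestModelResults:
    def test_summary_and_table_roundtrip(self, small_dataset):
        from dielarray.detect import detect_genes
        det = detect_genes(small_dataset["expr"], small_dataset["ercc"])
        model = FourierDielModel(small_dataset["expr"].sel_genes(det.detected))
        res = model.fit(n_background=100, seed=2, n_boot=50)
        frame = res.results_frame()
        for col in ("Fourier_score", "Fourier_FDR", "Diel", "Diel_cluster",
                    "peak", "trough"):
            assert col in frame.columns
        txt = res.summary()
        assert "diel genes" in txt
        assert str(res.n_diel) in txt
        assert (res.table.loc[res.diel_genes, "fdr"] < 0.25).all()

    def test_replicate_average_grid(self, small_dataset):
        avg, hours, reps = replicate_average(small_dataset["expr"])
        assert avg.shape[1] == 10
        assert np.allclose(np.diff(hours), 3.0)
        assert list(avg.columns)[:2] == ["L3", "L6"]
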