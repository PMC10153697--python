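"""Cross-site statistics: standardization, overlap, tests, pathways, shifts."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from dielarray.compare import (correlations, detection_overlap,
                               fisher_habitat_test, paired_unpaired_ttests,
                               pathway_correlations, pathway_matrix,
                               peak_shift_table, standardized_level,
                               welch_test)


def hand_welch(a, b):
    """Textbook Welch statistic and Satterthwaite df (independent oracle)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / (a.size - 1) + vb ** 2 / (b.size - 1))
    return t, df


def enumerate_fisher_p(table):
    """Exact two-sided p by full enumeration over fixed margins."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    probs = {}
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        probs[k] = (math.comb(r1, k) * math.comb(r2, c1 - k)
                    / math.comb(n, c1))
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))


class TestStandardizedLevel:
    def test_two_gene_hand_example(self):
        expr = pd.DataFrame({"s1": [2.0, 0.0], "s2": [2.0, 0.0]},
                            index=["A", "B"])
        lev = standardized_level(expr)
        assert lev["A"] == pytest.approx(1 / np.sqrt(2))
        assert lev["B"] == pytest.approx(-1 / np.sqrt(2))

    def test_gene_at_sample_mean_scores_zero(self):
        expr = pd.DataFrame({"s1": [1.0, 2.0, 3.0]}, index=["A", "B", "C"])
        assert standardized_level(expr)["B"] == 0.0

    def test_translation_invariance(self, rng):
        expr = pd.DataFrame(rng.normal(size=(10, 4)))
        shifted = expr + pd.Series([5.0, -2.0, 0.3, 9.0], index=expr.columns)
        pd.testing.assert_series_equal(standardized_level(expr),
                                       standardized_level(shifted))


class TestOverlap:
    def test_partition(self):
        both, only_a, only_b = detection_overlap(["g1", "g2", "g3"],
                                                 ["g2", "g3", "g4"])
        assert set(both) == {"g2", "g3"}
        assert set(only_a) == {"g1"}
        assert set(only_b) == {"g4"}

    def test_subset_and_empty(self):
        both, only_a, only_b = detection_overlap(["g1", "g2"], ["g1"])
        assert only_b.empty
        both, only_a, only_b = detection_overlap(["g1"], [])
        assert both.empty and set(only_a) == {"g1"}


class TestWelch:
    def test_identical_groups_null(self):
        t, df, p = welch_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_separated_groups_significant(self):
        _, _, p = welch_test([10, 11, 12], [1, 2, 3])
        assert p < 0.01

    def test_agrees_with_hand_formula(self, rng):
        for _ in range(100):
            a = rng.normal(size=rng.integers(3, 12))
            b = rng.normal(1.0, 2.0, size=rng.integers(3, 12))
            t, df, _ = welch_test(a, b)
            t2, df2 = hand_welch(a, b)
            assert t == pytest.approx(t2, abs=1e-8)
            assert df == pytest.approx(df2, abs=1e-8)


class TestOneSidedT:
    def test_paired_worked_example(self):
        t, p = paired_unpaired_ttests([2, 4, 6, 8], [1, 2, 3, 4], paired=True)
        assert t == pytest.approx(3.872983, abs=1e-5)
        assert p == pytest.approx(0.015232, abs=1e-5)

    def test_constant_differences_degenerate(self):
        with pytest.raises(ValueError):
            paired_unpaired_ttests([2, 3, 4, 5], [1, 2, 3, 4], paired=True)

    def test_equal_groups_one_sided_half(self):
        x = [1.0, 2.0, 3.0]
        t, p = paired_unpaired_ttests(x, x, paired=False)
        assert t == 0.0 and p == 0.5

    def test_unpaired_is_one_sided_welch(self, rng):
        a, b = rng.normal(size=6), rng.normal(size=8)
        t, p = paired_unpaired_ttests(a, b, paired=False)
        t2, _, p2 = welch_test(a, b, alternative="greater")
        assert (t, p) == (t2, p2)


class TestFisher:
    def test_cross_habitat_contingency_is_significant(self):
        _, p = fisher_habitat_test([[679, 81], [111, 649]])
        assert p < 0.001

    def test_symmetric_table_p_one(self):
        _, p = fisher_habitat_test([[2, 1], [1, 2]])
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_diagonal_table_enumeration(self):
        _, p = fisher_habitat_test([[5, 0], [0, 5]])
        assert p == pytest.approx(2 / 252, abs=1e-12)

    def test_matches_enumeration_oracle_on_small_tables(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            table = rng.integers(0, 8, size=(2, 2))
            _, p = fisher_habitat_test(table)
            assert p == pytest.approx(enumerate_fisher_p(table), abs=1e-10)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_habitat_test([[1, -1], [2, 3]])


class TestCorrelations:
    def test_perfect_line(self):
        x = np.arange(10.0)
        assert correlations(x, x, "pearson")[0] == pytest.approx(1.0)
        assert correlations(x, x, "spearman")[0] == pytest.approx(1.0)

    def test_reversed_spearman(self):
        x = np.arange(10.0)
        assert correlations(x, x[::-1], "spearman")[0] == pytest.approx(-1.0)

    def test_tied_ranks_match_scipy_oracle(self, rng):
        from scipy.stats import rankdata
        x = np.array([1.0, 2.0, 2.0, 4.0, 5.0, 6.0])
        y = rng.normal(size=6)
        rho, _ = correlations(x, y, "spearman")
        # Spearman = Pearson on mid-ranks
        rx, ry = rankdata(x), rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(expected, abs=1e-10)

    def test_pathway_correlations_respect_min_genes(self, rng):
        genes = [f"g{i}" for i in range(12)]
        a = pd.Series(rng.normal(size=12), index=genes)
        b = a + rng.normal(0, 0.1, size=12)
        pmap = pd.Series(["big"] * 8 + ["small"] * 4, index=genes)
        out = pathway_correlations(a, b, pmap, min_genes=5)
        assert list(out.index) == ["big"]
        assert out.loc["big", "rho"] > 0.8


class TestPathwayMatrix:
    def _column(self, medians_by_pathway, n_samples=6, detected_frac=1.0):
        genes, levels, pmap = [], [], {}
        rng = np.random.default_rng(0)
        for pw, med in medians_by_pathway.items():
            for k in range(3):
                g = f"{pw}_g{k}"
                genes.append(g)
                levels.append(np.full(n_samples, float(med)))
                pmap[g] = pw
        lv = pd.DataFrame(levels, index=genes,
                          columns=[f"s{j}" for j in range(n_samples)])
        n_det = max(1, int(round(detected_frac * n_samples)))
        det = pd.DataFrame(False, index=lv.index, columns=lv.columns)
        det.iloc[:, :n_det] = True
        return lv, det, pd.Series(pmap)

    def test_quantile_grid(self):
        col = self._column({"p1": 1, "p2": 5, "p3": 9})
        mat, _ = pathway_matrix({"siteA": col})
        assert mat["siteA"].to_dict() == {"p1": 0.0, "p2": 0.5, "p3": 1.0}

    def test_all_equal_medians_share_half(self):
        col = self._column({"p1": 4, "p2": 4, "p3": 4})
        mat, _ = pathway_matrix({"siteA": col})
        assert (mat["siteA"] == 0.5).all()

    def test_sparse_pathway_dropped(self):
        common = self._column({"p1": 1, "p2": 5, "p3": 9}, n_samples=10)
        lv, det, pmap = self._column({"rare": 7}, n_samples=10,
                                     detected_frac=0.3)
        lv2 = pd.concat([common[0], lv])
        det2 = pd.concat([common[1], det])
        pm2 = pd.concat([common[2], pmap])
        mat, _ = pathway_matrix({"siteA": (lv2, det2, pm2)})
        assert "rare" not in mat.index     # detected in 3 of 10 <= 1/3

    def test_monotone_transform_invariance(self):
        col_lin = self._column({"p1": 2, "p2": 10, "p3": 40})
        lv, det, pmap = col_lin
        col_log = (np.log1p(lv), det, pmap)
        a, _ = pathway_matrix({"c": col_lin})
        b, _ = pathway_matrix({"c": col_log})
        pd.testing.assert_frame_equal(a, b)


class TestPeakShift:
    def test_three_hour_shift(self):
        out = peak_shift_table(pd.Series({"g": "L9"}), pd.Series({"g": "L12"}))
        assert out.loc["g", "shift_h"] == 3.0
        assert out.loc["g", "category"] == "shifted <6 h"

    def test_antiphase_is_maximal(self):
        out = peak_shift_table(pd.Series({"g": "D6"}), pd.Series({"g": "L6"}))
        assert out.loc["g", "shift_h"] == 12.0
        assert out.loc["g", "category"] == "shifted >=6 h"

    def test_maintained_at_sunrise(self):
        out = peak_shift_table(pd.Series({"g": "D12"}), pd.Series({"g": "D12"}))
        assert out.loc["g", "shift_h"] == 0.0
        assert out.loc["g", "category"] == "maintained"

    def test_symmetric_and_bounded(self):
        labels = ["L3", "L6", "L9", "L12", "D3", "D6", "D9", "D12"]
        for a, b in itertools.product(labels, labels):
            ab = peak_shift_table(pd.Series({"g": a}), pd.Series({"g": b}))
            ba = peak_shift_table(pd.Series({"g": b}), pd.Series({"g": a}))
            assert ab.loc["g", "shift_h"] == ba.loc["g", "shift_h"] <= 12.0
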