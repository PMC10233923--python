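"""Metric battery and statistical comparison suite against brute-force oracles."""
from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from hmiol.evaluation import (
    BAND_THRESHOLDS,
    ComparisonTest,
    PredictionErrorSeries,
    cochran_q_bands,
    compute_pe,
    cumulative_curve,
    evaluate_formulas,
    formula_performance_index,
    friedman_medae_comparison,
    logrank_curves,
    pe_vs_al,
    subgroup_report,
    summarize,
)
from hmiol.features import ALSubgroup

from oracles import (
    cochran_q_oracle,
    friedman_permutation_p,
    friedman_statistic_oracle,
    logrank_oracle,
)


def _series(pe, name="F", ids=None):
    pe = np.asarray(pe, dtype=float)
    ids = ids or tuple(f"c{i}" for i in range(pe.size))
    return PredictionErrorSeries(name, pe, tuple(ids))


class TestPE:
    def test_signed_subtraction(self):
        assert compute_pe(-0.50, -0.25) == pytest.approx(-0.25)
        assert compute_pe(1.3, 1.3) == 0.0

    def test_negative_pe_means_more_myopic_than_predicted(self):
        # actual -1.00 vs predicted -0.50: eye ended more myopic, PE negative
        assert compute_pe(-1.00, -0.50) < 0


class TestSummarize:
    def test_degenerate_zero_series(self):
        r = summarize(_series([0.0, 0.0, 0.0, 0.0]))
        assert r.mean_pe == r.sd_pe == r.mae == r.medae == 0.0
        assert all(v == 100.0 for v in r.pct_within.values())

    def test_hand_computed_example(self):
        r = summarize(_series([-0.6, -0.2, 0.2, 0.6]))
        assert r.mae == pytest.approx(0.4)
        assert r.medae == pytest.approx(0.4)
        assert r.pct_within[0.50] == pytest.approx(50.0)
        assert r.pct_within[0.25] == pytest.approx(50.0)
        assert r.pct_within[0.75] == pytest.approx(100.0)

    def test_sd_uses_sample_denominator(self):
        r = summarize(_series([-0.5, 0.5]))
        assert r.sd_pe == pytest.approx(np.std([-0.5, 0.5], ddof=1))

    def test_band_thresholds_closed(self):
        r = summarize(_series([0.50, -0.50, 0.51]))
        assert r.pct_within[0.50] == pytest.approx(100.0 * 2 / 3)

    @given(
        st.lists(st.floats(-2.0, 2.0), min_size=2, max_size=40).map(
            lambda xs: np.round(xs, 3)
        )
    )
    def test_bands_monotone_and_mae_dominates_mean(self, pe):
        r = summarize(_series(pe))
        vals = [r.pct_within[t] for t in sorted(r.pct_within)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        assert r.mae >= abs(r.mean_pe) - 1e-12

    def test_sd_invariant_under_sign_flip(self):
        pe = np.array([-0.4, 0.1, 0.3, -0.2, 0.6])
        assert summarize(_series(pe)).sd_pe == pytest.approx(
            summarize(_series(-pe)).sd_pe
        )

    def test_fpi_computed_with_al(self, rng):
        al = rng.uniform(26, 35, 60)
        pe = rng.normal(0, 0.4, 60)
        r = summarize(_series(pe), al)
        sd, medae = r.sd_pe, r.medae
        expected = formula_performance_index(sd, medae, r.slope_pe_al, r.pct_within[0.50])
        assert r.fpi == pytest.approx(expected)
        assert 0 < r.fpi < 0.2  # few-hundredths scale


class TestCumulativeCurve:
    def test_limits_and_band_consistency(self, rng):
        s = _series(rng.normal(0, 0.5, 80))
        assert cumulative_curve(s, [np.inf])[0] == 100.0
        assert cumulative_curve(s, [-1e-9])[0] == 0.0
        curve = cumulative_curve(s, BAND_THRESHOLDS)
        bands = summarize(s).pct_within
        for t, v in zip(BAND_THRESHOLDS, curve):
            assert v == pytest.approx(bands[t])


class TestFriedman:
    def test_identical_columns_no_difference(self):
        a = _series([0.1, 0.2, 0.3, 0.4])
        b = _series([0.1, 0.2, 0.3, 0.4], name="G")
        res = friedman_medae_comparison([a, b])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_uniformly_worst_formula_has_smallest_adjusted_p(self, rng):
        base = rng.normal(0, 0.3, 14)
        a = _series(base, "A")
        b = _series(base + rng.normal(0, 0.02, 14), "B")
        worst = _series(base + 1.5, "W")  # uniformly largest |PE|
        res = friedman_medae_comparison([a, b, worst])
        pairs = res.adjusted_pairwise
        assert min(pairs, key=pairs.get) in {("A", "W"), ("B", "W")}

    def test_statistic_matches_first_principles_oracle(self, rng):
        mat = np.abs(rng.normal(0, 0.5, (12, 3)))
        series = [_series(mat[:, j], f"F{j}") for j in range(3)]
        res = friedman_medae_comparison(series)
        assert res.statistic == pytest.approx(friedman_statistic_oracle(mat), abs=1e-9)

    def test_p_value_agrees_with_permutation_null(self, rng):
        """Asymptotic p close to the within-eye permutation p on a 12-case fixture."""
        mat = np.abs(rng.normal(0, 0.5, (12, 3)))
        mat[:, 2] += 0.25  # moderate effect: p in a regime where chi2 is accurate
        series = [_series(mat[:, j], f"F{j}") for j in range(3)]
        res = friedman_medae_comparison(series)
        p_perm, mc_se = friedman_permutation_p(mat, n_perm=4000, seed=5)
        assert res.p_value == pytest.approx(p_perm, abs=max(4 * mc_se, 0.05))

    def test_adjusted_p_at_least_raw_and_capped(self, rng):
        mat = np.abs(rng.normal(0, 0.5, (15, 4)))
        series = [_series(mat[:, j], f"F{j}") for j in range(4)]
        res = friedman_medae_comparison(series)
        from scipy.stats import wilcoxon

        for (i, j), adj in res.adjusted_pairwise.items():
            ii, jj = int(i[1]), int(j[1])
            raw = wilcoxon(mat[:, ii], mat[:, jj], zero_method="wilcox").pvalue
            assert adj >= raw - 1e-12
            assert adj <= 1.0

    def test_misaligned_series_rejected(self):
        a = _series([0.1, 0.2, 0.3], ids=("x", "y", "z"))
        b = _series([0.1, 0.2, 0.3], name="G", ids=("x", "y", "w"))
        with pytest.raises(ValueError):
            friedman_medae_comparison([a, b])


class TestCochranQ:
    def test_identical_indicators_no_difference(self):
        a = _series([0.1, 0.9, 0.1, 0.9])
        b = _series([0.2, 0.8, 0.15, 0.6], name="G")  # same side of 0.5 everywhere
        res = cochran_q_bands([a, b], 0.5)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_statistic_matches_textbook_oracle(self, rng):
        mat = np.abs(rng.normal(0, 0.6, (10, 3)))
        series = [_series(mat[:, j], f"F{j}") for j in range(3)]
        res = cochran_q_bands(series, 0.5)
        ind = (mat <= 0.5).astype(int)
        assert res.statistic == pytest.approx(cochran_q_oracle(ind), abs=1e-9)

    def test_p_value_agrees_with_exhaustive_enumeration(self):
        """Exact within-row permutation null on an 8-case, 3-formula fixture."""
        ind = np.array(
            [
                [1, 0, 0],
                [1, 1, 0],
                [1, 0, 0],
                [0, 1, 0],
                [1, 0, 0],
                [1, 1, 1],
                [1, 0, 0],
                [1, 1, 0],
            ]
        )
        abs_pe = np.where(ind == 1, 0.2, 0.8)
        series = [_series(abs_pe[:, j], f"F{j}") for j in range(3)]
        res = cochran_q_bands(series, 0.5)
        observed = cochran_q_oracle(ind)
        # exhaustive enumeration of all within-row permutations (6^8 tables).
        # Row sums are permutation-invariant, so Q depends only on the column
        # sums; a dynamic program over column-sum states enumerates exactly.
        perms = list(permutations(range(3)))
        states: dict[tuple[int, int, int], int] = {(0, 0, 0): 1}
        for row in ind:
            nxt: dict[tuple[int, int, int], int] = {}
            for perm in perms:
                contrib = tuple(int(row[j]) for j in perm)
                for state, count in states.items():
                    key = (
                        state[0] + contrib[0],
                        state[1] + contrib[1],
                        state[2] + contrib[2],
                    )
                    nxt[key] = nxt.get(key, 0) + count
            states = nxt
        n, k = ind.shape
        row_sums = ind.sum(axis=1)
        den = k * row_sums.sum() - (row_sums**2).sum()
        hits = total = 0
        for col, count in states.items():
            col_arr = np.array(col)
            num = (k - 1) * (k * (col_arr**2).sum() - col_arr.sum() ** 2)
            q = 0.0 if den == 0 else num / den
            total += count
            if q >= observed - 1e-9:
                hits += count
        p_exact = hits / total
        assert total == 6**8
        assert res.p_value == pytest.approx(p_exact, abs=0.06)

    def test_two_formula_case_reduces_to_mcnemar(self):
        a = _series([0.1, 0.9, 0.1, 0.9, 0.1, 0.1, 0.9, 0.1])
        b = _series([0.9, 0.1, 0.9, 0.9, 0.1, 0.9, 0.1, 0.9], name="G")
        res = cochran_q_bands([a, b], 0.5)
        ia, ib = (np.abs(a.pe) <= 0.5).astype(int), (np.abs(b.pe) <= 0.5).astype(int)
        disc_b = np.sum((ia == 1) & (ib == 0))
        disc_c = np.sum((ia == 0) & (ib == 1))
        assert res.statistic == pytest.approx((disc_b - disc_c) ** 2 / (disc_b + disc_c))

    def test_adjusted_pairwise_p_capped_at_one(self, rng):
        mat = np.abs(rng.normal(0, 0.5, (12, 4)))
        series = [_series(mat[:, j], f"F{j}") for j in range(4)]
        res = cochran_q_bands(series, 0.5)
        assert all(0.0 <= p <= 1.0 for p in res.adjusted_pairwise.values())


class TestLogrank:
    def test_identical_series_p_one(self):
        a = _series([0.1, 0.4, 0.2])
        b = _series([0.2, 0.1, 0.4], name="G")
        res = logrank_curves(a, b)
        assert res.p_value == 1.0

    def test_shifted_series_detected(self, rng):
        base = np.abs(rng.normal(0, 0.4, 100))
        res = logrank_curves(_series(base, "A"), _series(base + 1.0, "B"))
        assert res.p_value < 1e-6

    def test_matches_independent_survival_oracle(self, rng):
        a = np.abs(rng.normal(0, 0.4, 20))
        b = np.abs(rng.normal(0.3, 0.5, 20))
        res = logrank_curves(_series(a, "A"), _series(b, "B"))
        chi2, p = logrank_oracle(a, b)
        assert res.statistic == pytest.approx(chi2, rel=1e-6)
        assert res.p_value == pytest.approx(p, rel=1e-6)


class TestPEvsAL:
    def test_constant_pe_gives_zero_correlation(self):
        r, slope, p = pe_vs_al(_series([0.2] * 5), np.array([26, 28, 30, 32, 34.0]))
        assert r == 0.0 and slope == 0.0

    def test_exact_linear_relation(self):
        al = np.array([26.0, 28.0, 30.0, 32.0, 34.0])
        r, slope, _ = pe_vs_al(_series(0.1 * al), al)
        assert r == pytest.approx(1.0)
        assert slope == pytest.approx(0.1)

    def test_closed_form_on_five_point_fixture(self):
        al = np.array([26.0, 27.0, 29.0, 31.0, 33.0])
        pe = np.array([-0.1, 0.0, 0.2, 0.1, 0.4])
        r, slope, p = pe_vs_al(_series(pe), al)
        sxy = np.sum((al - al.mean()) * (pe - pe.mean()))
        assert slope == pytest.approx(sxy / np.sum((al - al.mean()) ** 2))
        assert r == pytest.approx(sxy / (np.sqrt(np.sum((al - al.mean()) ** 2)) * np.sqrt(np.sum((pe - pe.mean()) ** 2))))

    def test_zero_al_variance_flagged(self):
        with pytest.raises(ValueError):
            pe_vs_al(_series([0.1, 0.2, 0.3]), np.array([30.0, 30.0, 30.0]))


class TestSubgroups:
    def test_single_bin_report_equals_global(self, rng):
        pe = rng.normal(0, 0.4, 30)
        al = rng.uniform(26.0, 27.9, 30)
        s = _series(pe)
        reports = subgroup_report(s, al)
        assert list(reports) == [ALSubgroup.AL_26_28]
        assert reports[ALSubgroup.AL_26_28].mae == pytest.approx(summarize(s, al).mae)

    def test_counts_partition_n(self, rng):
        pe = rng.normal(0, 0.4, 120)
        al = rng.uniform(26.0, 36.0, 120)
        reports = subgroup_report(_series(pe), al)
        assert sum(r.n for r in reports.values()) == 120


class TestHarness:
    def test_evaluate_formulas_structure(self, rng):
        n = 60
        actual = rng.normal(-0.2, 0.5, n)
        df = pd.DataFrame(
            {
                "case_id": [f"c{i}" for i in range(n)],
                "al_mm": rng.uniform(26, 35, n),
                "actual_se_d": actual,
                "FormulaA": actual + rng.normal(0, 0.3, n),
                "FormulaB": actual + rng.normal(0.2, 0.5, n),
            }
        )
        result = evaluate_formulas(df)
        assert set(result["reports"]) == {"FormulaA", "FormulaB"}
        assert set(result["subgroups"]) == {"FormulaA", "FormulaB"}
        assert result["comparisons"]["friedman_medae"].test_name is ComparisonTest.FRIEDMAN_BONFERRONI
        assert set(result["comparisons"]["cochran_q"]) == set(BAND_THRESHOLDS)
        assert ("FormulaA", "FormulaB") in result["comparisons"]["logrank"]
        # the better-calibrated formula should score the lower MAE here
        assert result["reports"]["FormulaA"].mae < result["reports"]["FormulaB"].mae
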