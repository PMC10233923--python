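"""Accuracy metrics and statistical comparison battery for IOL formulas.

The prediction error (PE) for one eye is the actual postoperative
refraction minus the formula-predicted refraction back-calculated at the
implanted power; negative PE means the eye ended more myopic than
predicted.  For each formula on a cohort the battery reports mean/SD of
PE, MAE, MedAE, the percentages of eyes within +/-0.25/0.50/0.75/1.00 D
(closed thresholds), the cumulative |PE| curve, the PE-vs-AL trend, and a
composite formula performance index (FPI).

Formula comparisons follow the standard clinical protocol: Friedman test
on absolute errors with Bonferroni-corrected pairwise post-hocs, Cochran's
Q (pairwise McNemar) on the within-band indicators, log-rank tests on the
cumulative absolute-error curves, and Pearson correlation of PE with AL.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test as _lifelines_logrank
from scipy import stats
from statsmodels.stats.contingency_tables import cochrans_q as _sm_cochrans_q
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

from .features import AL_SUBGROUP_BOUNDARIES, ALSubgroup, al_subgroup

logger = logging.getLogger(__name__)

#: canonical absolute-error band thresholds, diopters
BAND_THRESHOLDS = (0.25, 0.50, 0.75, 1.00)


class ComparisonTest(str, Enum):
    FRIEDMAN_BONFERRONI = "FRIEDMAN_BONFERRONI"
    COCHRAN_Q_BONFERRONI = "COCHRAN_Q_BONFERRONI"
    LOGRANK = "LOGRANK"
    PEARSON = "PEARSON"


@dataclass(frozen=True)
class PredictionErrorSeries:
    """Per-case signed prediction errors for one formula."""

    formula_name: str
    pe: np.ndarray
    case_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        pe = np.asarray(self.pe, dtype=float)
        object.__setattr__(self, "pe", pe)
        if pe.size < 1:
            raise ValueError("prediction-error series must be nonempty")
        if not np.all(np.isfinite(pe)):
            raise ValueError("prediction errors must be finite")
        if len(self.case_ids) != pe.size:
            raise ValueError("case_ids must align with the PE vector")


@dataclass(frozen=True)
class EvaluationReport:
    """The full metric battery for one formula on one cohort."""

    formula_name: str
    n: int
    mean_pe: float
    sd_pe: float
    mae: float
    mae_sd: float
    medae: float
    pct_within: dict[float, float]  # threshold (D) -> percentage of eyes
    pearson_r_pe_al: float = math.nan
    slope_pe_al: float = math.nan
    p_pe_al: float = math.nan
    fpi: float = math.nan

    def __post_init__(self) -> None:
        pcts = [self.pct_within[t] for t in sorted(self.pct_within)]
        if any(b < a - 1e-12 for a, b in zip(pcts, pcts[1:])):
            raise ValueError("band percentages must be nondecreasing in the threshold")


@dataclass(frozen=True)
class ComparisonResult:
    test_name: ComparisonTest
    statistic: float
    p_value: float
    adjusted_pairwise: dict[tuple[str, str], float] = field(default_factory=dict)


def compute_pe(actual: float | np.ndarray, predicted: float | np.ndarray) -> float | np.ndarray:
    """Prediction error: actual minus predicted postoperative refraction."""
    return np.subtract(actual, predicted)


def band_percentages(
    pe: np.ndarray, thresholds: Sequence[float] = BAND_THRESHOLDS
) -> dict[float, float]:
    """Percentage of eyes with |PE| <= t for each threshold (closed bands)."""
    abs_pe = np.abs(np.asarray(pe, dtype=float))
    return {float(t): float(100.0 * np.mean(abs_pe <= t)) for t in thresholds}


def formula_performance_index(
    sd_pe: float, medae: float, slope_pe_al: float, pct_within_050: float
) -> float:
    """Composite FPI: 1 / (SD + MedAE + |PE-vs-AL slope| + 10 / fraction within 0.50 D).

    The four components enter additively so each can be inspected on its
    own; the half-diopter hit rate enters as a fraction (0-1), which puts
    the index on the familiar few-hundredths scale.  Higher is better.
    """
    if pct_within_050 <= 0:
        return 0.0
    frac = pct_within_050 / 100.0
    denom = sd_pe + medae + abs(slope_pe_al) + 10.0 / frac
    return 1.0 / denom


def summarize(
    series: PredictionErrorSeries,
    al: Optional[np.ndarray] = None,
    thresholds: Sequence[float] = BAND_THRESHOLDS,
) -> EvaluationReport:
    """Full metric battery for one formula; AL enables the trend terms and FPI."""
    pe = series.pe
    n = pe.size
    abs_pe = np.abs(pe)
    sd = float(np.std(pe, ddof=1)) if n >= 2 else math.nan
    mae_sd = float(np.std(abs_pe, ddof=1)) if n >= 2 else math.nan
    pct = band_percentages(pe, thresholds)
    r = slope = p = math.nan
    fpi = math.nan
    if al is not None:
        r, slope, p = pe_vs_al(series, np.asarray(al, dtype=float))
        if n >= 2:
            fpi = formula_performance_index(sd, float(np.median(abs_pe)), slope, pct[0.50])
    return EvaluationReport(
        formula_name=series.formula_name,
        n=n,
        mean_pe=float(np.mean(pe)),
        sd_pe=sd,
        mae=float(np.mean(abs_pe)),
        mae_sd=mae_sd,
        medae=float(np.median(abs_pe)),
        pct_within=pct,
        pearson_r_pe_al=r,
        slope_pe_al=slope,
        p_pe_al=p,
        fpi=fpi,
    )


def cumulative_curve(
    series: PredictionErrorSeries, thresholds: Sequence[float]
) -> np.ndarray:
    """Empirical CDF of |PE| (percent of eyes), right-continuous, on a grid."""
    abs_pe = np.abs(series.pe)
    return np.asarray([100.0 * np.mean(abs_pe <= t) for t in thresholds], dtype=float)


# --- statistical comparisons -------------------------------------------------


def _aligned_matrix(series_list: Sequence[PredictionErrorSeries]) -> np.ndarray:
    """Stack |PE| columns after checking the case pairing; (n_cases, k)."""
    ids = series_list[0].case_ids
    for s in series_list[1:]:
        if s.case_ids != ids:
            raise ValueError(
                f"series {s.formula_name!r} is not paired case-for-case with "
                f"{series_list[0].formula_name!r}"
            )
    return np.column_stack([np.abs(s.pe) for s in series_list])


def _bonferroni(p: float, m: int) -> float:
    return min(1.0, p * m)


def friedman_medae_comparison(
    series_list: Sequence[PredictionErrorSeries],
) -> ComparisonResult:
    """Friedman test on paired absolute errors, Bonferroni pairwise post-hocs.

    The omnibus statistic ranks |PE| within each eye across formulas; the
    post-hocs are Wilcoxon signed-rank tests on each formula pair with the
    Bonferroni family spanning all pairs.
    """
    if len(series_list) < 2:
        raise ValueError("need at least two formulas to compare")
    mat = _aligned_matrix(series_list)
    names = [s.formula_name for s in series_list]
    if np.allclose(mat, mat[:, [0]]):
        stat, p = 0.0, 1.0
    elif mat.shape[1] == 2:
        # two-treatment Friedman reduces to a sign test on the paired ranks
        stat, p = _two_sample_friedman(mat[:, 0], mat[:, 1])
    else:
        stat, p = stats.friedmanchisquare(*(mat[:, j] for j in range(mat.shape[1])))
    pairs = list(combinations(range(len(names)), 2))
    adjusted: dict[tuple[str, str], float] = {}
    for i, j in pairs:
        d = mat[:, i] - mat[:, j]
        if np.allclose(d, 0.0):
            praw = 1.0
        else:
            praw = float(stats.wilcoxon(mat[:, i], mat[:, j], zero_method="wilcox").pvalue)
        adjusted[(names[i], names[j])] = _bonferroni(praw, len(pairs))
    return ComparisonResult(
        ComparisonTest.FRIEDMAN_BONFERRONI, float(stat), float(p), adjusted
    )


def _two_sample_friedman(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Tie-corrected Friedman chi-square for exactly two paired columns."""
    data = np.column_stack([a, b])
    ranks = np.apply_along_axis(stats.rankdata, 1, data)
    n, k = ranks.shape
    rj = ranks.sum(axis=0)
    ss = float(((rj - n * (k + 1) / 2.0) ** 2).sum())
    tie_term = 0.0
    for row in data:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float((counts**3 - counts).sum())
    denom = n * k * (k + 1) / 12.0 - tie_term / (12.0 * (k - 1))
    if denom <= 0:
        return 0.0, 1.0
    chi2 = ss / denom
    return chi2, float(stats.chi2.sf(chi2, k - 1))


def cochran_q_bands(
    series_list: Sequence[PredictionErrorSeries], threshold: float
) -> ComparisonResult:
    """Cochran's Q on the within-band indicators, Bonferroni McNemar post-hocs.

    Each eye contributes a paired binary success |PE| <= threshold per
    formula.  With identical indicator columns Q is undefined; that case
    is reported as "no difference" (statistic 0, p = 1).
    """
    mat = _aligned_matrix(series_list)
    names = [s.formula_name for s in series_list]
    ind = (mat <= threshold).astype(int)
    if np.all(ind == ind[:, [0]]):
        stat, p = 0.0, 1.0
    else:
        res = _sm_cochrans_q(ind, return_object=True)
        stat, p = float(res.statistic), float(res.pvalue)
    pairs = list(combinations(range(len(names)), 2))
    adjusted: dict[tuple[str, str], float] = {}
    for i, j in pairs:
        tbl = np.zeros((2, 2))
        for a, b in zip(ind[:, i], ind[:, j]):
            tbl[a, b] += 1
        if tbl[0, 1] + tbl[1, 0] == 0:
            praw = 1.0
        else:
            praw = float(_sm_mcnemar(tbl, exact=True).pvalue)
        adjusted[(names[i], names[j])] = _bonferroni(praw, len(pairs))
    return ComparisonResult(
        ComparisonTest.COCHRAN_Q_BONFERRONI, float(stat), float(p), adjusted
    )


def logrank_curves(
    series_a: PredictionErrorSeries, series_b: PredictionErrorSeries
) -> ComparisonResult:
    """Log-rank comparison of two cumulative |PE| curves.

    Absolute error plays the role of event time with every eye an
    observed event; a formula whose curve rises faster (smaller errors)
    is stochastically better.
    """
    a, b = np.abs(series_a.pe), np.abs(series_b.pe)
    if a.size == b.size and np.array_equal(np.sort(a), np.sort(b)):
        return ComparisonResult(ComparisonTest.LOGRANK, 0.0, 1.0)
    res = _lifelines_logrank(a, b)
    return ComparisonResult(
        ComparisonTest.LOGRANK, float(res.test_statistic), float(res.p_value)
    )


def pe_vs_al(
    series: PredictionErrorSeries, al: np.ndarray
) -> tuple[float, float, float]:
    """Pearson r, least-squares slope and two-sided p of PE against AL."""
    pe = series.pe
    al = np.asarray(al, dtype=float)
    if al.size != pe.size:
        raise ValueError("AL vector must align with the PE series")
    if pe.size < 3:
        raise ValueError("need at least 3 cases for a correlation")
    if np.std(al) < 1e-15:
        raise ValueError("AL has zero variance; correlation undefined")
    if np.std(pe) < 1e-15:
        return 0.0, 0.0, 1.0
    lr = stats.linregress(al, pe)
    return float(lr.rvalue), float(lr.slope), float(lr.pvalue)


def subgroup_report(
    series: PredictionErrorSeries,
    al: np.ndarray,
    boundaries: tuple[float, float] = AL_SUBGROUP_BOUNDARIES,
) -> dict[ALSubgroup, EvaluationReport]:
    """Per-axial-length-bin metric battery; empty bins are omitted with a notice."""
    al = np.asarray(al, dtype=float)
    if al.size != series.pe.size:
        raise ValueError("AL vector must align with the PE series")
    bins = np.asarray([al_subgroup(a, boundaries).value for a in al])
    out: dict[ALSubgroup, EvaluationReport] = {}
    for sg in ALSubgroup:
        mask = bins == sg.value
        if not mask.any():
            logger.info("AL subgroup %s empty; omitted from the report", sg.value)
            continue
        sub = PredictionErrorSeries(
            series.formula_name,
            series.pe[mask],
            tuple(np.asarray(series.case_ids)[mask].tolist()),
        )
        out[sg] = summarize(sub, al[mask])
    return out


# --- cohort-level harness ----------------------------------------------------


def series_from_frame(pred_df: pd.DataFrame, formula: str) -> PredictionErrorSeries:
    """Build a PE series from a predictions table (case_id, actual_se_d, <formula> columns)."""
    pe = compute_pe(pred_df["actual_se_d"].to_numpy(), pred_df[formula].to_numpy())
    return PredictionErrorSeries(formula, pe, tuple(pred_df["case_id"].astype(str)))


def evaluate_formulas(
    pred_df: pd.DataFrame,
    formulas: Optional[Sequence[str]] = None,
    thresholds: Sequence[float] = BAND_THRESHOLDS,
) -> dict:
    """Run the whole battery on a predictions table.

    The table needs ``case_id``, ``al_mm``, ``actual_se_d`` and one column
    of predicted refractions per formula (comparator formulas that cannot
    be recomputed locally enter as pre-computed columns).  Returns the
    per-formula reports, subgroup reports, and the comparison suite.
    """
    reserved = {"case_id", "al_mm", "actual_se_d"}
    if formulas is None:
        formulas = [c for c in pred_df.columns if c not in reserved]
    if not formulas:
        raise ValueError("no formula prediction columns found")
    al = pred_df["al_mm"].to_numpy(dtype=float)
    series = {f: series_from_frame(pred_df, f) for f in formulas}
    reports = {f: summarize(s, al, thresholds) for f, s in series.items()}
    subgroups = {f: subgroup_report(s, al) for f, s in series.items()}
    comparisons: dict[str, object] = {}
    if len(formulas) >= 2:
        comparisons["friedman_medae"] = friedman_medae_comparison(list(series.values()))
        comparisons["cochran_q"] = {
            t: cochran_q_bands(list(series.values()), t) for t in thresholds
        }
        comparisons["logrank"] = {
            (f1, f2): logrank_curves(series[f1], series[f2])
            for f1, f2 in combinations(formulas, 2)
        }
    return {"reports": reports, "subgroups": subgroups, "comparisons": comparisons}


def reports_to_frame(reports: Mapping[str, EvaluationReport]) -> pd.DataFrame:
    """Flatten per-formula reports into a table (formulas as columns)."""
    rows = {}
    for name, r in reports.items():
        rows[name] = {
            "n": r.n,
            "mean_pe_d": r.mean_pe,
            "sd_pe_d": r.sd_pe,
            "mae_d": r.mae,
            "mae_sd_d": r.mae_sd,
            "medae_d": r.medae,
            **{f"pct_within_{t:.2f}d": v for t, v in sorted(r.pct_within.items())},
            "pearson_r_pe_al": r.pearson_r_pe_al,
            "slope_pe_al": r.slope_pe_al,
            "fpi": r.fpi,
        }
    return pd.DataFrame(rows)
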