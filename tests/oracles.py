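"""Independent step-by-step oracles used to cross-check the library.

The vergence oracles deliberately avoid the closed-form refraction
expressions used by the implementation: they propagate reduced vergences
surface by surface through the eye and find the spectacle refraction by
bracketed root-finding, the way a step-by-step spreadsheet check would.
"""
from __future__ import annotations

import math

import numpy as np
from scipy.optimize import brentq


def _propagate(vergence_d: float, distance_mm: float, n: float) -> float:
    """Reduced-vergence translation over distance_mm in a medium of index n."""
    return vergence_d / (1.0 - (distance_mm / 1000.0 / n) * vergence_d)


def _chain_refraction(
    corneal_power_d: float,
    elp_mm: float,
    optical_al_mm: float,
    iol_power_d: float,
    n_internal: float = 1.336,
    vertex_mm: float = 12.0,
) -> float:
    """Spectacle refraction solving the physical vergence chain numerically."""

    def mismatch(ref: float) -> float:
        ref_corneal = ref / (1.0 - (vertex_mm / 1000.0) * ref)
        v_after_cornea = ref_corneal + corneal_power_d
        v_at_iol = _propagate(v_after_cornea, elp_mm, n_internal)
        v_after_iol = v_at_iol + iol_power_d
        required = 1000.0 * n_internal / (optical_al_mm - elp_mm)
        return v_after_iol - required

    return brentq(mismatch, -45.0, 45.0, xtol=1e-12)


def srkt_oracle(al, k_flat, k_steep, a_constant, iol_power) -> float:
    """Step-by-step SRK/T spectacle refraction."""
    k = (k_flat + k_steep) / 2.0
    r = 337.5 / k
    lcor = al if al <= 24.2 else -3.446 + 1.716 * al - 0.0237 * al * al
    cw = -5.41 + 0.58412 * lcor + 0.098 * k
    rad = r * r - cw * cw / 4.0
    h = r - math.sqrt(max(rad, 0.0))
    elp = h + (0.62467 * a_constant - 68.747) - 3.336
    lopt = al + 0.65696 - 0.02029 * al
    corneal_power = 1000.0 * 0.333 / r
    return _chain_refraction(corneal_power, elp, lopt, iol_power)


def haigis_oracle(al, k_flat, k_steep, acd, a0, a1, a2, iol_power) -> float:
    """Step-by-step Haigis spectacle refraction."""
    k = (k_flat + k_steep) / 2.0
    r = 337.5 / k
    elp = a0 + a1 * acd + a2 * al
    corneal_power = 1000.0 * (1.3315 - 1.0) / r
    return _chain_refraction(corneal_power, elp, al, iol_power)


def logrank_oracle(times_a: np.ndarray, times_b: np.ndarray) -> tuple[float, float]:
    """Textbook two-group log-rank chi-square with no censoring."""
    from scipy import stats

    times = np.concatenate([times_a, times_b])
    group = np.concatenate([np.zeros(len(times_a)), np.ones(len(times_b))])
    observed_a = 0.0
    expected_a = 0.0
    var_a = 0.0
    for t in np.unique(times):
        at_risk = times >= t
        n = at_risk.sum()
        n_a = (at_risk & (group == 0)).sum()
        d = (times == t).sum()
        d_a = ((times == t) & (group == 0)).sum()
        observed_a += d_a
        expected_a += d * n_a / n
        if n > 1:
            var_a += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    chi2 = (observed_a - expected_a) ** 2 / var_a
    return chi2, float(stats.chi2.sf(chi2, 1))


def cochran_q_oracle(indicators: np.ndarray) -> float:
    """Cochran's Q statistic from its textbook definition."""
    n, k = indicators.shape
    col = indicators.sum(axis=0)
    row = indicators.sum(axis=1)
    num = (k - 1) * (k * (col**2).sum() - col.sum() ** 2)
    den = k * row.sum() - (row**2).sum()
    return num / den


def friedman_statistic_oracle(abs_errors: np.ndarray) -> float:
    """Tie-corrected Friedman chi-square computed from first principles."""
    from scipy.stats import rankdata

    ranks = np.apply_along_axis(rankdata, 1, abs_errors)
    n, k = ranks.shape
    rj = ranks.sum(axis=0)
    ss = ((rj - n * (k + 1) / 2.0) ** 2).sum()
    a = (ranks**2).sum()
    c = n * k * (k + 1) ** 2 / 4.0
    if a == c:
        return 0.0
    return (k - 1) * ss / (a - c)


def friedman_permutation_p(
    abs_errors: np.ndarray, n_perm: int, seed: int
) -> tuple[float, float]:
    """Monte-Carlo permutation p-value of the Friedman statistic.

    Permutes each block's (eye's) errors across formulas under the null
    of exchangeability; returns (p, Monte-Carlo standard error).
    """
    rng = np.random.default_rng(seed)
    observed = friedman_statistic_oracle(abs_errors)
    n, k = abs_errors.shape
    hits = 0
    for _ in range(n_perm):
        perm = np.array([row[rng.permutation(k)] for row in abs_errors])
        if friedman_statistic_oracle(perm) >= observed - 1e-12:
            hits += 1
    p = hits / n_perm
    return p, math.sqrt(max(p * (1 - p), 1e-12) / n_perm)
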