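"""Seeded generator of highly myopic surgical cohorts with known ground truth.

Biometry is drawn so that the *post-truncation* marginals reproduce the
reference training-cohort moments (axial length 29.18 +/- 2.19 mm on
26.0-37.5 mm, keratometry 43.30/44.32 +/- 1.5/1.6 D, ACD 3.42 +/- 0.34 mm,
LT 4.44 +/- 0.39 mm, CD 11.75 +/- 0.42 mm): the axial length comes from a
truncated normal whose underlying location/scale are solved numerically
so the truncated mean and SD hit their targets exactly, and the remaining
fields are drawn conditionally on AL through a mild, configurable
physiologic correlation structure (deeper chambers and slightly flatter
corneas in longer eyes; the two keratometry meridians strongly coupled).

Each eye then receives an implanted power — the configured truth formula's
power for the target policy (emmetropia or -3 D), rounded to manufacturable
0.5 D steps — and an observed postoperative SE equal to the truth formula's
refraction at that power plus additive Gaussian noise.  The generator is
the oracle for every parameter-recovery test: the irreducible mean
absolute error of a perfect predictor is ``noise_sd * sqrt(2/pi)``.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache

import numpy as np
from scipy import optimize, stats

from .features import SurgicalCase
from .optics import (
    Biometry,
    FormulaName,
    IOLConstants,
    POWER_RANGE,
    convert_a_to_haigis,
    power_for_refraction,
    predict_refraction,
)

#: reference training-cohort biometry moments (mean, SD)
DEFAULT_MOMENTS: dict[str, tuple[float, float]] = {
    "al": (29.18, 2.19),
    "k_flat": (43.30, 1.51),
    "k_steep": (44.32, 1.61),
    "acd": (3.42, 0.34),
    "lt": (4.44, 0.39),
    "cd": (11.75, 0.42),
}
DEFAULT_AL_RANGE = (26.0, 37.5)


class TargetPolicy(str, Enum):
    EMMETROPIA = "EMMETROPIA"
    MYOPIC_MINUS_3 = "MYOPIC_MINUS_3"

    @property
    def target_refraction(self) -> float:
        return 0.0 if self is TargetPolicy.EMMETROPIA else -3.0


def _default_constants() -> IOLConstants:
    a0, a1, a2 = convert_a_to_haigis(118.0)
    return IOLConstants(a_constant=118.0, a0=a0, a1=a1, a2=a2)


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for one synthetic cohort."""

    n: int = 1462
    seed: int = 0
    moments: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MOMENTS)
    )
    al_range: tuple[float, float] = DEFAULT_AL_RANGE
    rho_al_acd: float = 0.3
    rho_al_k: float = -0.2
    rho_kf_ks: float = 0.9
    truth_model: FormulaName = FormulaName.HAIGIS
    truth_constants: IOLConstants = field(default_factory=_default_constants)
    noise_sd: float = 0.3
    # a -3 D target is the usual choice for high myopes and reproduces the
    # reference cohort's implanted-power distribution (~9.3 +/- 5.0 D)
    target_policy: TargetPolicy = TargetPolicy.MYOPIC_MINUS_3
    # surgeon-to-surgeon spread of the chosen target (D); gives outcomes the
    # power-response variation a real cohort has, so trained models remain
    # identifiable away from a single operating point
    target_jitter_sd: float = 0.75
    lens_model: str = "SYN-A118"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be at least 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.target_jitter_sd < 0:
            raise ValueError("target_jitter_sd must be nonnegative")
        lo, hi = self.al_range
        if not (20.0 < lo < hi < 40.0):
            raise ValueError("al_range must lie within (20, 40) mm")


@lru_cache(maxsize=32)
def _calibrated_truncnorm(
    mean: float, sd: float, lo: float, hi: float
) -> tuple[float, float]:
    """Underlying (loc, scale) whose [lo, hi]-truncated normal has the given moments."""

    def residual(params: np.ndarray) -> np.ndarray:
        loc, log_scale = params
        scale = math.exp(log_scale)
        a, b = (lo - loc) / scale, (hi - loc) / scale
        m, v = stats.truncnorm.stats(a, b, loc=loc, scale=scale, moments="mv")
        return np.array([m - mean, math.sqrt(v) - sd])

    sol = optimize.root(residual, x0=np.array([mean, math.log(sd)]), method="hybr")
    if not sol.success:
        raise RuntimeError(f"truncated-normal calibration failed: {sol.message}")
    loc, log_scale = sol.x
    return float(loc), float(math.exp(log_scale))


def _draw_biometry(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """(n, 6) array of [al, k_flat, k_steep, acd, lt, cd]."""
    n = spec.n
    mom = spec.moments
    lo, hi = spec.al_range
    al_mean, al_sd = mom["al"]
    loc, scale = _calibrated_truncnorm(al_mean, al_sd, lo, hi)
    a, b = (lo - loc) / scale, (hi - loc) / scale
    al = stats.truncnorm.rvs(a, b, loc=loc, scale=scale, size=n, random_state=rng)
    # standardized AL against its *target* moments so conditional draws keep
    # the specified marginal means/SDs and correlations exactly
    z_al = (al - al_mean) / al_sd

    def conditional(name: str, rho: float, extra: np.ndarray | None = None) -> np.ndarray:
        mean, sd = mom[name]
        resid_sd = sd * math.sqrt(max(0.0, 1.0 - rho**2))
        eps = rng.standard_normal(n) if extra is None else extra
        return mean + rho * sd * z_al + resid_sd * eps

    acd = conditional("acd", spec.rho_al_acd)
    # keratometry pair: shared AL loading rho_al_k, mutual residual correlation
    # chosen so corr(k_flat, k_steep) = rho_kf_ks overall
    rho_resid = (spec.rho_kf_ks - spec.rho_al_k**2) / (1.0 - spec.rho_al_k**2)
    rho_resid = min(max(rho_resid, -1.0), 1.0)
    e1 = rng.standard_normal(n)
    e2 = rho_resid * e1 + math.sqrt(max(0.0, 1.0 - rho_resid**2)) * rng.standard_normal(n)
    kf = conditional("k_flat", spec.rho_al_k, e1)
    ks = conditional("k_steep", spec.rho_al_k, e2)
    # enforce the flat <= steep ordering (rarely violated under strong coupling)
    k_lo, k_hi = np.minimum(kf, ks), np.maximum(kf, ks)
    lt = conditional("lt", 0.0)
    cd = conditional("cd", 0.0)
    out = np.column_stack([al, k_lo, k_hi, acd, lt, cd])
    if np.any(out <= 0):
        raise RuntimeError("generated biometry left the physical domain")
    return out


def _round_to_half_diopter(power: float) -> float:
    lo, hi = POWER_RANGE
    return float(np.clip(np.round(power * 2.0) / 2.0, lo, hi))


def truth_refraction(spec: CohortSpec, case: SurgicalCase, power: float) -> float:
    """Noiseless refraction of the configured truth formula at a given power."""
    return predict_refraction(
        spec.truth_model, case.biometry, power, spec.truth_constants
    ).predicted_refraction


def generate_cohort(spec: CohortSpec) -> list[SurgicalCase]:
    """Draw one fully deterministic synthetic cohort."""
    rng = np.random.default_rng(spec.seed)
    rows = _draw_biometry(spec, rng)
    noise = rng.normal(0.0, spec.noise_sd, size=spec.n) if spec.noise_sd > 0 else np.zeros(spec.n)
    base_target = spec.target_policy.target_refraction
    targets = base_target + (
        rng.normal(0.0, spec.target_jitter_sd, size=spec.n)
        if spec.target_jitter_sd > 0
        else np.zeros(spec.n)
    )
    cases: list[SurgicalCase] = []
    for i in range(spec.n):
        target = float(targets[i])
        al, kf, ks, acd, lt, cd = rows[i]
        biometry = Biometry(
            axial_length=float(al),
            k_flat=float(kf),
            k_steep=float(ks),
            acd_epithelium_to_lens=float(acd),
            lens_thickness=float(lt),
            corneal_diameter=float(cd),
        )
        # exact optical solution, then clamped/rounded to manufacturable powers
        exact_power = power_for_refraction(
            spec.truth_model, biometry, spec.truth_constants, target, power_range=None
        )
        implanted = _round_to_half_diopter(exact_power)
        truth_se = predict_refraction(
            spec.truth_model, biometry, implanted, spec.truth_constants
        ).predicted_refraction
        cases.append(
            SurgicalCase(
                case_id=f"SYN-{spec.seed}-{i:06d}",
                biometry=biometry,
                lens_model=spec.lens_model,
                iol_power_implanted=implanted,
                constants=spec.truth_constants,
                postop_se=float(truth_se + noise[i]),
                postop_bcva_logmar=0.0,
            )
        )
    return cases


def noise_floor_mae(noise_sd: float) -> float:
    """Irreducible MAE of a perfect predictor under N(0, sd) outcome noise."""
    return noise_sd * math.sqrt(2.0 / math.pi)
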