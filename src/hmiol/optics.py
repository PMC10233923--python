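"""Thin-lens vergence engines for IOL power calculation.

Implements the two classical theoretical formulas used as feature
transforms throughout the package:

* **SRK/T** — effective lens position (ELP) predicted from corneal height
  and an A-constant offset, with the axial length corrected for long eyes
  (LCOR) and a retinal-thickness term.
* **Haigis** — ELP as a linear function of anterior chamber depth and
  axial length, ``d = a0 + a1*ACD + a2*AL``.

Both engines run forward (spectacle-plane refraction from IOL power) and
inverse (IOL power for a target refraction, in closed form — each formula
is a Möbius function of power, so the inversion is exact).

Conventions, pinned in one place:

* keratometer index 1.3375, so corneal radius r = 337.5 / K (mm);
* vertex distance 12 mm for spectacle-plane refraction;
* SRK/T refractive indices: aqueous/vitreous 1.336, cornea 1.333;
* Haigis corneal power index 1.3315, internal index 1.336;
* all computation in double precision, no rounding until display.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

logger = logging.getLogger(__name__)

# --- optical constants -------------------------------------------------------

KERATOMETER_INDEX = 1.3375          #: K <-> radius conversion (IOLMaster convention)
VERTEX_MM = 12.0                    #: spectacle vertex distance, mm
N_AQUEOUS = 1.336                   #: aqueous/vitreous refractive index
N_CORNEA_SRKT = 1.333               #: fictitious corneal index used by SRK/T
N_CORNEA_HAIGIS = 1.3315            #: corneal index used by Haigis

#: plausible range for published SRK/T A constants
A_CONSTANT_RANGE = (110.0, 125.0)
#: manufacturable IOL power range searched by the inverse solvers, diopters
POWER_RANGE = (-10.0, 40.0)


class OpticsDomainError(ValueError):
    """Raised when an optical quantity leaves its physical domain."""


class DegenerateGeometryError(OpticsDomainError):
    """Raised when the predicted lens plane reaches or passes the retina."""


class PowerOutOfRangeError(OpticsDomainError):
    """Raised when no IOL power inside the manufacturable range satisfies the target."""


class FormulaName(str, Enum):
    SRKT = "SRKT"
    HAIGIS = "HAIGIS"


# --- domain types ------------------------------------------------------------


@dataclass(frozen=True)
class Biometry:
    """One eye's preoperative biometry.

    All lengths in millimetres, keratometry in diopters.  ACD is measured
    from the corneal epithelium to the anterior lens surface.
    """

    axial_length: float
    k_flat: float
    k_steep: float
    acd_epithelium_to_lens: float
    lens_thickness: float
    corneal_diameter: float

    def __post_init__(self) -> None:
        for name in (
            "axial_length",
            "k_flat",
            "k_steep",
            "acd_epithelium_to_lens",
            "lens_thickness",
            "corneal_diameter",
        ):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise OpticsDomainError(f"biometry field {name}={v!r} must be finite and positive")
        if self.k_flat > self.k_steep:
            raise OpticsDomainError(
                f"k_flat ({self.k_flat}) must not exceed k_steep ({self.k_steep})"
            )


@dataclass(frozen=True)
class IOLConstants:
    """Lens-model calibration constants.

    At least one of the A constant (SRK/T) or the Haigis triple
    (a0, a1, a2) must be present; a missing Haigis triple is derived from
    A via :func:`convert_a_to_haigis`.
    """

    a_constant: Optional[float] = None
    a0: Optional[float] = None
    a1: Optional[float] = None
    a2: Optional[float] = None

    def __post_init__(self) -> None:
        haigis = (self.a0, self.a1, self.a2)
        has_haigis = all(v is not None for v in haigis)
        if any(v is not None for v in haigis) and not has_haigis:
            raise OpticsDomainError("Haigis constants must be supplied as a full (a0, a1, a2) triple")
        if self.a_constant is None and not has_haigis:
            raise OpticsDomainError("need an A constant or a Haigis (a0, a1, a2) triple")
        if self.a_constant is not None:
            lo, hi = A_CONSTANT_RANGE
            if not (lo <= self.a_constant <= hi):
                raise OpticsDomainError(
                    f"A constant {self.a_constant} outside plausible range {A_CONSTANT_RANGE}"
                )

    def resolved_haigis(self) -> tuple[float, float, float]:
        """The Haigis triple, derived from A when not published."""
        if self.a0 is not None:
            return (self.a0, self.a1, self.a2)  # type: ignore[return-value]
        logger.info("Haigis constants missing; deriving (a0, a1, a2) from A=%s", self.a_constant)
        return convert_a_to_haigis(self.a_constant)  # type: ignore[arg-type]

    def require_a_constant(self) -> float:
        if self.a_constant is None:
            raise OpticsDomainError("SRK/T requires an A constant")
        return self.a_constant


@dataclass(frozen=True)
class TheoreticalPrediction:
    """A vergence-formula result plus its optical intermediates."""

    formula_name: FormulaName
    predicted_refraction: float  # diopters, spectacle plane at 12 mm vertex
    elp: float  # mm
    intermediates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.elp <= 0:
            raise OpticsDomainError(f"ELP must be positive, got {self.elp}")
        if not math.isfinite(self.predicted_refraction):
            raise OpticsDomainError("predicted refraction must be finite")


# --- elementary operations ---------------------------------------------------


def mean_k(k_flat: float, k_steep: float) -> float:
    """Arithmetic mean keratometry, diopters."""
    if not (math.isfinite(k_flat) and math.isfinite(k_steep)):
        raise OpticsDomainError("keratometry must be finite")
    if k_flat > k_steep:
        raise OpticsDomainError("k_flat must not exceed k_steep")
    return (k_flat + k_steep) / 2.0


def corneal_radius(k: float) -> float:
    """Corneal radius of curvature (mm) from keratometry via the 1.3375 index."""
    if not math.isfinite(k) or k <= 0:
        raise OpticsDomainError(f"keratometry {k!r} must be finite and positive")
    r = 1000.0 * (KERATOMETER_INDEX - 1.0) / k  # = 337.5 / K
    if r <= 0:
        raise OpticsDomainError("corneal radius must be positive")
    return r


def standardize_refraction(se_at_5m: float) -> float:
    """Standardize a 5 m lane spherical equivalent to 6 m by adding -0.03 D."""
    if not math.isfinite(se_at_5m):
        raise OpticsDomainError("spherical equivalent must be finite")
    return se_at_5m - 0.03


def destandardize_refraction(se_at_6m: float) -> float:
    """Inverse of :func:`standardize_refraction`."""
    if not math.isfinite(se_at_6m):
        raise OpticsDomainError("spherical equivalent must be finite")
    return se_at_6m + 0.03


def convert_a_to_haigis(a_constant: float) -> tuple[float, float, float]:
    """Fallback Haigis triple from a published A constant.

    Standard single-optimized conversion: a0 = 0.62467*A - 72.434 with the
    default regression slopes a1 = 0.4 (on ACD) and a2 = 0.1 (on AL).
    """
    lo, hi = A_CONSTANT_RANGE
    if not (math.isfinite(a_constant) and lo <= a_constant <= hi):
        raise OpticsDomainError(f"A constant {a_constant!r} outside {A_CONSTANT_RANGE}")
    return (0.62467 * a_constant - 72.434, 0.4, 0.1)


# --- SRK/T -------------------------------------------------------------------


_CLAMP_WARNED = False  # first clamp warns, later ones log at debug


def srkt_lcor(axial_length: float) -> float:
    """Long-eye corrected axial length (mm)."""
    if axial_length <= 24.2:
        return axial_length
    return -3.446 + 1.716 * axial_length - 0.0237 * axial_length**2


def _srkt_geometry(b: Biometry, a_constant: float) -> dict[str, float]:
    k = mean_k(b.k_flat, b.k_steep)
    r = corneal_radius(k)
    lcor = srkt_lcor(b.axial_length)
    cw = -5.41 + 0.58412 * lcor + 0.098 * k
    radicand = r * r - cw * cw / 4.0
    if radicand < 0:
        # classical SRK/T behavior in long, steep eyes: clamp rather than fail
        global _CLAMP_WARNED
        level = logging.DEBUG if _CLAMP_WARNED else logging.WARNING
        logger.log(
            level,
            "SRK/T corneal-height radicand negative (%.4f) for AL=%.2f, K=%.2f; clamping to 0",
            radicand, b.axial_length, k,
        )
        _CLAMP_WARNED = True
        radicand = 0.0
    h = r - math.sqrt(radicand)
    acd_const = 0.62467 * a_constant - 68.747
    offset = acd_const - 3.336
    elp = h + offset
    rethick = 0.65696 - 0.02029 * b.axial_length
    lopt = b.axial_length + rethick
    return {
        "mean_k": k,
        "corneal_radius_r": r,
        "lcor": lcor,
        "corneal_width_cw": cw,
        "corneal_height_h": h,
        "acd_constant": acd_const,
        "offset": offset,
        "elp": elp,
        "retinal_thickness": rethick,
        "optical_axial_length": lopt,
    }


def _srkt_moebius(g: dict[str, float]) -> tuple[float, float, float, float]:
    """Coefficients of REF(P) = (A1 - P*B1) / (C1 - 0.001*P*D1)."""
    na = N_AQUEOUS
    ncm1 = N_CORNEA_SRKT - 1.0
    v = VERTEX_MM
    r, elp, lopt = g["corneal_radius_r"], g["elp"], g["optical_axial_length"]
    if elp >= lopt:
        raise DegenerateGeometryError(
            f"ELP ({elp:.3f} mm) reaches the optical axial length ({lopt:.3f} mm)"
        )
    a1 = 1000.0 * na * (na * r - ncm1 * lopt)
    b1 = (lopt - elp) * (na * r - ncm1 * elp)
    c1 = na * (v * (na * r - ncm1 * lopt) + lopt * r)
    d1 = (lopt - elp) * (v * (na * r - ncm1 * elp) + elp * r)
    return a1, b1, c1, d1


def srkt_predict_refraction(
    b: Biometry, iol_power: float, c: IOLConstants
) -> TheoreticalPrediction:
    """Spectacle-plane refraction predicted by SRK/T for a given IOL power."""
    if not math.isfinite(iol_power):
        raise OpticsDomainError("IOL power must be finite")
    g = _srkt_geometry(b, c.require_a_constant())
    a1, b1, c1, d1 = _srkt_moebius(g)
    ref = (a1 - iol_power * b1) / (c1 - 0.001 * iol_power * d1)
    return TheoreticalPrediction(
        formula_name=FormulaName.SRKT,
        predicted_refraction=ref,
        elp=g["elp"],
        intermediates=g,
    )


def srkt_power_for_refraction(
    b: Biometry,
    c: IOLConstants,
    target: float,
    power_range: Optional[tuple[float, float]] = POWER_RANGE,
) -> float:
    """Closed-form SRK/T IOL power achieving a target spectacle refraction.

    ``power_range=None`` disables the manufacturable-range check and
    returns the exact optical solution.
    """
    if not math.isfinite(target):
        raise OpticsDomainError("target refraction must be finite")
    g = _srkt_geometry(b, c.require_a_constant())
    a1, b1, c1, d1 = _srkt_moebius(g)
    power = (a1 - target * c1) / (b1 - 0.001 * target * d1)
    if power_range is not None:
        lo, hi = power_range
        if not (lo <= power <= hi):
            raise PowerOutOfRangeError(
                f"SRK/T power for target {target:+.2f} D is {power:.2f} D, outside {power_range}"
            )
    return power


def srkt_emmetropia_power(b: Biometry, c: IOLConstants) -> float:
    """SRK/T IOL power for a plano (0 D) outcome."""
    return srkt_power_for_refraction(b, c, 0.0)


# --- Haigis ------------------------------------------------------------------


def haigis_elp(b: Biometry, c: IOLConstants) -> float:
    """Haigis effective lens position d = a0 + a1*ACD + a2*AL (mm)."""
    a0, a1, a2 = c.resolved_haigis()
    return a0 + a1 * b.acd_epithelium_to_lens + a2 * b.axial_length


def _haigis_setup(b: Biometry, c: IOLConstants) -> tuple[float, float]:
    d = haigis_elp(b, c)
    if d <= 0:
        raise OpticsDomainError(f"Haigis ELP must be positive, got {d:.3f} mm")
    if d >= b.axial_length:
        raise DegenerateGeometryError(
            f"Haigis ELP ({d:.3f} mm) reaches the axial length ({b.axial_length:.3f} mm)"
        )
    r = corneal_radius(mean_k(b.k_flat, b.k_steep))
    dc = 1000.0 * (N_CORNEA_HAIGIS - 1.0) / r  # corneal power, D
    return d, dc


def haigis_predict_refraction(
    b: Biometry, iol_power: float, c: IOLConstants
) -> TheoreticalPrediction:
    """Spectacle-plane refraction predicted by the Haigis formula.

    Thin-lens vergence chain with aqueous/vitreous index 1.336: the IOL
    power splits the eye into an image-side requirement n/(AL - d) and an
    object-side vergence whose corneal component is DC; the corneal-plane
    refraction is carried back to the 12 mm spectacle plane.
    """
    if not math.isfinite(iol_power):
        raise OpticsDomainError("IOL power must be finite")
    d, dc = _haigis_setup(b, c)
    n = 1000.0 * N_AQUEOUS  # 1336, works in mm/diopters
    q = n / (b.axial_length - d) - iol_power
    if abs(q) < 1e-12:
        # vergence behind the IOL vanishes: the pre-IOL vergence must be zero
        refc = -dc
    else:
        z = n / (n / q + d)
        refc = z - dc
    ref = refc / (1.0 + (VERTEX_MM / 1000.0) * refc)
    return TheoreticalPrediction(
        formula_name=FormulaName.HAIGIS,
        predicted_refraction=ref,
        elp=d,
        intermediates={"elp": d, "corneal_power": dc},
    )


def haigis_power_for_refraction(
    b: Biometry,
    c: IOLConstants,
    target: float,
    power_range: Optional[tuple[float, float]] = POWER_RANGE,
) -> float:
    """Closed-form Haigis IOL power achieving a target spectacle refraction.

    ``power_range=None`` disables the manufacturable-range check and
    returns the exact optical solution.
    """
    if not math.isfinite(target):
        raise OpticsDomainError("target refraction must be finite")
    d, dc = _haigis_setup(b, c)
    n = 1000.0 * N_AQUEOUS
    refc = target / (1.0 - (VERTEX_MM / 1000.0) * target)  # carry to corneal plane
    z = dc + refc
    power = n / (b.axial_length - d) - n / (n / z - d)
    if power_range is not None:
        lo, hi = power_range
        if not (lo <= power <= hi):
            raise PowerOutOfRangeError(
                f"Haigis power for target {target:+.2f} D is {power:.2f} D, outside {power_range}"
            )
    return power


def haigis_emmetropia_power(b: Biometry, c: IOLConstants) -> float:
    """Haigis IOL power for a plano (0 D) outcome."""
    return haigis_power_for_refraction(b, c, 0.0)


# --- dispatch helpers --------------------------------------------------------

_PREDICTORS = {
    FormulaName.SRKT: srkt_predict_refraction,
    FormulaName.HAIGIS: haigis_predict_refraction,
}
_INVERTERS = {
    FormulaName.SRKT: srkt_power_for_refraction,
    FormulaName.HAIGIS: haigis_power_for_refraction,
}


def predict_refraction(
    formula: FormulaName | str, b: Biometry, iol_power: float, c: IOLConstants
) -> TheoreticalPrediction:
    return _PREDICTORS[FormulaName(formula)](b, iol_power, c)


def power_for_refraction(
    formula: FormulaName | str,
    b: Biometry,
    c: IOLConstants,
    target: float,
    power_range: Optional[tuple[float, float]] = POWER_RANGE,
) -> float:
    return _INVERTERS[FormulaName(formula)](b, c, target, power_range=power_range)
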