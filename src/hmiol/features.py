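"""Cohort ingestion, inclusion screening and feature construction.

A cohort is a list of :class:`SurgicalCase` records read from a flat CSV
(schema documented in :data:`COHORT_COLUMNS`).  Screening enforces the
high-myopia inclusion rules: axial length of at least 26.00 mm, complete
six-field biometry, an observed postoperative spherical equivalent, and
(when recorded) a best-corrected acuity of 20/40 or better.

Two feature sets feed the learners.  Both carry the six biometrics, the
implanted power and the A constant plus the Haigis-predicted refraction;
set 1 additionally carries the SRK/T-predicted refraction.  The formula
features are recomputed at whatever IOL power is being queried, which is
what lets a trained model answer "what if I implant P?" questions.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .optics import (
    Biometry,
    IOLConstants,
    OpticsDomainError,
    haigis_predict_refraction,
    srkt_predict_refraction,
)

#: minimum axial length defining high myopia, mm
HIGH_MYOPIA_AL_MM = 26.00
#: worst acceptable postoperative BCVA, logMAR (20/40 Snellen)
BCVA_LOGMAR_LIMIT = 0.30

#: documented cohort CSV schema ('?' columns optional)
COHORT_COLUMNS = [
    "case_id",
    "patient_id?",
    "eye?",
    "al_mm",
    "k_flat_d",
    "k_steep_d",
    "acd_mm",
    "lt_mm",
    "cd_mm",
    "lens_model",
    "iol_power_d",
    "a_constant?",
    "a0?",
    "a1?",
    "a2?",
    "postop_se_d",
    "postop_bcva_logmar?",
]

_BIOMETRY_FIELDS = {
    "al_mm": "axial_length",
    "k_flat_d": "k_flat",
    "k_steep_d": "k_steep",
    "acd_mm": "acd_epithelium_to_lens",
    "lt_mm": "lens_thickness",
    "cd_mm": "corneal_diameter",
}


class FeatureSet(str, Enum):
    SET1 = "SET1"  # Haigis + SRK/T transforms
    SET2 = "SET2"  # Haigis transform only


FEATURE_NAMES: dict[FeatureSet, tuple[str, ...]] = {
    FeatureSet.SET2: (
        "al_mm",
        "k_flat_d",
        "k_steep_d",
        "acd_mm",
        "lt_mm",
        "cd_mm",
        "iol_power_d",
        "a_constant",
        "haigis_pred_refraction_d",
    ),
    FeatureSet.SET1: (
        "al_mm",
        "k_flat_d",
        "k_steep_d",
        "acd_mm",
        "lt_mm",
        "cd_mm",
        "iol_power_d",
        "a_constant",
        "haigis_pred_refraction_d",
        "srkt_pred_refraction_d",
    ),
}


class RejectionReason(str, Enum):
    AL_BELOW_26 = "AL_BELOW_26"
    INCOMPLETE_BIOMETRY = "INCOMPLETE_BIOMETRY"
    MISSING_POSTOP_SE = "MISSING_POSTOP_SE"
    BCVA_BELOW_20_40 = "BCVA_BELOW_20_40"
    MALFORMED_ROW = "MALFORMED_ROW"


class CohortParseError(ValueError):
    """Malformed cohort row; carries the offending line number."""

    def __init__(self, line: int, message: str) -> None:
        self.line = line
        super().__init__(f"row {line}: {message}")


@dataclass(frozen=True)
class SurgicalCase:
    """One operated eye: biometry, implanted lens, observed outcome."""

    case_id: str
    biometry: Biometry
    lens_model: str
    iol_power_implanted: float
    constants: IOLConstants
    postop_se: float  # spherical equivalent, standardized to 6 m, diopters
    postop_bcva_logmar: Optional[float] = None
    patient_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not (-10.0 <= self.iol_power_implanted <= 40.0):
            raise ValueError(
                f"implanted power {self.iol_power_implanted} D outside [-10, 40] D"
            )


@dataclass(frozen=True)
class Rejection:
    case_id: str
    reason: RejectionReason


@dataclass(frozen=True)
class FeatureVector:
    feature_set_id: FeatureSet
    names: tuple[str, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        expected = FEATURE_NAMES[self.feature_set_id]
        if self.names != expected:
            raise ValueError(f"feature ordering mismatch for {self.feature_set_id}")
        if len(self.values) != len(expected):
            raise ValueError("feature length mismatch")
        if not all(math.isfinite(v) for v in self.values):
            raise ValueError("features must be finite")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


# --- inclusion screening -----------------------------------------------------


def _optional_float(record: Mapping, key: str) -> Optional[float]:
    v = record.get(key)
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return float(v)


def include_case(record: Mapping) -> SurgicalCase | Rejection:
    """Screen one raw cohort record against the inclusion rules.

    Returns the parsed :class:`SurgicalCase` if eligible, otherwise a
    :class:`Rejection` with a machine-readable reason code.
    """
    case_id = str(record.get("case_id", "?"))
    bio_vals = {}
    for col, fld in _BIOMETRY_FIELDS.items():
        v = _optional_float(record, col)
        if v is None or not math.isfinite(v):
            return Rejection(case_id, RejectionReason.INCOMPLETE_BIOMETRY)
        bio_vals[fld] = v
    if bio_vals["axial_length"] < HIGH_MYOPIA_AL_MM:
        return Rejection(case_id, RejectionReason.AL_BELOW_26)
    postop_se = _optional_float(record, "postop_se_d")
    if postop_se is None or not math.isfinite(postop_se):
        return Rejection(case_id, RejectionReason.MISSING_POSTOP_SE)
    bcva = _optional_float(record, "postop_bcva_logmar")
    if bcva is not None and bcva > BCVA_LOGMAR_LIMIT:
        return Rejection(case_id, RejectionReason.BCVA_BELOW_20_40)
    try:
        biometry = Biometry(**bio_vals)
        constants = IOLConstants(
            a_constant=_optional_float(record, "a_constant"),
            a0=_optional_float(record, "a0"),
            a1=_optional_float(record, "a1"),
            a2=_optional_float(record, "a2"),
        )
        return SurgicalCase(
            case_id=case_id,
            biometry=biometry,
            lens_model=str(record.get("lens_model", "")),
            iol_power_implanted=float(record["iol_power_d"]),
            constants=constants,
            postop_se=postop_se,
            postop_bcva_logmar=bcva,
            patient_id=(str(record["patient_id"]) if record.get("patient_id") not in (None, "") else None),
        )
    except (OpticsDomainError, ValueError, KeyError):
        return Rejection(case_id, RejectionReason.MALFORMED_ROW)


# --- feature construction ----------------------------------------------------


def feature_values(
    biometry: Biometry,
    constants: IOLConstants,
    iol_power: float,
    set_id: FeatureSet,
) -> tuple[float, ...]:
    """Ordered feature values for an eye at a queried IOL power."""
    b = biometry
    haigis = haigis_predict_refraction(b, iol_power, constants).predicted_refraction
    base = (
        b.axial_length,
        b.k_flat,
        b.k_steep,
        b.acd_epithelium_to_lens,
        b.lens_thickness,
        b.corneal_diameter,
        iol_power,
        constants.require_a_constant(),
        haigis,
    )
    if set_id is FeatureSet.SET2:
        return base
    srkt = srkt_predict_refraction(b, iol_power, constants).predicted_refraction
    return base + (srkt,)


def build_features(case: SurgicalCase, set_id: FeatureSet) -> FeatureVector:
    """Feature vector for a case at its implanted power (training view)."""
    set_id = FeatureSet(set_id)
    values = feature_values(case.biometry, case.constants, case.iol_power_implanted, set_id)
    return FeatureVector(feature_set_id=set_id, names=FEATURE_NAMES[set_id], values=values)


def design_matrix(cases: Sequence[SurgicalCase], set_id: FeatureSet) -> np.ndarray:
    """Stacked feature matrix (n_cases x n_features) at implanted powers."""
    return np.asarray([build_features(c, set_id).values for c in cases], dtype=float)


def target_vector(cases: Sequence[SurgicalCase]) -> np.ndarray:
    """Training target: observed postoperative spherical equivalent."""
    return np.asarray([c.postop_se for c in cases], dtype=float)


# --- cohort-level operations -------------------------------------------------


def split_cohort(
    cohort: Sequence[SurgicalCase], train_fraction: float = 0.8, seed: int = 0
) -> tuple[list[SurgicalCase], list[SurgicalCase]]:
    """Deterministic random train/test partition; |train| = floor(n * fraction)."""
    n = len(cohort)
    if n < 2:
        raise ValueError("need at least 2 cases to split")
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must lie in (0, 1)")
    n_train = math.floor(n * train_fraction)
    order = np.random.default_rng(seed).permutation(n)
    train = [cohort[i] for i in sorted(order[:n_train])]
    test = [cohort[i] for i in sorted(order[n_train:])]
    return train, test


def al_limit_filter(
    cohort: Sequence[SurgicalCase], max_al: float
) -> tuple[list[SurgicalCase], list[SurgicalCase]]:
    """Split a cohort at an axial-length input limit (closed: AL <= max_al retained).

    Mirrors the exclusion forced by calculators that cap AL input (e.g. at
    35.00 mm) when benchmarking against them.
    """
    if max_al <= HIGH_MYOPIA_AL_MM:
        raise ValueError("max_al must exceed the 26 mm inclusion floor")
    retained = [c for c in cohort if c.biometry.axial_length <= max_al]
    excluded = [c for c in cohort if c.biometry.axial_length > max_al]
    return retained, excluded


class ALSubgroup(str, Enum):
    AL_26_28 = "26.00-28.00"
    AL_28_30 = "28.00-30.00"
    AL_GE_30 = ">=30.00"


#: interior subgroup boundaries (mm); boundary value goes to the upper bin
AL_SUBGROUP_BOUNDARIES = (28.0, 30.0)


def al_subgroup(
    axial_length: float, boundaries: tuple[float, float] = AL_SUBGROUP_BOUNDARIES
) -> ALSubgroup:
    """Half-open axial-length bin [26, b1), [b1, b2), [b2, inf)."""
    if axial_length < HIGH_MYOPIA_AL_MM:
        raise ValueError(f"AL {axial_length} below the {HIGH_MYOPIA_AL_MM} mm inclusion floor")
    b1, b2 = boundaries
    if axial_length < b1:
        return ALSubgroup.AL_26_28
    if axial_length < b2:
        return ALSubgroup.AL_28_30
    return ALSubgroup.AL_GE_30


def dedupe_one_eye_per_patient(
    records: pd.DataFrame, seed: int = 0
) -> pd.DataFrame:
    """Keep one randomly chosen row per patient_id (no-op without that column)."""
    if "patient_id" not in records.columns:
        return records
    rng = np.random.default_rng(seed)
    keep = []
    for _, group in records.groupby("patient_id", sort=True):
        keep.append(group.index[rng.integers(len(group))])
    return records.loc[sorted(keep)].reset_index(drop=True)


# --- CSV I/O -----------------------------------------------------------------


def load_cohort(
    path: str | Path,
    registry=None,
    dedupe_seed: Optional[int] = None,
) -> tuple[list[SurgicalCase], list[Rejection]]:
    """Read a cohort CSV, apply inclusion screening, return (cases, rejections).

    Constants may come per-row (a_constant/a0..a2 columns) or from a
    :class:`hmiol.registry.ConstantsRegistry` keyed by lens_model.
    """
    df = pd.read_csv(path)
    if dedupe_seed is not None:
        df = dedupe_one_eye_per_patient(df, seed=dedupe_seed)
    cases: list[SurgicalCase] = []
    rejections: list[Rejection] = []
    for i, row in enumerate(df.to_dict("records")):
        if registry is not None and "a_constant" not in df.columns:
            try:
                c = registry.resolve(str(row.get("lens_model", "")))
            except KeyError as exc:
                raise CohortParseError(i + 2, str(exc)) from exc
            row = {**row, "a_constant": c.a_constant, "a0": c.a0, "a1": c.a1, "a2": c.a2}
        result = include_case(row)
        if isinstance(result, Rejection):
            rejections.append(result)
        else:
            cases.append(result)
    return cases, rejections


def cohort_to_frame(cases: Iterable[SurgicalCase]) -> pd.DataFrame:
    """Serialize cases to the documented cohort CSV schema."""
    rows = []
    for c in cases:
        b = c.biometry
        rows.append(
            {
                "case_id": c.case_id,
                "patient_id": c.patient_id,
                "al_mm": b.axial_length,
                "k_flat_d": b.k_flat,
                "k_steep_d": b.k_steep,
                "acd_mm": b.acd_epithelium_to_lens,
                "lt_mm": b.lens_thickness,
                "cd_mm": b.corneal_diameter,
                "lens_model": c.lens_model,
                "iol_power_d": c.iol_power_implanted,
                "a_constant": c.constants.a_constant,
                "a0": c.constants.a0,
                "a1": c.constants.a1,
                "a2": c.constants.a2,
                "postop_se_d": c.postop_se,
                "postop_bcva_logmar": c.postop_bcva_logmar,
            }
        )
    return pd.DataFrame(rows)


def save_cohort(cases: Iterable[SurgicalCase], path: str | Path) -> None:
    cohort_to_frame(cases).to_csv(path, index=False)
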