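"""Four-sub-model weighted ensemble predicting postoperative refraction.

Two learner families (gradient-boosted trees via XGBoost, RBF-kernel
support vector regression) are each trained on the two feature sets,
giving four sub-models.  The assembled prediction is a weighted average
of the four outputs; by default the weights are proportional to the
inverse out-of-fold mean absolute error of each sub-model under an
internal 5-fold scheme on the training data (equal weights selectable).
The training target is the observed postoperative spherical equivalent.

Feature standardization is applied inside the SVR pipelines only; the
tree family is scale-invariant.
"""
from __future__ import annotations

import hashlib
import time
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Optional, Sequence

import joblib
import numpy as np
from sklearn.model_selection import KFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from xgboost import XGBRegressor

from .features import (
    FEATURE_NAMES,
    FeatureSet,
    SurgicalCase,
    design_matrix,
    feature_values,
    target_vector,
)
from .optics import Biometry, IOLConstants, POWER_RANGE

ARTIFACT_FORMAT_VERSION = 1
MIN_TRAINING_CASES = 50


class Learner(str, Enum):
    GRADIENT_BOOSTED_TREES = "GRADIENT_BOOSTED_TREES"
    KERNEL_SVR = "KERNEL_SVR"


class WeightMode(str, Enum):
    INVERSE_MAE = "INVERSE_MAE"
    EQUAL = "EQUAL"


#: conservative, reproducibility-first hyperparameter defaults
DEFAULT_HYPERPARAMETERS: dict[Learner, dict] = {
    Learner.GRADIENT_BOOSTED_TREES: {
        "max_depth": 4,
        "n_estimators": 300,
        "learning_rate": 0.05,
    },
    Learner.KERNEL_SVR: {"kernel": "rbf", "C": 10.0, "epsilon": 0.1},
}


class TrainingError(RuntimeError):
    pass


class EnsembleLoadError(RuntimeError):
    pass


@dataclass(frozen=True)
class SubModelSpec:
    learner: Learner
    feature_set: FeatureSet
    hyperparameters: tuple[tuple[str, float | int | str], ...] = ()
    seed: int = 0

    @property
    def key(self) -> str:
        tag = "xgb" if self.learner is Learner.GRADIENT_BOOSTED_TREES else "svr"
        return f"{tag}_{self.feature_set.value.lower()}"

    def resolved_hyperparameters(self) -> dict:
        hp = dict(DEFAULT_HYPERPARAMETERS[self.learner])
        hp.update(dict(self.hyperparameters))
        return hp


def full_ensemble_specs(seed: int = 0, hyperparameters: Optional[Mapping] = None) -> list[SubModelSpec]:
    """The four canonical (learner, feature set) sub-model specs."""
    hp = hyperparameters or {}
    specs = []
    for learner in Learner:
        for fs in (FeatureSet.SET1, FeatureSet.SET2):
            overrides = tuple(sorted(hp.get(learner, {}).items()))
            specs.append(SubModelSpec(learner, fs, overrides, seed=seed))
    return specs


def _make_estimator(spec: SubModelSpec):
    hp = spec.resolved_hyperparameters()
    if spec.learner is Learner.GRADIENT_BOOSTED_TREES:
        return XGBRegressor(
            objective="reg:squarederror",
            random_state=spec.seed,
            n_jobs=1,
            tree_method="hist",
            **hp,
        )
    return make_pipeline(StandardScaler(), SVR(**hp))


def train_submodel(train_cases: Sequence[SurgicalCase], spec: SubModelSpec):
    """Fit one sub-model on a training cohort; deterministic under its seed."""
    if len(train_cases) < MIN_TRAINING_CASES:
        raise TrainingError(
            f"need at least {MIN_TRAINING_CASES} training cases, got {len(train_cases)}"
        )
    X = design_matrix(train_cases, spec.feature_set)
    y = target_vector(train_cases)
    if np.std(y) < 1e-12:
        raise TrainingError("degenerate training target: zero variance in postoperative SE")
    est = _make_estimator(spec)
    est.fit(X, y)
    return est


def fit_weights(validation_maes: Mapping[str, float], mode: WeightMode = WeightMode.INVERSE_MAE) -> dict[str, float]:
    """Combination weights from per-sub-model validation MAEs.

    Inverse-MAE weighting, normalized to sum to one.  A sub-model with
    zero validation MAE (an exact interpolator) takes all the weight.
    """
    keys = list(validation_maes)
    if mode is WeightMode.EQUAL:
        return {k: 1.0 / len(keys) for k in keys}
    maes = np.array([validation_maes[k] for k in keys], dtype=float)
    if np.any(maes < 0):
        raise ValueError("validation MAE cannot be negative")
    zero = maes < 1e-15
    if zero.any():
        w = zero.astype(float) / zero.sum()
    else:
        w = (1.0 / maes) / (1.0 / maes).sum()
    return dict(zip(keys, w))


@dataclass
class TrainedEnsemble:
    """Four fitted sub-models plus their normalized combination weights."""

    sub_models: dict[str, object]
    weights: dict[str, float]
    specs: dict[str, SubModelSpec]
    feature_schema: dict[str, tuple[str, ...]]
    training_metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.sub_models) != set(self.weights):
            raise ValueError("sub-model keys and weight keys differ")
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-12 or any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be non-negative and sum to 1")

    # -- prediction -----------------------------------------------------------

    def submodel_predictions(
        self, biometry: Biometry, constants: IOLConstants, iol_power: float
    ) -> dict[str, float]:
        out = {}
        for key, est in self.sub_models.items():
            fs = self.specs[key].feature_set
            x = np.asarray(
                [feature_values(biometry, constants, iol_power, fs)], dtype=float
            )
            out[key] = float(est.predict(x)[0])
        return out

    def predict_refraction(
        self, biometry: Biometry, constants: IOLConstants, iol_power: float
    ) -> float:
        """Weighted-average predicted postoperative SE at a queried power."""
        lo, hi = POWER_RANGE
        if not (lo <= iol_power <= hi):
            raise ValueError(f"IOL power {iol_power} D outside {POWER_RANGE}")
        preds = self.submodel_predictions(biometry, constants, iol_power)
        return sum(self.weights[k] * preds[k] for k in preds)

    def predict_case(self, case: SurgicalCase, iol_power: Optional[float] = None) -> float:
        power = case.iol_power_implanted if iol_power is None else iol_power
        return self.predict_refraction(case.biometry, case.constants, power)

    def predict_cases(self, cases: Sequence[SurgicalCase]) -> np.ndarray:
        return np.asarray([self.predict_case(c) for c in cases], dtype=float)


def predict_se(ensemble: TrainedEnsemble, case: SurgicalCase, iol_power: float) -> float:
    """Ensemble predicted postoperative SE for a case at a queried power."""
    return ensemble.predict_case(case, iol_power)


def _cohort_hash(cases: Sequence[SurgicalCase]) -> str:
    h = hashlib.sha256()
    for c in cases:
        h.update(repr((c.case_id, c.biometry, c.iol_power_implanted, c.postop_se)).encode())
    return h.hexdigest()[:16]


def train_ensemble(
    train_cases: Sequence[SurgicalCase],
    seed: int = 0,
    weight_mode: WeightMode = WeightMode.INVERSE_MAE,
    hyperparameters: Optional[Mapping] = None,
    n_weight_folds: int = 5,
) -> TrainedEnsemble:
    """Train the full four-sub-model ensemble.

    Weights come from out-of-fold MAEs under an internal K-fold split of
    the training cohort (so the validation folds are disjoint from the
    folds used to fit each fold-model); the final sub-models are then
    refit on the whole training cohort.
    """
    specs = full_ensemble_specs(seed=seed, hyperparameters=hyperparameters)
    cases = list(train_cases)
    if weight_mode is WeightMode.INVERSE_MAE:
        kf = KFold(n_splits=n_weight_folds, shuffle=True, random_state=seed)
        idx = np.arange(len(cases))
        oof_maes: dict[str, float] = {}
        y = target_vector(cases)
        for spec in specs:
            X = design_matrix(cases, spec.feature_set)
            oof = np.empty(len(cases))
            for tr, va in kf.split(idx):
                est = _make_estimator(spec)
                est.fit(X[tr], y[tr])
                oof[va] = est.predict(X[va])
            oof_maes[spec.key] = float(np.mean(np.abs(oof - y)))
        weights = fit_weights(oof_maes, WeightMode.INVERSE_MAE)
    else:
        oof_maes = {}
        weights = fit_weights({s.key: 1.0 for s in specs}, WeightMode.EQUAL)

    sub_models = {spec.key: train_submodel(cases, spec) for spec in specs}
    meta = {
        "n_train": len(cases),
        "cohort_hash": _cohort_hash(cases),
        "seed": seed,
        "weight_mode": weight_mode.value,
        "oof_maes": oof_maes,
        "trained_at_unix": time.time(),
    }
    return TrainedEnsemble(
        sub_models=sub_models,
        weights=weights,
        specs={s.key: s for s in specs},
        feature_schema={fs.value: FEATURE_NAMES[fs] for fs in FeatureSet},
        training_metadata=meta,
    )


# --- persistence -------------------------------------------------------------


def save_ensemble(ensemble: TrainedEnsemble, path: str | Path) -> None:
    """Persist the ensemble as a single portable artifact."""
    payload = {
        "format_version": ARTIFACT_FORMAT_VERSION,
        "feature_schema": ensemble.feature_schema,
        "weights": ensemble.weights,
        "specs": ensemble.specs,
        "sub_models": ensemble.sub_models,
        "training_metadata": ensemble.training_metadata,
    }
    joblib.dump(payload, path)


def load_ensemble(path: str | Path) -> TrainedEnsemble:
    """Load a persisted ensemble, validating version tag and feature schema."""
    try:
        payload = joblib.load(path)
    except Exception as exc:  # empty/corrupt file
        raise EnsembleLoadError(f"cannot read ensemble artifact {path}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format_version") != ARTIFACT_FORMAT_VERSION:
        raise EnsembleLoadError(
            f"unsupported artifact format version {getattr(payload, 'get', lambda *_: '?')('format_version')}"
        )
    expected_schema = {fs.value: FEATURE_NAMES[fs] for fs in FeatureSet}
    schema = {k: tuple(v) for k, v in payload.get("feature_schema", {}).items()}
    if schema != expected_schema:
        raise EnsembleLoadError("feature schema in artifact does not match this package version")
    return TrainedEnsemble(
        sub_models=payload["sub_models"],
        weights=payload["weights"],
        specs=payload["specs"],
        feature_schema=schema,
        training_metadata=payload.get("training_metadata", {}),
    )
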