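"""Clinical forward use: pick the IOL power that best hits a target refraction.

The planner evaluates the trained ensemble (or any refraction predictor)
over an exhaustive grid of manufacturable powers and selects the power
whose predicted postoperative SE is closest to the surgeon's target.
Ties break toward the higher power — the more myopic outcome — which is
the conventional safe direction for eyes that must not end up hyperopic.
An optional mode excludes any candidate predicted to land on the
hyperopic side of the target.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Protocol

import numpy as np

from .optics import Biometry, IOLConstants

logger = logging.getLogger(__name__)

DEFAULT_GRID = (-5.0, 35.0, 0.5)  # min, max, step (diopters)


class RefractionPredictor(Protocol):
    def predict_refraction(
        self, biometry: Biometry, constants: IOLConstants, iol_power: float
    ) -> float: ...


@dataclass(frozen=True)
class PowerPlan:
    """Result of an inverse power search."""

    selected_power: float
    predicted_refraction: float
    target_refraction: float
    candidate_table: tuple[tuple[float, float], ...]  # (power, predicted SE), sorted by power

    def as_rows(self) -> list[dict[str, float]]:
        return [
            {"iol_power_d": p, "predicted_se_d": r, "selected": p == self.selected_power}
            for p, r in self.candidate_table
        ]


def power_grid(grid_min: float, grid_max: float, step: float) -> np.ndarray:
    if step <= 0:
        raise ValueError("grid step must be positive")
    n = int(round((grid_max - grid_min) / step))
    grid = grid_min + step * np.arange(n + 1)
    grid = grid[grid <= grid_max + 1e-9]
    if grid.size == 0:
        raise ValueError("empty power grid")
    return grid


def select_iol_power(
    predictor: RefractionPredictor | Callable[[Biometry, IOLConstants, float], float],
    biometry: Biometry,
    constants: IOLConstants,
    target: float,
    grid_min: float = DEFAULT_GRID[0],
    grid_max: float = DEFAULT_GRID[1],
    step: float = DEFAULT_GRID[2],
    avoid_hyperopic: bool = False,
) -> PowerPlan:
    """Exhaustive-grid inverse search for the optimal IOL power.

    Parameters
    ----------
    predictor
        A trained ensemble (anything with ``predict_refraction``) or a
        bare callable ``(biometry, constants, power) -> predicted SE``.
    target
        Desired postoperative spherical equivalent, diopters.  No range
        restriction is imposed: extreme myopes may legitimately target
        strongly myopic outcomes.
    avoid_hyperopic
        If true, restrict candidates to predictions at or below (more
        myopic than) the target; falls back to the unrestricted search,
        with a warning, when no candidate qualifies.
    """
    if not math.isfinite(target):
        raise ValueError("target refraction must be finite")
    fn = predictor.predict_refraction if hasattr(predictor, "predict_refraction") else predictor
    grid = power_grid(grid_min, grid_max, step)
    preds = np.asarray([fn(biometry, constants, p) for p in grid], dtype=float)
    table = tuple(zip(grid.tolist(), preds.tolist()))

    mask = np.ones_like(grid, dtype=bool)
    if avoid_hyperopic:
        mask = preds <= target + 1e-12
        if not mask.any():
            logger.warning(
                "no candidate avoids a hyperopic outcome for target %+.2f D; "
                "falling back to the unrestricted search",
                target,
            )
            mask = np.ones_like(grid, dtype=bool)

    gaps = np.abs(preds - target)
    gaps_masked = np.where(mask, gaps, np.inf)
    best_gap = gaps_masked.min()
    # tie -> highest power (most myopic predicted outcome)
    best_idx = int(np.flatnonzero(gaps_masked <= best_gap + 1e-12).max())
    return PowerPlan(
        selected_power=float(grid[best_idx]),
        predicted_refraction=float(preds[best_idx]),
        target_refraction=target,
        candidate_table=table,
    )
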