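"""Lens-constant registry: map lens-model names to their calibration constants.

The registry is a plain CSV (``lens_model, a_constant, a0, a1, a2``) so
surgeons can maintain it alongside their cohort exports.  When a lens
model lacks a published Haigis triple the SRK/T A constant is converted
via :func:`hmiol.optics.convert_a_to_haigis` (logged, since single-
optimized conversions are less accurate than triple-optimized constants).
"""
from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .optics import IOLConstants

logger = logging.getLogger(__name__)


class ConstantsRegistry:
    """In-memory lens-model -> :class:`IOLConstants` lookup."""

    def __init__(self, entries: dict[str, IOLConstants] | None = None) -> None:
        self._entries: dict[str, IOLConstants] = dict(entries or {})

    def __contains__(self, lens_model: str) -> bool:
        return lens_model in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def add(self, lens_model: str, constants: IOLConstants) -> None:
        self._entries[lens_model] = constants

    def resolve(self, lens_model: str) -> IOLConstants:
        try:
            c = self._entries[lens_model]
        except KeyError:
            raise KeyError(f"lens model {lens_model!r} not in constants registry") from None
        if c.a0 is None:
            logger.info("lens model %r has no Haigis triple; deriving from A constant", lens_model)
        return c

    @classmethod
    def from_csv(cls, path: str | Path) -> "ConstantsRegistry":
        df = pd.read_csv(path)
        required = {"lens_model"}
        if not required.issubset(df.columns):
            raise ValueError(f"registry CSV must have columns {sorted(required)}")
        entries: dict[str, IOLConstants] = {}
        for _, row in df.iterrows():
            kwargs = {}
            for col in ("a_constant", "a0", "a1", "a2"):
                if col in df.columns and pd.notna(row.get(col)):
                    kwargs[col] = float(row[col])
            entries[str(row["lens_model"])] = IOLConstants(**kwargs)
        return cls(entries)

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {
                "lens_model": name,
                "a_constant": c.a_constant,
                "a0": c.a0,
                "a1": c.a1,
                "a2": c.a2,
            }
            for name, c in self._entries.items()
        ]
        pd.DataFrame(rows).to_csv(path, index=False)
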