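"""Arterial input function extraction from an aorta region.

The kinetic model is driven by the *plasma* concentration Cp(t).  The mean
concentration over an aorta mask is whole-blood concentration, so it is
divided by (1 - hematocrit); set ``hematocrit=0`` to disable the
correction.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DimensionError, InvalidInputError
from .relaxometry import ConcentrationSeries


@dataclass
class AifCurve:
    """Plasma contrast concentration over time, mmol/L."""

    times: np.ndarray
    cp: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.cp = np.asarray(self.cp, dtype=float)
        if self.times.shape != self.cp.shape or self.times.ndim != 1:
            raise InvalidInputError("times and cp must be 1D vectors of equal length")
        if not np.all(np.isfinite(self.cp)):
            raise InvalidInputError("cp must be finite")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"time_s": self.times, "cp_mmol_per_L": self.cp}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "AifCurve":
        df = pd.read_csv(path)
        return cls(times=df["time_s"].to_numpy(), cp=df["cp_mmol_per_L"].to_numpy())


def extract_aif(
    conc: ConcentrationSeries,
    aorta_mask: np.ndarray,
    hematocrit: float = 0.42,
) -> AifCurve:
    """Mean blood concentration over the aorta mask, converted to plasma.

    Cp(t) = mean_{mask} C_blood(t) / (1 - hematocrit).  The mean (not the
    median) is used because the region is assumed hand-picked; voxel order
    inside the mask is irrelevant.
    """
    mask = np.asarray(aorta_mask, dtype=bool)
    if mask.shape != conc.conc.shape[:3]:
        raise DimensionError("aorta mask grid does not match the concentration grid")
    if not mask.any():
        raise InvalidInputError("aorta mask is empty")
    if not 0 <= hematocrit < 1:
        raise InvalidInputError("hematocrit must be in [0, 1)")
    blood = conc.conc[mask].mean(axis=0)
    return AifCurve(times=conc.times.copy(), cp=blood / (1.0 - hematocrit))
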