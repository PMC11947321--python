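"""Explant histomorphometry: maturation score, overall score, thickness profiles.

An explant section is segmented upstream into five pixel classes — bone, bone
marrow, cartilage, fibrous tissue and background — and quantified as areas in
one arbitrary common unit.  The ossicle maturation score expresses how far a
cartilage template has remodelled into bone:

    maturation = 100 · (bone + bone_marrow) / (bone + bone_marrow + cartilage + fibrous)

Background is excluded from the denominator.  Because every implant starts
from the same cell number, an overall score additionally weights maturation by
the mineralized volume produced: ``overall = maturation/100 × volume`` (mm³),
the simplest combination monotone in both inputs, reported alongside both so
alternatives can be recomputed.  Mineral-thickness distribution profiles are
compared between replicates as standardized measures (z-scores over bins).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError

TISSUES = ("bone", "bone_marrow", "cartilage", "fibrous")
AREA_COLUMNS = TISSUES + ("background",)


@dataclass
class OssicleScore:
    """Per-explant scores: maturation (%), volume (mm³), overall (mm³)."""

    maturation: float
    volume: float | None = None

    @property
    def overall(self) -> float | None:
        if self.volume is None or np.isnan(self.maturation):
            return None
        return overall_score(self.maturation, self.volume)


def maturation_score(areas: Mapping[str, float] | pd.Series) -> float:
    """Ossicle maturation: percentage of tissue area that is bone or marrow.

    Returns NaN (with a warning) when all four tissue areas are zero.
    """
    a = {t: float(areas[t]) for t in TISSUES}
    if any(v < 0 for v in a.values()):
        raise ValidationError("tissue areas must be ≥ 0")
    total = sum(a.values())
    if total == 0:
        warnings.warn("all tissue areas zero; maturation score undefined", stacklevel=2)
        return float("nan")
    return 100.0 * (a["bone"] + a["bone_marrow"]) / total


def overall_score(maturation: float, volume: float) -> float:
    """Volume-weighted maturation: ``maturation/100 × volume``."""
    if volume < 0:
        raise ValidationError("volume must be ≥ 0")
    if not 0.0 <= maturation <= 100.0:
        raise ValidationError("maturation must be a percentage in [0, 100]")
    return maturation / 100.0 * volume


def standardize_profile(frequencies: Iterable[float]) -> np.ndarray:
    """Z-score a thickness-distribution profile over its bins (sample SD, n−1).

    Constant profiles are rejected: a zero-variance profile carries no shape.
    """
    f = np.asarray(list(frequencies) if not isinstance(frequencies, np.ndarray) else frequencies, dtype=float)
    if f.ndim != 1 or f.size < 2:
        raise ValidationError("profile needs ≥ 2 bins")
    sd = f.std(ddof=1)
    if sd == 0:
        raise ValidationError("constant profile has zero variance; cannot standardize")
    return (f - f.mean()) / sd


def aggregate_explant(
    sections: pd.DataFrame, volume: float | None = None
) -> OssicleScore:
    """Score one explant from its sections' areas.

    Areas are summed across sections before scoring (area-weighted pooling,
    so tissue-rich sections count more), then the maturation and, when a
    volume is given, the overall score are computed.
    """
    if len(sections) == 0:
        raise ValidationError("explant has no sections")
    for col in TISSUES:
        if col not in sections.columns:
            raise ValidationError(f"section table lacks column {col!r}")
    pooled = sections[list(TISSUES)].sum(axis=0)
    return OssicleScore(maturation=maturation_score(pooled), volume=volume)


def score_explants(
    area_table: pd.DataFrame, volumes: Mapping[str, float] | pd.Series | None = None
) -> pd.DataFrame:
    """Score every explant in a sections table.

    ``area_table`` has one row per (explant, section) with tissue-area
    columns; ``volumes`` optionally maps explant → mineralized volume (mm³).
    Returns a per-explant frame with maturation, volume and overall score.
    """
    if "explant" not in area_table.columns:
        raise ValidationError("area table lacks an 'explant' column")
    rows = []
    for explant, sections in area_table.groupby("explant", sort=False):
        vol = None if volumes is None else float(volumes[explant])
        score = aggregate_explant(sections, volume=vol)
        rows.append(
            {
                "explant": explant,
                "n_sections": len(sections),
                "maturation": score.maturation,
                "volume": score.volume,
                "overall": score.overall,
            }
        )
    return pd.DataFrame(rows).set_index("explant")
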