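"""Overlap classification of three transcriptome contrasts.

Given differential-expression tables for HyC-vs-basal, FiC-vs-basal and
HyC-vs-FiC over one shared gene universe, every gene is assigned to exactly
one class by set algebra on significance calls:

* ``common_chondrogenic`` — significant versus the control in both treated
  groups, in the same direction, and not different between the treated groups.
* ``hyc_specific`` — significant in HyC-vs-basal and in HyC-vs-FiC.
* ``fic_specific`` — significant in FiC-vs-basal and in HyC-vs-FiC.
* ``unclassified`` — everything else, including conflicting combinations
  (e.g. opposite directions versus control with no treated difference).

A gene significant in all three contrasts shows group-specific magnitude and
is assigned to the side favoured by the HyC-vs-FiC direction.  Significance
means FDR < ``fdr_max`` and |log2FC| > ``log2fc_min`` (default 0:
significance-only mode).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

CLASSES = ("common_chondrogenic", "hyc_specific", "fic_specific", "unclassified")


@dataclass(frozen=True)
class DEGThresholds:
    fdr_max: float = 0.05
    log2fc_min: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fdr_max <= 1.0:
            raise ValidationError("fdr_max must be in [0, 1]")
        if self.log2fc_min < 0:
            raise ValidationError("log2fc_min must be ≥ 0")


@dataclass
class OverlapPartition:
    """Gene → class assignment plus per-class counts."""

    assignments: pd.Series
    counts: dict[str, int]

    def genes(self, cls: str) -> pd.Index:
        return self.assignments.index[self.assignments == cls]


def _require_columns(table: pd.DataFrame, name: str) -> None:
    for col in ("log2fc", "fdr"):
        if col not in table.columns:
            raise ValidationError(f"{name}: missing column {col!r}")


def classify_gene_sets(
    de_hyc_basal: pd.DataFrame,
    de_fic_basal: pd.DataFrame,
    de_hyc_fic: pd.DataFrame,
    thr: DEGThresholds = DEGThresholds(),
) -> OverlapPartition:
    """Partition the shared gene universe into overlap classes.

    Each table is indexed by gene with columns ``log2fc`` and ``fdr``;
    the three tables must share one gene universe.
    """
    tables = {
        "HyC_vs_basal": de_hyc_basal,
        "FiC_vs_basal": de_fic_basal,
        "HyC_vs_FiC": de_hyc_fic,
    }
    for name, t in tables.items():
        _require_columns(t, name)
        if not t.index.is_unique:
            raise ValidationError(f"{name}: duplicate gene ids")
    universe = de_hyc_basal.index
    for name, t in tables.items():
        diff = universe.symmetric_difference(t.index)
        if len(diff):
            raise ValidationError(
                f"gene universes differ ({name}): {sorted(map(str, diff))[:10]}"
            )
    fic = de_fic_basal.loc[universe]
    hf = de_hyc_fic.loc[universe]
    hyc = de_hyc_basal

    def sig(t: pd.DataFrame) -> np.ndarray:
        return (
            (t["fdr"].to_numpy() < thr.fdr_max)
            & (t["log2fc"].abs().to_numpy() > thr.log2fc_min)
        )

    a, b, c = sig(hyc), sig(fic), sig(hf)
    sign_a = np.sign(hyc["log2fc"].to_numpy())
    sign_b = np.sign(fic["log2fc"].to_numpy())
    up_in_hyc = hf["log2fc"].to_numpy() > 0

    cls = np.full(len(universe), "unclassified", dtype=object)
    common = a & b & ~c & (sign_a == sign_b)
    cls[common] = "common_chondrogenic"
    cls[a & ~b & c] = "hyc_specific"
    cls[~a & b & c] = "fic_specific"
    three_way = a & b & c
    cls[three_way & up_in_hyc] = "hyc_specific"
    cls[three_way & ~up_in_hyc] = "fic_specific"

    assignments = pd.Series(cls, index=universe, name="overlap_class")
    counts = {k: int((assignments == k).sum()) for k in CLASSES}
    return OverlapPartition(assignments=assignments, counts=counts)
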