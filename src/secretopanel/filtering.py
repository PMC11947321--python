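"""Detection, low-read and coverage filters.

The filter funnel runs in a fixed order on a :class:`~secretopanel.io.QuantMatrix`:

1. :func:`clean_low_reads` — intensities below a floor (default 5) become
   missing; low quantities are treated as not identified.
2. :func:`collapse_technical_replicates` — a protein counts as *detected* in a
   biological sample only if at least a fraction (default 2/3) of that
   sample's technical replicates carry a value; the collapsed abundance is the
   mean over the detected replicates.
3. :func:`compute_coverage` — per-group identification coverage: the fraction
   of a group's biological samples in which the protein is detected.
4. :func:`apply_coverage_filter` — a protein is retained iff its best
   per-group coverage reaches the keep threshold (default 70%).

The published removal sentence conjoins a "below 30% within the experimental
groups" clause with the 70%-in-one-condition clause; the 70% rule subsumes the
30% rule (a protein under 30% everywhere has no group at 70%), so retention is
decided by the 70% rule alone while both clauses are evaluated and reported in
the removal log for transparency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import QuantMatrix

_EPS = 1e-9  # guards ratio-vs-threshold comparisons against float dust


@dataclass(frozen=True)
class FilterThresholds:
    """Thresholds of the identification filter funnel.

    Attributes
    ----------
    low_read
        Intensities strictly below this are set to missing (default 5).
    replicate_fraction
        Minimum fraction of a sample's technical replicates that must carry a
        value for the protein to count as detected in that sample (default 2/3).
    group_floor
        Reporting-only coverage floor (default 0.30): proteins below it in
        every group are flagged in the removal log.
    condition_keep
        Retention threshold: keep a protein iff some group's coverage is at
        least this (default 0.70).
    """

    low_read: float = 5.0
    replicate_fraction: float = 2.0 / 3.0
    group_floor: float = 0.30
    condition_keep: float = 0.70

    def __post_init__(self) -> None:
        if self.low_read < 0:
            raise ValidationError("low_read must be ≥ 0")
        for name in ("replicate_fraction", "group_floor", "condition_keep"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")


@dataclass
class DetectionMatrix:
    """Per-sample detection calls after technical-replicate collapse.

    ``detected`` is a protein × sample boolean frame; ``values`` holds the
    collapsed abundance (mean over detected replicates) where detected and
    NaN elsewhere; ``sample_groups`` maps sample → group.
    """

    detected: pd.DataFrame
    values: pd.DataFrame
    sample_groups: pd.Series

    def __post_init__(self) -> None:
        if not self.detected.columns.equals(self.values.columns) or not (
            self.detected.index.equals(self.values.index)
        ):
            raise ValidationError("detected and values must share shape and labels")
        if (self.values.notna() != self.detected).to_numpy().any():
            raise ValidationError(
                "collapsed value must be present exactly where detected"
            )

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.sample_groups))


def clean_low_reads(
    quant: QuantMatrix, thresholds: FilterThresholds = FilterThresholds()
) -> QuantMatrix:
    """Set every intensity strictly below ``low_read`` to missing.

    Values at or above the floor pass through unchanged; no rows are dropped.
    """
    values = quant.values.where(quant.values >= thresholds.low_read)
    return QuantMatrix(values=values, runs=quant.runs.copy())


def collapse_technical_replicates(
    quant: QuantMatrix, thresholds: FilterThresholds = FilterThresholds()
) -> DetectionMatrix:
    """Collapse runs to per-sample detection calls and mean abundances.

    A protein is detected in a sample iff at least ``replicate_fraction`` of
    that sample's runs carry a value; the collapsed abundance is the
    arithmetic mean over the non-missing replicate values.  A sample with a
    single run uses that run directly.
    """
    samples = quant.samples
    sample_groups = quant.sample_groups()
    detected = pd.DataFrame(index=quant.protein_ids, columns=samples, dtype=bool)
    collapsed = pd.DataFrame(index=quant.protein_ids, columns=samples, dtype=float)
    run_sample = quant.runs["sample_id"]
    for sample in samples:
        cols = run_sample.index[run_sample == sample]
        if len(cols) == 0:  # unreachable through QuantMatrix, kept defensive
            raise ValidationError(f"sample {sample!r} has no runs")
        block = quant.values[list(cols)]
        n_present = block.notna().sum(axis=1)
        det = n_present >= thresholds.replicate_fraction * len(cols) - _EPS
        detected[sample] = det
        collapsed[sample] = block.mean(axis=1).where(det)
    return DetectionMatrix(
        detected=detected, values=collapsed, sample_groups=sample_groups
    )


def compute_coverage(det: DetectionMatrix) -> pd.DataFrame:
    """Per-group identification coverage: detected samples / group size."""
    return det.detected.T.groupby(det.sample_groups).mean().T


def apply_coverage_filter(
    cov: pd.DataFrame, thresholds: FilterThresholds = FilterThresholds()
) -> tuple[pd.Index, pd.DataFrame]:
    """Retain proteins whose best per-group coverage reaches ``condition_keep``.

    Returns the retained protein index and a removal log: one row per removed
    protein with its per-group coverages, whether it also fell below
    ``group_floor`` in every group, and the removal reason.
    """
    if cov.shape[1] < 2:
        raise ValidationError("coverage filter needs ≥ 2 groups")
    keep = (cov.max(axis=1) + _EPS) >= thresholds.condition_keep
    removed = cov.loc[~keep].copy()
    removed["below_floor_everywhere"] = (
        (removed + _EPS) < thresholds.group_floor
    ).all(axis=1)
    removed["reason"] = np.where(
        removed["below_floor_everywhere"],
        f"coverage < {thresholds.group_floor:.0%} in every group",
        f"no group with coverage ≥ {thresholds.condition_keep:.0%}",
    )
    return cov.index[keep], removed


def run_filters(
    quant: QuantMatrix, thresholds: FilterThresholds = FilterThresholds()
) -> tuple[DetectionMatrix, pd.DataFrame, pd.Index, pd.DataFrame]:
    """Run the full funnel; returns (detection, coverage, retained, removal log)."""
    cleaned = clean_low_reads(quant, thresholds)
    det = collapse_technical_replicates(cleaned, thresholds)
    cov = compute_coverage(det)
    retained, removal_log = apply_coverage_filter(cov, thresholds)
    return det, cov, retained, removal_log


def identified_per_sample(det: DetectionMatrix) -> pd.Series:
    """Number of identified proteins per biological sample (after collapse)."""
    return det.detected.sum(axis=0)
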