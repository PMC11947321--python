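"""Localization restriction and biomarker-panel selection.

Two panel families are derived from the filtered, tested secretome:

* **group-specific panels** — proteins fully covered (100% of samples) in
  their target group that are strongly and significantly enriched over the
  other groups (log2FC > 2, FDR < 0.05).  By default enrichment must hold
  against *each* other group (pairwise mode), which makes distinct groups'
  panels provably disjoint and keeps the treatment-common panel out of them;
  a one-vs-rest mode (enrichment over the pooled remaining groups) is
  available by flag, and the one-vs-rest statistics are recorded for every
  member in either mode.
* **treatment-common panel** — proteins fully covered in both treated groups,
  enriched (log2FC > 2, FDR < 0.05) over the control in both treated-vs-control
  contrasts, and *equivalent* between the treated groups under the operational
  no-difference rule |log2FC| < 2 and FDR > 0.05.  The FDR > 0.05 clause is a
  literal conjunction even where it conflicts with small-fold-change
  intuition.

Members are additionally flagged ``exclusive`` when they are detected in zero
samples of every non-target group — the strictest reading of an exclusive
marker.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError, UsageError, ValidationError
from .filtering import DetectionMatrix
from .io import localization_of

SECRETED_ONLY = "secreted_only"
SECRETED_AND_MEMBRANE = "secreted_and_membrane"

_MODE_LABELS = {
    SECRETED_ONLY: frozenset({"extracellular"}),
    SECRETED_AND_MEMBRANE: frozenset({"extracellular", "membrane"}),
}


@dataclass(frozen=True)
class PanelCriteria:
    """Membership thresholds for biomarker panels.

    ``coverage_required`` applies to the target group(s) (default 100%);
    enrichment needs ``log2fc_min`` exceeded and ``fdr_max`` undercut;
    the treated-groups equivalence rule needs |log2FC| below
    ``equivalence_log2fc_max`` and FDR above ``equivalence_fdr_min``.
    """

    coverage_required: float = 1.0
    log2fc_min: float = 2.0
    fdr_max: float = 0.05
    equivalence_log2fc_max: float = 2.0
    equivalence_fdr_min: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.coverage_required <= 1.0:
            raise ValidationError("coverage_required must be in [0, 1]")
        for name in ("fdr_max", "equivalence_fdr_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.equivalence_log2fc_max < 0:
            raise ValidationError("equivalence_log2fc_max must be ≥ 0")


@dataclass
class BiomarkerPanel:
    """A named protein panel with per-member admission records."""

    name: str
    panel_class: str  # "group_specific" | "treatment_common"
    target_groups: tuple[str, ...]
    members: pd.DataFrame
    criteria: PanelCriteria = field(default_factory=PanelCriteria)

    @property
    def protein_ids(self) -> pd.Index:
        return self.members.index

    def __len__(self) -> int:
        return len(self.members)


def filter_by_localization(
    proteins: Iterable[str], loc: pd.Series, mode: str = SECRETED_ONLY
) -> pd.Index:
    """Keep proteins whose localization label matches ``mode``.

    ``secreted_only`` keeps extracellular proteins; ``secreted_and_membrane``
    additionally keeps membrane proteins.  Unknown and unlisted proteins are
    excluded in both modes.
    """
    if mode not in _MODE_LABELS:
        raise ConfigurationError(
            f"unknown localization mode {mode!r}; expected one of {sorted(_MODE_LABELS)}"
        )
    idx = pd.Index(proteins)
    labels = localization_of(loc, idx)
    return idx[labels.isin(_MODE_LABELS[mode])]


def _lookup_pairwise(
    de: Mapping[str, pd.DataFrame], a: str, b: str
) -> tuple[pd.DataFrame, float]:
    """Find the pairwise table for (a, b) in either orientation.

    Returns the table and a sign (+1 if oriented a-vs-b, −1 if reversed, so
    ``sign * log2fc`` is always the a-minus-b fold change).
    """
    if f"{a}_vs_{b}" in de:
        return de[f"{a}_vs_{b}"], 1.0
    if f"{b}_vs_{a}" in de:
        return de[f"{b}_vs_{a}"], -1.0
    raise ConfigurationError(f"missing pairwise contrast between {a!r} and {b!r}")


def select_group_panel(
    group: str,
    de: Mapping[str, pd.DataFrame],
    cov: pd.DataFrame,
    det: DetectionMatrix,
    criteria: PanelCriteria = PanelCriteria(),
    candidates: Iterable[str] | None = None,
    mode: str = "pairwise",
) -> BiomarkerPanel:
    """Derive the biomarker panel specific to ``group``.

    ``de`` maps contrast names (``a_vs_b`` / ``g_vs_rest``) to result tables.
    ``candidates`` is the localization-restricted protein set to evaluate
    (defaults to all proteins present in the required tables).
    """
    if group not in cov.columns:
        raise ConfigurationError(f"unknown group {group!r}")
    others = [g for g in cov.columns if g != group]
    ovr_name = f"{group}_vs_rest"

    if mode == "pairwise":
        needed = [_lookup_pairwise(de, group, g) for g in others]
    elif mode == "one_vs_rest":
        if ovr_name not in de:
            raise ConfigurationError(f"missing contrast {ovr_name!r}")
        needed = [(de[ovr_name], 1.0)]
    else:
        raise ConfigurationError(f"unknown panel mode {mode!r}")

    universe = needed[0][0].index
    for table, _ in needed[1:]:
        universe = universe.intersection(table.index)
    idx = universe if candidates is None else universe.intersection(pd.Index(candidates))

    keep = cov.loc[idx, group] >= criteria.coverage_required - 1e-12
    record = pd.DataFrame(index=idx)
    record[f"coverage_{group}"] = cov.loc[idx, group]
    for g in others:
        record[f"coverage_{g}"] = cov.loc[idx, g]
    for (table, sign), g in zip(needed, others if mode == "pairwise" else ["rest"]):
        fc = sign * table.loc[idx, "log2fc"]
        fdr = table.loc[idx, "fdr"]
        record[f"log2fc_vs_{g}"] = fc
        record[f"fdr_vs_{g}"] = fdr
        keep &= (fc > criteria.log2fc_min) & (fdr < criteria.fdr_max)
    if ovr_name in de and mode == "pairwise":
        ovr = de[ovr_name]
        shared = idx.intersection(ovr.index)
        record.loc[shared, "log2fc_vs_rest"] = ovr.loc[shared, "log2fc"]
        record.loc[shared, "fdr_vs_rest"] = ovr.loc[shared, "fdr"]

    other_samples = det.sample_groups.index[~det.sample_groups.eq(group)]
    record["exclusive"] = det.detected.loc[idx, list(other_samples)].sum(axis=1) == 0

    members = record.loc[keep.fillna(False)].copy()
    return BiomarkerPanel(
        name=f"{group}_specific",
        panel_class="group_specific",
        target_groups=(group,),
        members=members,
        criteria=criteria,
    )


def select_common_panel(
    de: Mapping[str, pd.DataFrame],
    cov: pd.DataFrame,
    det: DetectionMatrix,
    criteria: PanelCriteria = PanelCriteria(),
    candidates: Iterable[str] | None = None,
    treated: Sequence[str] = ("FiC", "HyC"),
    control: str = "basal",
) -> BiomarkerPanel:
    """Derive the panel common to both treated groups.

    Membership needs full coverage in both treated groups, enrichment over
    the control in both treated-vs-control contrasts, and equivalence between
    the treated groups (|log2FC| < equivalence_log2fc_max and
    FDR > equivalence_fdr_min in the treated-vs-treated contrast).
    """
    if len(treated) != 2:
        raise ConfigurationError("exactly two treated groups are required")
    t1, t2 = treated
    vs_control = [_lookup_pairwise(de, t, control) for t in treated]
    between, _ = _lookup_pairwise(de, t2, t1)

    universe = between.index
    for table, _ in vs_control:
        universe = universe.intersection(table.index)
    idx = universe if candidates is None else universe.intersection(pd.Index(candidates))

    record = pd.DataFrame(index=idx)
    keep = pd.Series(True, index=idx)
    for t in treated:
        record[f"coverage_{t}"] = cov.loc[idx, t]
        keep &= cov.loc[idx, t] >= criteria.coverage_required - 1e-12
    record[f"coverage_{control}"] = cov.loc[idx, control]
    for (table, sign), t in zip(vs_control, treated):
        fc = sign * table.loc[idx, "log2fc"]
        fdr = table.loc[idx, "fdr"]
        record[f"log2fc_{t}_vs_{control}"] = fc
        record[f"fdr_{t}_vs_{control}"] = fdr
        keep &= (fc > criteria.log2fc_min) & (fdr < criteria.fdr_max)
    eq_fc = between.loc[idx, "log2fc"].abs()
    eq_fdr = between.loc[idx, "fdr"]
    record[f"abs_log2fc_{t2}_vs_{t1}"] = eq_fc
    record[f"fdr_{t2}_vs_{t1}"] = eq_fdr
    keep &= (eq_fc < criteria.equivalence_log2fc_max) & (
        eq_fdr > criteria.equivalence_fdr_min
    )

    control_samples = det.sample_groups.index[det.sample_groups.eq(control)]
    record["detected_in_control"] = (
        det.detected.loc[idx, list(control_samples)].sum(axis=1) > 0
    )
    record["exclusive"] = ~record["detected_in_control"]

    members = record.loc[keep.fillna(False)].copy()
    return BiomarkerPanel(
        name="treatment_common",
        panel_class="treatment_common",
        target_groups=tuple(treated),
        members=members,
        criteria=criteria,
    )


def split_common_by_basal_detection(
    panel: BiomarkerPanel, det: DetectionMatrix, control: str = "basal"
) -> tuple[pd.Index, pd.Index]:
    """Partition a treatment-common panel by any-detection in the control group.

    Returns (detected_in_control, treatment_exclusive) protein indexes; the
    two subsets partition the panel.
    """
    if panel.panel_class != "treatment_common":
        raise UsageError(
            f"expected a treatment_common panel, got {panel.panel_class!r}"
        )
    control_samples = det.sample_groups.index[det.sample_groups.eq(control)]
    in_control = det.detected.loc[panel.protein_ids, list(control_samples)].sum(axis=1) > 0
    return panel.protein_ids[in_control], panel.protein_ids[~in_control]


def assert_panel_consistency(panels: Sequence[BiomarkerPanel]) -> None:
    """Cross-panel invariants checked on every pipeline run.

    Group-specific panels for distinct groups must be pairwise disjoint, and
    the treatment-common panel must be disjoint from the specific panels of
    its treated groups (equivalence contradicts their between-treated
    fold-change requirement).
    """
    specific = [p for p in panels if p.panel_class == "group_specific"]
    common = [p for p in panels if p.panel_class == "treatment_common"]
    for i, a in enumerate(specific):
        for b in specific[i + 1 :]:
            overlap = a.protein_ids.intersection(b.protein_ids)
            if len(overlap):
                raise ValidationError(
                    f"panels {a.name!r} and {b.name!r} overlap: {list(overlap)[:5]}"
                )
    for c in common:
        for s in specific:
            if set(s.target_groups) <= set(c.target_groups):
                overlap = c.protein_ids.intersection(s.protein_ids)
                if len(overlap):
                    raise ValidationError(
                        f"common panel overlaps {s.name!r}: {list(overlap)[:5]}"
                    )
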