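"""Localization restriction, panel membership, exclusivity and equivalence."""

import numpy as np
import pandas as pd
import pytest

import secretopanel as sp
from conftest import make_detection


def loc_series(**kwargs):
    return pd.Series(kwargs, name="localization")


class TestFilterByLocalization:
    LOC = loc_series(P1="extracellular", P2="membrane", P3="intracellular")

    def test_secreted_and_membrane(self):
        got = sp.filter_by_localization(["P1", "P2", "P3"], self.LOC, sp.SECRETED_AND_MEMBRANE)
        assert set(got) == {"P1", "P2"}

    def test_secreted_only(self):
        got = sp.filter_by_localization(["P1", "P2", "P3"], self.LOC, sp.SECRETED_ONLY)
        assert set(got) == {"P1"}

    def test_unlisted_proteins_excluded(self):
        got = sp.filter_by_localization(["P1", "P99"], self.LOC, sp.SECRETED_AND_MEMBRANE)
        assert set(got) == {"P1"}

    def test_empty_input(self):
        assert len(sp.filter_by_localization([], self.LOC, sp.SECRETED_ONLY)) == 0

    def test_unknown_mode_rejected(self):
        with pytest.raises(sp.ConfigurationError):
            sp.filter_by_localization(["P1"], self.LOC, "everything")


def build_scene(
    cov_rows: dict,
    stats: dict,
    groups=(("basal", 5), ("FiC", 4), ("HyC", 6)),
):
    """Construct coverage, detection and DE tables from compact per-protein specs.

    ``cov_rows``: protein → {group: coverage fraction}; detection booleans are
    laid out to match each coverage exactly.  ``stats``: contrast name →
    {protein: (log2fc, fdr)}.
    """
    proteins = list(cov_rows)
    group_sizes = dict(groups)
    cov = pd.DataFrame(
        {g: [cov_rows[p][g] for p in proteins] for g, _ in groups}, index=proteins
    )
    sample_ids, group_of = [], []
    for g, n in groups:
        for i in range(1, n + 1):
            sample_ids.append(f"{g}_s{i}")
            group_of.append(g)
    detected = pd.DataFrame(False, index=proteins, columns=sample_ids)
    for p in proteins:
        for g, n in groups:
            k = round(cov_rows[p][g] * n)
            for i in range(1, k + 1):
                detected.loc[p, f"{g}_s{i}"] = True
    det = make_detection(detected, pd.Series(group_of, index=sample_ids))
    de = {}
    for cname, rows in stats.items():
        fc = [rows[p][0] for p in proteins]
        fdr = [rows[p][1] for p in proteins]
        de[cname] = pd.DataFrame(
            {"log2fc": fc, "fdr": fdr, "p": fdr, "t": 0.0}, index=proteins
        )
    return cov, det, de


class TestSelectGroupPanel:
    def scene(self, cov_hyc=1.0, fdr=0.01, others_cov=0.0, fc=3.4):
        cov_rows = {"P1": {"basal": others_cov, "FiC": others_cov, "HyC": cov_hyc}}
        stats = {
            "HyC_vs_basal": {"P1": (fc, fdr)},
            "HyC_vs_FiC": {"P1": (fc, fdr)},
            "HyC_vs_rest": {"P1": (fc, fdr)},
        }
        return build_scene(cov_rows, stats)

    def test_full_coverage_strong_fc_low_fdr_is_exclusive_member(self):
        cov, det, de = self.scene()
        panel = sp.select_group_panel("HyC", de, cov, det)
        assert list(panel.protein_ids) == ["P1"]
        assert bool(panel.members.loc["P1", "exclusive"]) is True

    def test_high_fdr_excludes(self):
        cov, det, de = self.scene(fdr=0.20)
        panel = sp.select_group_panel("HyC", de, cov, det)
        assert len(panel) == 0

    def test_partial_coverage_excludes_despite_huge_fc(self):
        cov, det, de = self.scene(cov_hyc=5 / 6, fdr=0.001, fc=6.0)
        panel = sp.select_group_panel("HyC", de, cov, det)
        assert len(panel) == 0

    def test_detection_in_other_group_clears_exclusive_flag(self):
        cov, det, de = self.scene(others_cov=0.25)  # 1 of 4 FiC samples
        panel = sp.select_group_panel("HyC", de, cov, det)
        assert len(panel) == 1
        assert bool(panel.members.loc["P1", "exclusive"]) is False

    def test_missing_contrast_is_configuration_error(self):
        cov, det, de = self.scene()
        del de["HyC_vs_FiC"]
        with pytest.raises(sp.ConfigurationError, match="missing"):
            sp.select_group_panel("HyC", de, cov, det)

    def test_one_vs_rest_mode_uses_pooled_contrast_only(self):
        cov, det, de = self.scene()
        del de["HyC_vs_FiC"]
        panel = sp.select_group_panel("HyC", de, cov, det, mode="one_vs_rest")
        assert list(panel.protein_ids) == ["P1"]


class TestSelectCommonPanel:
    def scene(self, between_fc=0.5, between_fdr=0.6, cov_treated=1.0):
        cov_rows = {
            "P1": {"basal": 0.2, "FiC": cov_treated, "HyC": cov_treated}
        }
        stats = {
            "HyC_vs_basal": {"P1": (3.0, 0.01)},
            "FiC_vs_basal": {"P1": (2.5, 0.02)},
            "HyC_vs_FiC": {"P1": (between_fc, between_fdr)},
        }
        return build_scene(cov_rows, stats)

    def test_enriched_vs_control_and_equivalent_between_treated_is_member(self):
        cov, det, de = self.scene()
        panel = sp.select_common_panel(de, cov, det)
        assert list(panel.protein_ids) == ["P1"]

    def test_significant_treated_difference_excludes(self):
        cov, det, de = self.scene(between_fc=2.5, between_fdr=0.01)
        panel = sp.select_common_panel(de, cov, det)
        assert len(panel) == 0

    def test_equivalence_is_a_literal_conjunction_on_fdr(self):
        # |log2FC| under the bound but FDR below 0.05 still excludes
        cov, det, de = self.scene(between_fc=1.9, between_fdr=0.03)
        panel = sp.select_common_panel(de, cov, det)
        assert len(panel) == 0

    def test_equivalence_is_sign_blind(self):
        cov, det, de = self.scene(between_fc=-2.5, between_fdr=0.6)
        panel = sp.select_common_panel(de, cov, det)
        assert len(panel) == 0

    def test_partial_treated_coverage_excludes(self):
        cov, det, de = self.scene(cov_treated=0.75)
        panel = sp.select_common_panel(de, cov, det)
        assert len(panel) == 0


class TestSplitCommonByBasalDetection:
    def test_partition_by_any_control_detection(self):
        cov_rows = {
            "P1": {"basal": 0.2, "FiC": 1.0, "HyC": 1.0},
            "P2": {"basal": 0.0, "FiC": 1.0, "HyC": 1.0},
        }
        stats = {
            "HyC_vs_basal": {"P1": (3.0, 0.01), "P2": (3.0, 0.01)},
            "FiC_vs_basal": {"P1": (3.0, 0.01), "P2": (3.0, 0.01)},
            "HyC_vs_FiC": {"P1": (0.1, 0.9), "P2": (0.1, 0.9)},
        }
        cov, det, de = build_scene(cov_rows, stats)
        panel = sp.select_common_panel(de, cov, det)
        in_control, exclusive = sp.split_common_by_basal_detection(panel, det)
        assert list(in_control) == ["P1"]
        assert list(exclusive) == ["P2"]
        assert len(in_control) + len(exclusive) == len(panel)

    def test_wrong_panel_class_rejected(self):
        panel = sp.BiomarkerPanel(
            name="x", panel_class="group_specific", target_groups=("HyC",),
            members=pd.DataFrame(),
        )
        with pytest.raises(sp.UsageError):
            sp.split_common_by_basal_detection(panel, det=None)


class TestPanelProperties:
    def test_pipeline_panels_are_consistent(self, default_result):
        sp.assert_panel_consistency(list(default_result.panels.values()))

    def test_overlapping_specific_panels_rejected(self):
        members = pd.DataFrame(index=["P1"])
        a = sp.BiomarkerPanel("a_specific", "group_specific", ("a",), members)
        b = sp.BiomarkerPanel("b_specific", "group_specific", ("b",), members)
        with pytest.raises(sp.ValidationError, match="overlap"):
            sp.assert_panel_consistency([a, b])

    def test_tightening_thresholds_never_enlarges_panels(self, default_dataset, default_result):
        tight = sp.PanelCriteria(log2fc_min=3.0, fdr_max=0.01, coverage_required=1.0)
        res_tight = sp.run_pipeline(
            default_dataset.quant, default_dataset.localization, criteria=tight
        )
        for name, panel in res_tight.panels.items():
            assert set(panel.protein_ids) <= set(default_result.panels[name].protein_ids)
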