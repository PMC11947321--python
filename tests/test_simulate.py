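"""The synthetic-data generator and its planted ground truth."""

import numpy as np
import pandas as pd
import pytest

import secretopanel as sp


def small_config(**kwargs):
    defaults = dict(
        n_proteins=60,
        groups=(("basal", 3), ("FiC", 3), ("HyC", 3)),
        planted_panel_sizes={
            "hyc_specific": 5,
            "fic_specific": 5,
            "basal_specific": 5,
            "treatment_common": 5,
        },
        seed=0,
    )
    defaults.update(kwargs)
    return sp.SimulationConfig(**defaults)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs,match",
        [
            (dict(planted_panel_sizes={"hyc_specific": 100}), "n_proteins"),
            (dict(frac_secreted=0.8, frac_membrane=0.5), "≤ 1"),
            (dict(frac_secreted=-0.1), "frac_secreted"),
            (dict(n_tech_reps=0), "n_tech_reps"),
            (dict(groups=(("basal", 1), ("HyC", 3))), "≥ 2 biological samples"),
            (dict(dropout_slope=0.0), "dropout_slope"),
            (dict(planted_panel_sizes={"weird": 3}), "unknown panel class"),
        ],
    )
    def test_invalid_config_names_violated_invariant(self, kwargs, match):
        with pytest.raises(sp.ConfigurationError, match=match):
            small_config(**kwargs)


class TestSimulateDataset:
    def test_same_config_same_seed_is_bit_identical(self):
        a = sp.simulate_dataset(small_config())
        b = sp.simulate_dataset(small_config())
        pd.testing.assert_frame_equal(a.quant.values, b.quant.values)
        pd.testing.assert_frame_equal(a.truth, b.truth)
        pd.testing.assert_series_equal(a.localization, b.localization)

    def test_different_seed_changes_values(self):
        a = sp.simulate_dataset(small_config(seed=1))
        b = sp.simulate_dataset(small_config(seed=2))
        assert not a.quant.values.equals(b.quant.values)

    def test_disabled_dropout_and_noise_gives_full_coverage(self):
        cfg = small_config(
            dropout_midpoint=-1000.0, dropout_slope=100.0, tech_cv=0.0, abundance_sd=0.0
        )
        ds = sp.simulate_dataset(cfg)
        assert not ds.quant.values.isna().any().any()
        det, cov, _, _ = sp.run_filters(ds.quant)
        assert (cov == 1.0).all().all()

    def test_ground_truth_covers_every_protein_once(self):
        ds = sp.simulate_dataset(small_config())
        assert ds.truth.index.equals(ds.quant.protein_ids)
        assert ds.truth.index.is_unique

    def test_treatment_common_means_equal_in_treated_and_raised(self):
        cfg = small_config()
        ds = sp.simulate_dataset(cfg)
        common = ds.truth[ds.truth.panel_class == "treatment_common"]
        assert (common["mean_FiC"] == common["mean_HyC"]).all()
        assert (
            common["mean_FiC"] - common["mean_basal"] >= cfg.effect_log2fc
        ).all()

    def test_planted_proteins_forced_extracellular(self):
        ds = sp.simulate_dataset(small_config())
        planted = ds.truth[ds.truth.panel_class != "background"]
        assert (planted["localization"] == "extracellular").all()

    def test_raising_abundance_never_loses_detections(self):
        lo = sp.simulate_dataset(small_config(base_abundance_log2=10.0))
        hi = sp.simulate_dataset(small_config(base_abundance_log2=11.0))
        lo_det = lo.quant.values.notna().to_numpy()
        hi_det = hi.quant.values.notna().to_numpy()
        assert (hi_det | ~lo_det).all()  # lo detections ⊆ hi detections

    def test_recovered_count_regression_at_stated_settings(self):
        """Planted 20-protein hypertrophic panel, effect 4: pipeline recovery.

        The recovered count is a frozen self-oracle; an independent re-run
        with a different seed must agree within binomial sampling error.
        """

        def recovered(seed):
            cfg = sp.SimulationConfig(
                seed=seed, planted_panel_sizes={"hyc_specific": 20}
            )
            ds = sp.simulate_dataset(cfg)
            res = sp.run_pipeline(ds.quant, ds.localization)
            planted = set(sp.planted_proteins(ds.truth, "hyc_specific"))
            return len(planted & set(res.panels["HyC_specific"].protein_ids))

        assert recovered(11) == 19
        assert abs(recovered(12) - 19) <= 4


class TestSimulateDETables:
    def test_identical_gene_universe_across_contrasts(self):
        tables = sp.simulate_de_tables(small_config())
        names = list(tables)
        assert len(names) == 3
        for t in tables.values():
            assert t.index.equals(tables[names[0]].index)

    def test_planted_common_gene_classified_common_in_zero_noise_limit(self):
        tables = sp.simulate_de_tables(small_config(abundance_sd=0.0, effect_log2fc=6.0))
        partition = sp.classify_gene_sets(
            tables["HyC_vs_basal"], tables["FiC_vs_basal"], tables["HyC_vs_FiC"]
        )
        # gene ids mirror protein ordering: treatment_common block is planted last
        truth_cfg = small_config()
        start = sum(
            truth_cfg.planted_panel_sizes[c]
            for c in ("hyc_specific", "fic_specific", "basal_specific")
        )
        common_gene = tables["HyC_vs_basal"].index[start]
        assert partition.assignments[common_gene] == "common_chondrogenic"

    def test_null_simulation_is_calibrated(self):
        raw_rates, fdr_fracs = [], []
        for seed in range(5):
            cfg = sp.SimulationConfig(
                seed=seed, n_proteins=400, planted_panel_sizes={}, effect_log2fc=0.0
            )
            for t in sp.simulate_de_tables(cfg).values():
                raw_rates.append((t["p"] < 0.05).mean())
                fdr_fracs.append((t["fdr"] < 0.05).mean())
        se = np.sqrt(0.05 * 0.95 / (400 * 15))
        assert abs(np.mean(raw_rates) - 0.05) < 4 * se
        assert np.mean(fdr_fracs) <= 0.05


class TestSimulateTissueAreas:
    def test_pure_bone_scores_100(self):
        table = sp.simulate_tissue_areas(3, {"bone": 1.0}, noise_sd=0.0, seed=0)
        scores = sp.score_explants(table)
        assert (scores["maturation"] == 100.0).all()

    def test_pure_cartilage_scores_0(self):
        table = sp.simulate_tissue_areas(3, {"cartilage": 1.0}, noise_sd=0.0, seed=0)
        scores = sp.score_explants(table)
        assert (scores["maturation"] == 0.0).all()

    def test_fixed_seed_reproducible(self):
        kwargs = dict(
            n_explants=4,
            composition={"bone": 0.3, "cartilage": 0.2, "bone_marrow": 0.1, "fibrous": 0.1},
            noise_sd=0.05,
            seed=9,
        )
        pd.testing.assert_frame_equal(
            sp.simulate_tissue_areas(**kwargs), sp.simulate_tissue_areas(**kwargs)
        )

    def test_fractions_over_one_rejected(self):
        with pytest.raises(sp.ConfigurationError, match="sum"):
            sp.simulate_tissue_areas(2, {"bone": 0.8, "cartilage": 0.4}, 0.05, 0)

    def test_areas_nonnegative(self):
        table = sp.simulate_tissue_areas(
            5, {"bone": 0.5, "cartilage": 0.3}, noise_sd=0.2, seed=3
        )
        assert (table[["bone", "bone_marrow", "cartilage", "fibrous", "background"]] >= 0).all().all()


class TestIdentificationHierarchy:
    def test_mean_identified_counts_order_with_group_shifts(self):
        # light 3-seed check; the 10-seed version runs in the acceptance suite
        for seed in (0, 1, 2):
            ds = sp.simulate_dataset(sp.SimulationConfig(seed=seed))
            det, _, _, _ = sp.run_filters(ds.quant)
            m = sp.identified_per_sample(det).groupby(det.sample_groups).mean()
            assert m["basal"] < m["FiC"] < m["HyC"]
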