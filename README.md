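# secretopanel

Biomarker-panel discovery from label-free DIA secreted-proteome data, for
groups of conditioned-medium experiments such as cartilage/bone organoid
secretomes. The package implements the full post-quantification pipeline —
identification filtering, per-protein differential testing with FDR control,
subcellular-localization restriction, and panel selection with exclusivity
and equivalence criteria — together with a transcriptome overlap classifier,
explant histomorphometry scores, and a synthetic-data generator with planted
ground truth so that every stage can be verified end to end.

## Who this is for

Proteomics and skeletal tissue-engineering groups comparing the secretome of
treated versus control cultures (here: hypertrophic-cartilage organoids HyC,
fibrocartilage organoids FiC, and an undifferentiated basal control) who want
a reproducible, scriptable version of the usual "custom R scripts" step
between the search-engine protein matrix and the biomarker tables.

## The method

Starting from a proteins × runs intensity matrix with run metadata
(sample, group, technical replicate):

1. **Low reads.** Intensities n < 5 are treated as not identified.
2. **Replicate collapse.** A protein is *detected* in a biological sample iff
   ≥ 2/3 of the sample's technical replicates carry a value; the collapsed
   abundance is the mean over detected replicates.
3. **Coverage filter.** Identification coverage is the fraction of a group's
   samples with a detection. A protein is retained iff
   max over groups of coverage ≥ 70% (which subsumes a "below-30%-everywhere"
   removal clause; both are reported in the removal log).
4. **Differential testing.** Abundances are normalized as log₂(n + 1) with
   not-detected as n = 0; each protein is compared with a two-sided unpaired
   t-test (Welch by default) per contrast, including one-versus-rest
   contrasts with pooled samples; p-values are Benjamini–Hochberg adjusted
   within each contrast. Log₂FC is the difference of group means of
   log₂(n + 1).
5. **Localization.** UniProt-style labels restrict the differential analysis
   to extracellular + membrane proteins and the panels to extracellular
   (actively secreted) proteins.
6. **Panels.** A *group-specific* panel member needs 100% coverage in its
   group, Log₂FC > 2 and FDR < 0.05 versus each other group; it is flagged
   *exclusive* when it has zero detections in every other group. The
   *treatment-common* panel needs 100% coverage in both treated groups,
   Log₂FC > 2 and FDR < 0.05 versus control in both treated-vs-control
   contrasts, and *equivalence* between the treated groups:
   |Log₂FC| < 2 and FDR > 0.05. The common panel is split by any-detection
   in the control group.

Gene-level tables for the three contrasts can additionally be partitioned by
the overlap rule (significant in both treated-vs-control contrasts with the
same sign and no treated-vs-treated difference → common-chondrogenic;
significant in a treated-vs-control and the treated-vs-treated contrast →
group-specific). Explants are scored by the ossicle maturation score
100·(bone + marrow)/(bone + marrow + cartilage + fibrous), the volume-aware
overall score (maturation/100 × volume), and standardized mineral-thickness
profiles.

## Worked example

```python
import secretopanel as sp

dataset = sp.simulate_dataset(sp.SimulationConfig(seed=1))   # 2000 proteins, 5/4/6 design
result = sp.run_pipeline(dataset.quant, dataset.localization)
print(result.counts)
```

prints

```
{'proteins_in': 2000, 'proteins_retained': 327, 'proteins_removed': 1673,
 'secreted_and_membrane': 325, 'secreted_only': 325,
 'panel_basal_specific': 25, 'panel_FiC_specific': 49,
 'panel_HyC_specific': 89, 'panel_treatment_common': 144,
 'common_detected_in_control': 17, 'common_treatment_exclusive': 127, ...}
```

Of 2000 simulated proteins, 327 survive the identification funnel; the HyC
panel recovers 89 of the 100 planted hypertrophic markers (the misses fail
the strict 100%-coverage rule), the treatment-common panel 144 of 150, with
precision 1.0 throughout:

```python
print(sp.panel_recovery(dataset.truth, {
    "hyc_specific": result.panels["HyC_specific"].protein_ids,
    "treatment_common": result.panels["treatment_common"].protein_ids,
}))
```

The same stages are available from the shell:

```
secretopanel simulate --seed 1 --out data/
secretopanel run-all --quant data/quant.tsv --metadata data/metadata.tsv \
    --localization data/localization.tsv --out results/
```

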