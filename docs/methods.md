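# Methods

## Scope and data model

The package operates strictly downstream of spectral processing: its raw
input is a protein-level intensity matrix (proteins × runs) as produced by a
DIA search engine after protein rollup, plus run metadata (biological sample,
group, technical replicate). Missing and zero are distinct states
throughout: an empty field means *not identified*, a written 0 is a detected
zero. All identification rules operate on detection, not abundance, which is
why the distinction is preserved end to end. Whether the upstream matrix
contains normalized or raw quantities is accepted as-is and recorded in the
run manifest.

## Identification filtering

The funnel runs in a fixed order; each step is idempotent.

* **Low reads** (`low_read`, default 5, strict `<`): intensities below the
  floor become missing. The strict inequality follows the operational rule
  "reads below 5 are removed"; a value of exactly 5 is kept.
* **Replicate collapse** (`replicate_fraction`, default 2/3, inclusive): a
  protein is detected in a biological sample iff at least that fraction of
  the sample's technical replicates carry a value; the collapsed abundance
  is the arithmetic mean over detected replicates. Single-run samples use
  the run directly. The rule is applied uniformly — both for
  identification counting and upstream of differential testing — and this
  choice is echoed in the manifest.
* **Coverage filter** (`condition_keep`, default 0.70, inclusive): retained
  iff the best per-group coverage reaches the threshold. The companion
  "below 30% in every group" clause (`group_floor`) is logically subsumed by
  the 70% rule — a protein under 30% everywhere cannot have a group at 70% —
  so it does not change the retained set, but it is evaluated separately and
  reported per removed protein for transparency.

Ratio-versus-threshold comparisons carry a 1e-9 guard so that fractions such
as 2/3 computed in floating point compare as intended.

## Differential testing

Collapsed abundances are normalized as log₂(n + 1) with not-detected treated
as n = 0. The +1 offset exists precisely to accommodate zeros, so
missingness is mapped to a zero signal rather than deleted row-wise;
consequently every protein has a complete vector and the per-side sample
sizes equal the group sizes. Log₂FC is the difference of group means on
this scale (not a ratio of raw means).

The per-protein test is a two-sided unpaired t-test. Welch (unequal
variances) is the default because the group sizes are unequal (5/4/6);
Student's pooled-variance flavor is available by flag and both are recorded
in the manifest. Degenerate inputs follow an explicit contract instead of
propagating NaN: both sides zero variance and equal means → t = 0, p = 1;
both sides zero variance and unequal means → p = 0 with a `degenerate` flag
(the difference is unambiguous in the model's terms). Proteins untestable
in a contrast (a side with < 2 samples) are kept in the table with NaN
statistics and excluded from the FDR universe.

Benjamini–Hochberg adjustment is the classical step-up
(q(i) = min over j ≥ i of p(j)·m/j, capped at 1) and is applied within each
contrast across its tested proteins; adjusting per contrast rather than
jointly keeps each table self-contained and is recorded as a choice. The
FDR universe of the panel-selection stage is the secreted-only protein set
(the stage-appropriate localization restriction), so panel decisions use
contrast tables re-adjusted on that universe; the reported differential
tables use the broader secreted-and-membrane universe.

## Panel selection

Group-specific membership requires 100% coverage in the target group and
enrichment (Log₂FC > 2, FDR < 0.05) against **each** other group. The
one-versus-rest contrast is computed and recorded for every member, and a
`one_vs_rest` mode exists in which it alone carries the enrichment
condition; pairwise is the default because it is the variant under which the
panel families are provably disjoint: a protein equivalent between the
treated groups cannot simultaneously clear a Log₂FC > 2 bar between them, so
the treatment-common panel cannot intersect a group-specific panel, and two
different groups' panels cannot share a member (the same pairwise fold
change cannot exceed +2 in both directions). Under pooled one-versus-rest
enrichment those guarantees fail — a protein raised equally in both treated
groups still clears the bar against a pool dominated by the control — which
both muddles the interpretation of "specific" and contaminates the specific
panels with treatment-common proteins. The disjointness invariants are
asserted on every pipeline run.

Equivalence between treated groups is |Log₂FC| < 2 **and** FDR > 0.05, as a
literal conjunction. The absolute value is deliberate: a large negative
fold change plainly indicates a difference. The FDR clause is kept literal
even where it conflicts with small-fold-change intuition (a protein with
|Log₂FC| = 0.1 but FDR = 0.03 is excluded); this is documented rather than
softened. The 100%-coverage condition for the common panel is applied per
treated group (both at 100%), the stricter of the two readings.

"Exclusive" markers are operationalized as zero detected samples in every
non-target group — the strictest reading. The common panel is split by
any-detection in the control group into detected-in-control versus
treatment-exclusive subsets, which partition it by construction.

## Transcriptome overlap classification

The classifier is pure set algebra over three gene-level DE tables sharing
one universe; it is independent of how the tables were fit. Significance
defaults to FDR < 0.05 with no fold-change cut (`log2fc_min = 0`), since DEG
counting by an FDR criterion alone is the common convention for such tables.
Genes significant in both treated-vs-control contrasts must agree in sign to
be called common-chondrogenic; opposite-direction genes are unclassified. A
gene significant in all three contrasts indicates group-specific magnitude
and is assigned to the side favoured by the treated-vs-treated direction,
keeping the classes mutually exclusive and jointly exhaustive. Note that
genes *lower* in both treated groups also satisfy the common rule — the
class captures "equal in the treated groups, different from control",
irrespective of direction.

## Histomorphometry

The maturation score is 100·(bone + marrow)/(bone + marrow + cartilage +
fibrous); background pixels are excluded from the denominator because the
upstream pixel classes include non-tissue. Sections of an explant are
pooled by summed areas (not averaged percentages), weighting sections by
tissue content. The overall score is defined here as maturation/100 ×
mineralized volume (mm³) — the simplest combination monotone in both
inputs — and is always reported alongside both inputs so any alternative
combination can be recomputed. Thickness profiles are standardized to mean
0, SD 1 over bins (sample SD, n − 1) within each replicate; constant
profiles are rejected as shapeless.

## Synthetic-data generator

The generator emulates the *structure* of a three-group conditioned-medium
DIA experiment, not its absolute scale. Per protein i, sample s, replicate
t: a sample-level true abundance x_is ~ Normal(μ_i[group(s)], σ_bio) on the
log₂ scale shared across the sample's replicates; a reported intensity
2^x_is times multiplicative lognormal technical noise with CV `tech_cv`
(mean 1); and missing-not-at-random dropout — the replicate is reported with
probability sigmoid(slope·(x_is − midpoint)). Abundance-coupled dropout is
the only mechanism that reproduces grossly group-dependent identification
counts from group-shifted abundances, which is the central feature the
pipeline's filters are built around. One root seed drives all randomness
through deterministically derived per-stage substreams, so raising every
abundance at a fixed seed keeps the dropout coin-flips fixed and can only
add detections (a tested monotonicity property).

Planted classes shift group means by `effect_log2fc`: hyc-, fic- and
basal-specific classes in exactly one group, the treatment-common class
equally in both treated groups. All planted proteins are annotated
extracellular; background proteins draw labels from the configured
secreted/membrane fractions (defaults 0.24/0.26, matching typical UniProt
annotation proportions for a secretome experiment), with the remainder split
80/20 between intracellular and unknown.

Default parameters (the emulated study conditions): groups basal n = 5,
FiC n = 4, HyC n = 6; 3 technical replicates; 2000 proteins; planted sizes
100/50/25/150 (hyc/fic/basal/common); effect 4 log₂ units; base abundance
10 log₂ units with σ_bio = 0.5 (≈ 40% biological CV) and tech_cv = 0.2;
dropout midpoint 11.6, slope 1.8. The midpoint sits 1.6 log₂ units above
the background abundance, so baseline-level proteins are identified only
sporadically (≈ 1–2% of samples) while planted proteins in their raised
groups are identified in ≈ 99.7% — the regime of treatment-induced secreted
markers lying below the detection limit in control medium. This placement
matters statistically as well as biologically: with the midpoint at the
background abundance, off-target proteins produce sporadic full-abundance
detections whose huge within-group variance (values like 0, 0, 0, 10 on a
4-sample side) inflates Welch standard errors at ≈ 3 degrees of freedom and
makes even 10-log₂-unit fold changes non-significant — a regime in which no
presence/absence marker analysis of this design can work.

What the generator does **not** emulate: per-protein spread of baseline
abundances (all background proteins share one mean, so the identified
fraction per sample is lower than in real data where many housekeeping
proteins are robustly detected everywhere); peptide-level evidence,
retention time, shared-peptide rollup artifacts; correlated biological
covariates (donor sex, batch); and the absolute protein counts of real
experiments. Passing the recovery tests therefore demonstrates that the
pipeline's rules are implemented correctly and are jointly attainable under
the stated noise model — not that real data of any particular study would
yield panels of any particular size.

Gene-level DE tables reuse the same planted-class construction on simulated
log-expression without dropout (they stand in for count-model output from an
upstream RNA-seq fit, which is out of scope); with σ_bio = 0 the
degenerate-variance contract yields exact p ∈ {0, 1} — the zero-noise limit
in which the overlap classifier must recover planted classes exactly.
Tissue-area tables draw Dirichlet-perturbed fractions (concentration
1/noise_sd²) times a lognormally jittered total area, with three sections
per explant; at noise_sd = 0 they are exact and deterministic.

## Numerical and testing choices

Problem sizes in the test and acceptance suites are chosen so the whole
suite completes in well under a minute: calibration simulations use 300
proteins × 20 seeds (6000 tests per contrast, Monte-Carlo SE ≈ 0.0028 on a
0.05 rate), recovery runs use the full 2000-protein design over 5 seeds, and
the brute-force filter oracle uses ≤ 30-protein matrices over 120 draws.
Two calibration details are deliberate: the nominal-level band is asserted
on the pooled-variance t flavor, because under the generator's global null
the equal-variance assumption holds exactly and the pooled null distribution
is exact, whereas the Welch approximation is intrinsically slightly
conservative at n ≤ 6 (true level ≈ 0.044–0.046 at nominal 0.05) and is
therefore bounded rather than banded. And under a global null the expected
fraction of BH-rejected features is near zero (BH controls the FDR, not the
per-feature rejection rate), so null calibration of the adjusted values is
asserted as "≤ nominal", while the raw p-value rate is banded around
nominal.

## Known limitations

* The coverage thresholds interact with group size discretely (70% of 6
  samples means 5 of 6); very small groups make the filter coarse.
* The equivalence criterion is an operational rule, not a TOST-style
  equivalence test; FDR > 0.05 is evidence of absence only in the loose,
  conventional sense.
* The overall-score formula is one reasonable choice among monotone
  combinations; both inputs are always reported so alternatives remain
  computable.
* With `panel_mode="one_vs_rest"` the cross-panel disjointness assertions
  can legitimately fire; the mode exists for comparability, not as the
  recommended analysis.
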