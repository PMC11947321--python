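"""Synthetic data with the statistical structure the pipeline assumes.

The generator emulates a conditioned-medium DIA experiment over three groups
— an undifferentiated control (basal) and two chondrogenic treatments
(fibrocartilage FiC, hypertrophic cartilage HyC) — with known ground truth,
so every downstream stage can be verified without the original raw data.

Model per protein *i*, biological sample *s*, technical replicate *t*:

* true log2 abundance ``x_is ~ Normal(mu_i[group(s)], abundance_sd)``,
  shared across the sample's technical replicates;
* reported intensity ``2**x_is`` times multiplicative lognormal technical
  noise with coefficient of variation ``tech_cv`` (mean 1);
* the replicate is reported only with probability
  ``sigmoid(dropout_slope · (x_is − dropout_midpoint))`` — missing-not-at-
  random dropout coupled to abundance, which is what produces the
  group-dependent identification counts seen in sparse control secretomes.

Planted panel classes shift group means by ``effect_log2fc``: the
group-specific classes are raised in exactly one group, the treatment-common
class equally in both treated groups.  All planted proteins are annotated
extracellular; background proteins draw localization labels from the
configured fractions.

A single seed governs all randomness through one root ``SeedSequence`` with
deterministically derived sub-streams per stage, so raising every true
abundance while keeping the seed leaves the dropout coin-flips fixed and can
only add detections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .differential import _two_sample_t, bh_adjust
from .errors import ConfigurationError
from .io import QuantMatrix

#: Planted panel classes; the remainder of the proteome is "background".
PANEL_CLASSES = ("hyc_specific", "fic_specific", "basal_specific", "treatment_common")

#: Default study design: (group, biological samples), control first.
DEFAULT_GROUPS = (("basal", 5), ("FiC", 4), ("HyC", 6))

_DEFAULT_PANEL_SIZES = {
    "hyc_specific": 100,
    "fic_specific": 50,
    "basal_specific": 25,
    "treatment_common": 150,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic secreted-proteome experiment.

    Defaults reproduce the study design (3 groups of 5/4/6 biological
    samples, 3 technical replicates, ~2000 proteins) with an effect size of
    4 log2 units on planted panels, biological SD 0.5 and technical CV 0.2 on
    intensities, and a logistic dropout curve placed above the background
    abundance, so that baseline-level proteins are identified only
    sporadically (a few percent of samples) while planted proteins in their
    raised groups are identified almost always — the regime of
    treatment-induced secreted markers sitting below the detection limit in
    control medium.
    """

    n_proteins: int = 2000
    groups: tuple[tuple[str, int], ...] = DEFAULT_GROUPS
    n_tech_reps: int = 3
    planted_panel_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_PANEL_SIZES)
    )
    effect_log2fc: float = 4.0
    base_abundance_log2: float = 10.0
    abundance_sd: float = 0.5
    tech_cv: float = 0.2
    dropout_midpoint: float = 11.6
    dropout_slope: float = 1.8
    frac_secreted: float = 0.24
    frac_membrane: float = 0.26
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ConfigurationError("n_proteins must be ≥ 1")
        if self.n_tech_reps < 1:
            raise ConfigurationError("n_tech_reps must be ≥ 1")
        if len(self.groups) < 2:
            raise ConfigurationError("need ≥ 2 groups")
        for g, n in self.groups:
            if n < 2:
                raise ConfigurationError(
                    f"group {g!r} needs ≥ 2 biological samples, got {n}"
                )
        unknown = set(self.planted_panel_sizes) - set(PANEL_CLASSES) - {"background"}
        if unknown:
            raise ConfigurationError(f"unknown panel class(es) {sorted(unknown)}")
        planted = sum(
            int(self.planted_panel_sizes.get(c, 0)) for c in PANEL_CLASSES
        )
        if any(int(self.planted_panel_sizes.get(c, 0)) < 0 for c in PANEL_CLASSES):
            raise ConfigurationError("planted panel sizes must be ≥ 0")
        if planted > self.n_proteins:
            raise ConfigurationError(
                f"planted panel sizes sum to {planted} > n_proteins {self.n_proteins}"
            )
        if "background" in self.planted_panel_sizes and (
            int(self.planted_panel_sizes["background"]) != self.n_proteins - planted
        ):
            raise ConfigurationError(
                "explicit background size inconsistent with n_proteins"
            )
        for name in ("abundance_sd", "tech_cv", "effect_log2fc"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be ≥ 0")
        if self.dropout_slope <= 0:
            raise ConfigurationError("dropout_slope must be > 0")
        for name in ("frac_secreted", "frac_membrane"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.frac_secreted + self.frac_membrane > 1.0:
            raise ConfigurationError("frac_secreted + frac_membrane must be ≤ 1")

    @property
    def group_names(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.groups)

    def class_target_groups(self, panel_class: str) -> tuple[str, ...]:
        """Groups whose mean a planted class raises (control first by design)."""
        names = self.group_names
        mapping = {
            "basal_specific": (names[0],),
            "fic_specific": (names[1],),
            "hyc_specific": (names[-1],),
            "treatment_common": tuple(names[1:]),
        }
        return mapping[panel_class]


@dataclass
class SimulatedDataset:
    """Quant matrix + localization table + planted ground truth."""

    quant: QuantMatrix
    localization: pd.Series
    truth: pd.DataFrame
    config: SimulationConfig


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(n)
    return [np.random.default_rng(c) for c in children]


def _true_means(config: SimulationConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Per-protein true group means and panel-class labels."""
    ids = pd.Index([f"P{i + 1:05d}" for i in range(config.n_proteins)], name="protein_id")
    classes = pd.Series("background", index=ids, dtype=object, name="panel_class")
    means = pd.DataFrame(
        config.base_abundance_log2,
        index=ids,
        columns=list(config.group_names),
        dtype=float,
    )
    start = 0
    for cls in PANEL_CLASSES:
        size = int(config.planted_panel_sizes.get(cls, 0))
        block = ids[start : start + size]
        classes.loc[block] = cls
        for g in config.class_target_groups(cls):
            means.loc[block, g] += config.effect_log2fc
        start += size
    return means, classes


def simulate_dataset(config: SimulationConfig = SimulationConfig()) -> SimulatedDataset:
    """Draw one synthetic experiment; bit-for-bit reproducible per config."""
    rng_bio, rng_tech, rng_drop, rng_loc, _ = _streams(config.seed, 5)
    means, classes = _true_means(config)
    ids = means.index

    samples: list[str] = []
    sample_group: list[str] = []
    for g, n in config.groups:
        for i in range(1, n + 1):
            samples.append(f"{g}_s{i}")
            sample_group.append(g)
    n_s, n_r = len(samples), config.n_tech_reps

    mu = means[sample_group].to_numpy()  # proteins × samples
    x = mu + config.abundance_sd * rng_bio.standard_normal(mu.shape)

    if config.tech_cv > 0:
        sigma = math.sqrt(math.log(1.0 + config.tech_cv**2))
        factors = np.exp(
            rng_tech.normal(-0.5 * sigma**2, sigma, size=(len(ids), n_s, n_r))
        )
    else:
        factors = np.ones((len(ids), n_s, n_r))
    intensity = np.exp2(x)[:, :, None] * factors

    p_detect = 1.0 / (1.0 + np.exp(-config.dropout_slope * (x - config.dropout_midpoint)))
    u = rng_drop.uniform(size=(len(ids), n_s, n_r))
    kept = u < p_detect[:, :, None]
    intensity = np.where(kept, intensity, np.nan)

    run_names, run_sample, run_group, run_rep = [], [], [], []
    for s, g in zip(samples, sample_group):
        for r in range(1, n_r + 1):
            run_names.append(f"{s}_{r}")
            run_sample.append(s)
            run_group.append(g)
            run_rep.append(r)
    values = pd.DataFrame(
        intensity.reshape(len(ids), n_s * n_r), index=ids, columns=run_names
    )
    runs = pd.DataFrame(
        {"sample_id": run_sample, "group": run_group, "tech_rep": run_rep},
        index=pd.Index(run_names, name="run"),
    )
    quant = QuantMatrix(values=values, runs=runs)

    localization = _draw_localization(config, classes, rng_loc)
    truth = pd.concat(
        [classes, localization.rename("localization"), means.add_prefix("mean_")],
        axis=1,
    )
    return SimulatedDataset(
        quant=quant, localization=localization, truth=truth, config=config
    )


def _draw_localization(
    config: SimulationConfig, classes: pd.Series, rng: np.random.Generator
) -> pd.Series:
    """Labels for every protein; planted panel members are forced extracellular.

    Background labels are drawn from (secreted, membrane, intracellular,
    unknown) with the configured secreted/membrane fractions; the remainder
    splits 80/20 between intracellular and unknown.
    """
    rem = 1.0 - config.frac_secreted - config.frac_membrane
    probs = [config.frac_secreted, config.frac_membrane, 0.8 * rem, 0.2 * rem]
    labels = np.array(["extracellular", "membrane", "intracellular", "unknown"])
    drawn = labels[rng.choice(4, size=len(classes), p=probs)]
    loc = pd.Series(drawn, index=classes.index, name="localization")
    loc[classes != "background"] = "extracellular"
    return loc


# ---------------------------------------------------------------------------
# Transcriptome DE tables


def simulate_de_tables(
    config: SimulationConfig = SimulationConfig(),
) -> dict[str, pd.DataFrame]:
    """Gene-level DE tables for the three organoid contrasts.

    Log-expression is drawn per gene and sample as
    ``Normal(mu_gene[group], abundance_sd)`` with the same planted class
    structure as the proteome (common-chondrogenic genes shifted equally in
    both treated groups, class-specific genes shifted in one group); each
    contrast is tested with a two-sided Welch t-test and BH-adjusted within
    the table.  With ``abundance_sd = 0`` the degenerate-variance contract
    yields exact p ∈ {0, 1}, the zero-noise limit.

    Returns tables keyed ``HyC_vs_basal``, ``FiC_vs_basal``, ``HyC_vs_FiC``
    (generalized to the configured group names), each indexed by gene with
    columns ``log2fc``, ``t``, ``p``, ``fdr``; all three share one gene
    universe.
    """
    rng_expr = _streams(config.seed, 5)[4]
    means, classes = _true_means(config)
    ids = pd.Index(
        [f"G{i + 1:05d}" for i in range(config.n_proteins)], name="gene_id"
    )
    means.index = ids

    sample_group = [g for g, n in config.groups for _ in range(n)]
    mu = means[sample_group].to_numpy()
    y = mu + config.abundance_sd * rng_expr.standard_normal(mu.shape)
    group_cols: dict[str, np.ndarray] = {}
    offset = 0
    for g, n in config.groups:
        group_cols[g] = y[:, offset : offset + n]
        offset += n

    basal, fic, hyc = config.group_names[0], config.group_names[1], config.group_names[-1]
    tables: dict[str, pd.DataFrame] = {}
    for name, (a, b) in {
        f"{hyc}_vs_{basal}": (hyc, basal),
        f"{fic}_vs_{basal}": (fic, basal),
        f"{hyc}_vs_{fic}": (hyc, fic),
    }.items():
        t, p, degenerate = _two_sample_t(group_cols[a], group_cols[b])
        tables[name] = pd.DataFrame(
            {
                "log2fc": group_cols[a].mean(axis=1) - group_cols[b].mean(axis=1),
                "t": t,
                "p": p,
                "fdr": bh_adjust(p),
                "degenerate": degenerate,
            },
            index=ids,
        )
    return tables


# ---------------------------------------------------------------------------
# Tissue-area tables


def simulate_tissue_areas(
    n_explants: int,
    composition: Mapping[str, float],
    noise_sd: float,
    seed: int,
    n_sections: int = 3,
    mean_total_area: float = 1e6,
) -> pd.DataFrame:
    """Per-explant, per-section tissue areas with Dirichlet-perturbed fractions.

    ``composition`` maps tissue class (bone, cartilage, bone_marrow, fibrous)
    to its mean area fraction; fractions must sum to ≤ 1 and the remainder is
    background.  ``noise_sd`` sets the scatter of the realized fractions
    (Dirichlet concentration ``1/noise_sd²``); at 0 the fractions are exact
    and the table is fully deterministic.
    """
    tissue_order = ("bone", "bone_marrow", "cartilage", "fibrous")
    unknown = set(composition) - set(tissue_order)
    if unknown:
        raise ConfigurationError(f"unknown tissue class(es) {sorted(unknown)}")
    fractions = np.array([float(composition.get(t, 0.0)) for t in tissue_order])
    if (fractions < 0).any():
        raise ConfigurationError("composition fractions must be ≥ 0")
    if fractions.sum() > 1.0 + 1e-12:
        raise ConfigurationError(
            f"composition fractions sum to {fractions.sum():.3f} > 1"
        )
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be ≥ 0")
    background = max(0.0, 1.0 - fractions.sum())
    probs = np.append(fractions, background)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for e in range(1, n_explants + 1):
        for s in range(1, n_sections + 1):
            if noise_sd == 0:
                frac = probs
                total = mean_total_area / n_sections
            else:
                frac = np.zeros_like(probs)
                positive = probs > 0
                frac[positive] = rng.dirichlet(probs[positive] / noise_sd**2)
                total = (mean_total_area / n_sections) * rng.lognormal(0.0, 0.2)
            rows.append(
                {
                    "explant": f"E{e}",
                    "section": s,
                    **{t: frac[i] * total for i, t in enumerate(tissue_order)},
                    "background": frac[-1] * total,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Ground-truth evaluation


def planted_proteins(truth: pd.DataFrame, panel_class: str) -> pd.Index:
    return truth.index[truth["panel_class"] == panel_class]


def panel_recovery(
    truth: pd.DataFrame, derived: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Jaccard, sensitivity and precision of derived panels vs planted ones.

    ``derived`` maps panel class (e.g. ``hyc_specific``) to the recovered
    protein ids.
    """
    rows = []
    for cls, proteins in derived.items():
        planted = set(planted_proteins(truth, cls))
        got = set(proteins)
        tp = len(planted & got)
        union = len(planted | got)
        rows.append(
            {
                "panel_class": cls,
                "n_planted": len(planted),
                "n_derived": len(got),
                "true_positives": tp,
                "jaccard": tp / union if union else 1.0,
                "sensitivity": tp / len(planted) if planted else 1.0,
                "precision": tp / len(got) if got else 1.0,
            }
        )
    return pd.DataFrame(rows).set_index("panel_class")
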