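"""Download-free synthetic cohorts with the statistical structure the
pipeline assumes.

The generator emulates a multi-cancer-type tumor cohort: a planted expression
signature in aberrant samples over a standard-normal per-gene baseline,
aberration labels evidenced by either a non-silent target-gene mutation or a
high copy-number gain, mutation-burden heterogeneity including hypermutators,
and optional phenocopying genes that plant the same signature without a core
target event.  It makes no attempt to match real gene-gene correlation
structure, batch effects, or mutation spectra -- only the relative shifts the
classifier is trained to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort_io import (
    CohortError,
    CopyNumberMatrix,
    CovariateTable,
    ExpressionMatrix,
    GeneTargetSpec,
    MutationTable,
)
from .status_labels import StatusVector

#: Default simulated target genes: the three canonical Ras oncogenes plus a
#: tumor suppressor, so both evidence directions are exercised.
DEFAULT_ONCOGENES = ("KRAS", "NRAS", "HRAS")
DEFAULT_TUMOR_SUPPRESSORS = ("NF1",)

# A small pool of realistic activating-variant annotations used to populate
# nucleotide/protein change fields on planted target-gene mutations.
_VARIANT_POOL = (
    ("c.35G>T", "p.G12V"),
    ("c.35G>A", "p.G12D"),
    ("c.34G>T", "p.G12C"),
    ("c.38G>A", "p.G13D"),
    ("c.183A>C", "p.Q61H"),
    ("c.182A>G", "p.Q61R"),
)

_BACKGROUND_CLASSES = (
    "Missense_Mutation",
    "Silent",
    "Nonsense_Mutation",
    "Frame_Shift_Del",
    "Splice_Site",
)
_BACKGROUND_CLASS_P = (0.55, 0.25, 0.08, 0.07, 0.05)


@dataclass(frozen=True)
class CancerTypeConfig:
    """One simulated cancer type: cohort fraction and aberration prevalence."""

    name: str
    sample_fraction: float
    aberration_prevalence: float


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic cohort generator.

    Defaults describe a desk-scale cohort: 1,000 samples over three cancer
    types at 20% aberration prevalence, 2,000 genes of which 100 carry a
    one-standard-deviation planted signature, 20% of positive labels driven
    by copy gains, ~50 background mutations per sample and 2% hypermutators
    at a >= 10x inflated burden.
    """

    n_samples: int = 1000
    n_genes: int = 2000
    cancer_types: tuple[CancerTypeConfig, ...] = (
        CancerTypeConfig("COAD", 0.4, 0.2),
        CancerTypeConfig("LUAD", 0.35, 0.2),
        CancerTypeConfig("PAAD", 0.25, 0.2),
    )
    n_signal_genes: int = 100
    effect_size: float = 1.0
    copy_fraction: float = 0.2
    hypermutator_fraction: float = 0.02
    hypermutator_inflation: float = 20.0
    baseline_mutation_rate: float = 50.0
    background_cnv_rate: float = 0.01
    oncogenes: tuple[str, ...] = DEFAULT_ONCOGENES
    tumor_suppressors: tuple[str, ...] = DEFAULT_TUMOR_SUPPRESSORS
    phenocopy_genes: tuple[str, ...] = ()
    phenocopy_prevalence: float = 0.0
    seed: int = 0

    def __post_init__(self):
        fractions = sum(ct.sample_fraction for ct in self.cancer_types)
        if abs(fractions - 1.0) > 1e-9:
            raise CohortError(f"cancer-type sample fractions sum to {fractions}, not 1")
        for ct in self.cancer_types:
            if not 0.0 <= ct.aberration_prevalence <= 1.0:
                raise CohortError(f"prevalence out of [0,1] for {ct.name}")
        if self.effect_size < 0:
            raise CohortError("effect_size must be >= 0")
        if self.n_signal_genes > self.n_genes:
            raise CohortError("n_signal_genes cannot exceed n_genes")
        if not 0.0 <= self.copy_fraction <= 1.0:
            raise CohortError("copy_fraction must lie in [0,1]")
        if not 0.0 <= self.hypermutator_fraction <= 1.0:
            raise CohortError("hypermutator_fraction must lie in [0,1]")
        if self.hypermutator_inflation < 10.0:
            raise CohortError("hypermutators must be inflated at least 10x baseline")
        if not 0.0 <= self.phenocopy_prevalence <= 1.0:
            raise CohortError("phenocopy_prevalence must lie in [0,1]")

    @property
    def target_spec(self) -> GeneTargetSpec:
        return GeneTargetSpec(
            oncogenes=self.oncogenes, tumor_suppressors=self.tumor_suppressors
        )


@dataclass
class SimulatedCohort:
    """A generated cohort plus the ground truth used only for testing."""

    expression: ExpressionMatrix
    mutations: MutationTable
    copy_number: CopyNumberMatrix
    covariates: CovariateTable
    truth: StatusVector
    signal_genes: list[str]
    hypermutators: list[str]
    phenocopy_samples: list[str]
    spec: GeneTargetSpec


def _gene_names(config: SimulationConfig) -> list[str]:
    named = list(config.oncogenes) + list(config.tumor_suppressors) + list(
        config.phenocopy_genes
    )
    if len(named) > config.n_genes:
        raise CohortError("n_genes too small to hold all named target genes")
    width = max(4, len(str(config.n_genes)))
    filler = [f"G{i:0{width}d}" for i in range(1, config.n_genes - len(named) + 1)]
    return named + filler


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate one cohort under ``config``; fully determined by its seed."""
    rng = np.random.default_rng(config.seed)
    genes = _gene_names(config)
    named = set(config.oncogenes) | set(config.tumor_suppressors) | set(
        config.phenocopy_genes
    )
    candidate_signal = [g for g in genes if g not in named]
    signal_genes = sorted(
        rng.choice(candidate_signal, size=config.n_signal_genes, replace=False)
    )

    # cancer types and per-type aberration
    n = config.n_samples
    sample_ids = [f"S{i:05d}" for i in range(1, n + 1)]
    fracs = np.array([ct.sample_fraction for ct in config.cancer_types])
    counts = np.floor(fracs * n).astype(int)
    counts[-1] = n - counts[:-1].sum()
    types = np.repeat([ct.name for ct in config.cancer_types], counts)
    prevalence = np.repeat(
        [ct.aberration_prevalence for ct in config.cancer_types], counts
    )
    aberrant = rng.random(n) < prevalence

    # phenocopy samples: drawn from non-aberrant samples, receive the
    # signature plus a phenocopy-gene mutation but no core target event
    phenocopy = np.zeros(n, dtype=bool)
    if config.phenocopy_genes and config.phenocopy_prevalence > 0:
        phenocopy = (~aberrant) & (rng.random(n) < config.phenocopy_prevalence)

    # expression: standard-normal baseline, shifted in signature carriers
    expr = rng.standard_normal((n, config.n_genes))
    expr_df = pd.DataFrame(expr, index=sample_ids, columns=genes)
    carriers = aberrant | phenocopy
    sig_idx = [genes.index(g) for g in signal_genes]
    expr_df.iloc[np.where(carriers)[0], sig_idx] += config.effect_size

    # copy-number calls: sparse background noise plus planted +2 gains
    cnv = np.zeros((n, config.n_genes), dtype=int)
    noise = rng.random((n, config.n_genes)) < config.background_cnv_rate
    cnv[noise] = rng.choice([-1, 1], size=int(noise.sum()))

    hyper = rng.random(n) < config.hypermutator_fraction
    base_rate = np.where(
        hyper,
        config.baseline_mutation_rate * config.hypermutator_inflation,
        config.baseline_mutation_rate,
    )
    background_counts = rng.poisson(base_rate)

    rows: list[tuple] = []
    onco = list(config.oncogenes)
    target_set = set(config.oncogenes) | set(config.tumor_suppressors)
    non_target = [g for g in genes if g not in target_set]
    copy_driven = rng.random(n) < config.copy_fraction
    for i, sid in enumerate(sample_ids):
        if aberrant[i]:
            gene = onco[rng.integers(len(onco))]
            if copy_driven[i]:
                cnv[i, genes.index(gene)] = 2
            else:
                nt, aa = _VARIANT_POOL[rng.integers(len(_VARIANT_POOL))]
                rows.append((sid, gene, "Missense_Mutation", nt, aa))
        if phenocopy[i]:
            pgene = config.phenocopy_genes[rng.integers(len(config.phenocopy_genes))]
            rows.append((sid, pgene, "Missense_Mutation", "c.1799T>A", "p.V600E"))
        # background mutations: hypermutators draw from all genes (so they hit
        # target genes by chance -- the label noise the burden filter removes);
        # ordinary samples draw from non-target genes only
        pool = genes if hyper[i] else non_target
        k = int(background_counts[i])
        if k:
            hit = rng.choice(pool, size=k, replace=True)
            classes = rng.choice(_BACKGROUND_CLASSES, size=k, p=_BACKGROUND_CLASS_P)
            rows.extend((sid, g, c, None, None) for g, c in zip(hit, classes))

    mut_df = pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "gene_id",
            "variant_classification",
            "nucleotide_change",
            "protein_change",
        ],
    )
    mutations = MutationTable(mut_df, sample_universe=sample_ids)

    non_silent = mut_df[
        mut_df["variant_classification"] != "Silent"
    ]  # total non-silent burden per sample
    burden = non_silent.groupby("sample_id").size().reindex(sample_ids, fill_value=0)
    covariates = CovariateTable(
        pd.DataFrame(
            {"cancer_type": types, "mutation_count": burden.to_numpy()},
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )

    truth = StatusVector(
        status=pd.Series(aberrant.astype(int), index=sample_ids),
        has_mutation_event=pd.Series(aberrant & ~copy_driven, index=sample_ids),
        has_copy_event=pd.Series(aberrant & copy_driven, index=sample_ids),
    )
    return SimulatedCohort(
        expression=ExpressionMatrix(expr_df),
        mutations=mutations,
        copy_number=CopyNumberMatrix(pd.DataFrame(cnv, index=sample_ids, columns=genes)),
        covariates=covariates,
        truth=truth,
        signal_genes=list(signal_genes),
        hypermutators=[s for s, h in zip(sample_ids, hyper) if h],
        phenocopy_samples=[s for s, p in zip(sample_ids, phenocopy) if p],
        spec=config.target_spec,
    )


def simulate_external_profiles(
    model_genes: Sequence[str],
    n_profiles: int,
    mutant_fraction: float,
    effect_size: float,
    seed: int,
    signal_genes: Sequence[str] | None = None,
    location: float = 100.0,
    scale: float = 10.0,
) -> tuple[ExpressionMatrix, pd.Series]:
    """Generate external (cell-line-like) profiles on an arbitrary scale.

    Each gene gets its own mean and variance, distinct from the
    standard-normal training scale, so per-gene z-scoring at transfer time is
    actually exercised.  Mutant profiles carry an ``effect_size``
    (in within-dataset SD units) shift on ``signal_genes`` (default: every
    model gene).
    """
    if not 0.0 <= mutant_fraction <= 1.0:
        raise CohortError("mutant_fraction must lie in [0,1]")
    if n_profiles < 2:
        raise CohortError("at least 2 profiles are required")
    rng = np.random.default_rng(seed)
    model_genes = list(model_genes)
    if signal_genes is None:
        signal_genes = model_genes
    unknown = set(signal_genes) - set(model_genes)
    if unknown:
        raise CohortError(f"signal genes not among model genes: {sorted(unknown)[:5]}")

    mu = location * (0.5 + rng.random(len(model_genes)))
    sd = scale * (0.5 + rng.random(len(model_genes)))
    values = mu + sd * rng.standard_normal((n_profiles, len(model_genes)))
    ids = [f"P{i:04d}" for i in range(1, n_profiles + 1)]
    n_mut = int(round(mutant_fraction * n_profiles))
    labels = np.zeros(n_profiles, dtype=int)
    mutant_idx = rng.choice(n_profiles, size=n_mut, replace=False)
    labels[mutant_idx] = 1
    sig_cols = [model_genes.index(g) for g in signal_genes]
    values[np.ix_(mutant_idx, sig_cols)] += effect_size * sd[sig_cols]

    expr = ExpressionMatrix(pd.DataFrame(values, index=ids, columns=model_genes))
    return expr, pd.Series(labels, index=ids, name="mutant")
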