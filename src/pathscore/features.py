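"""Feature-matrix assembly: MAD-based gene selection, target-gene removal,
covariate encoding, and standardization.

Gene features are the most variably expressed genes ranked by median absolute
deviation, with the target genes themselves removed so the classifier must
learn the downstream transcriptional response rather than target-gene dosage.
Covariates are one 0/1 indicator per retained cancer type (the full set --
no reference level is dropped, since the model is penalized) plus
log10(mutation_count + 1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort_io import CohortError, CovariateTable, ExpressionMatrix, GeneTargetSpec

logger = logging.getLogger(__name__)

#: Column name for the mutation-burden covariate.
BURDEN_FEATURE = "log10_mut"

#: Expanded RASopathy gene panel used by the gene-dropping ablation.
RASOPATHY_PANEL = (
    "BRAF",
    "CBL",
    "HRAS",
    "KRAS",
    "MAP2K1",
    "MAP2K2",
    "NF1",
    "NRAS",
    "PTPN11",
    "RAF1",
    "SHOC2",
    "SOS1",
    "SPRED1",
    "RIT1",
)


@dataclass
class FeatureMatrix:
    """Samples x features design matrix: gene block then covariate block.

    ``means`` / ``sds`` hold the per-feature standardization constants once
    :func:`standardize` has been applied (indicator columns carry none).
    """

    data: pd.DataFrame
    gene_features: list[str]
    covariate_features: list[str]
    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        expected = list(self.gene_features) + list(self.covariate_features)
        if list(self.data.columns) != expected:
            raise CohortError("feature columns must be gene block then covariate block")

    @property
    def sample_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def feature_names(self) -> list[str]:
        return self.data.columns.tolist()

    def subset_samples(self, samples) -> "FeatureMatrix":
        return replace(self, data=self.data.loc[list(samples)])


def median_absolute_deviation(expr: ExpressionMatrix) -> pd.Series:
    """Per-gene MAD = median(|x - median(x)|) across samples."""
    med = expr.data.median(axis=0)
    return (expr.data - med).abs().median(axis=0)


def select_mad_genes(expr: ExpressionMatrix, k: int = 8000) -> list[str]:
    """The ``k`` most variably expressed genes by MAD.

    Ties are broken lexicographically by gene symbol so builds are
    deterministic regardless of input column order.
    """
    if k > len(expr.gene_ids):
        raise CohortError(
            f"requested {k} genes but expression matrix has only {len(expr.gene_ids)}"
        )
    mad = median_absolute_deviation(expr)
    order = sorted(mad.index, key=lambda g: (-mad[g], g))
    return order[:k]


def drop_target_genes(
    gene_list: Sequence[str],
    spec: GeneTargetSpec,
    extra_drop: Iterable[str] = (),
) -> list[str]:
    """Remove the target genes (and any extra panel) from a feature gene list.

    Genes absent from the list are ignored silently.
    """
    drop = set(spec.targets) | set(extra_drop)
    return [g for g in gene_list if g not in drop]


def build_covariates(
    covariates: CovariateTable, retained_types: Sequence[str]
) -> pd.DataFrame:
    """One indicator column per retained cancer type plus log10 burden."""
    retained = sorted(retained_types)
    unseen = set(covariates.cancer_type.unique()) - set(retained)
    if unseen:
        raise CohortError(
            f"samples with cancer types outside the retained set: {sorted(unseen)}"
        )
    block = pd.DataFrame(index=covariates.data.index)
    for ctype in retained:
        block[ctype] = (covariates.cancer_type == ctype).astype(float)
    block[BURDEN_FEATURE] = np.log10(covariates.mutation_count + 1.0)
    return block


def assemble_features(
    expr: ExpressionMatrix,
    genes: Sequence[str],
    covariates: CovariateTable | None = None,
    retained_types: Sequence[str] | None = None,
    include_type_indicators: bool = True,
) -> FeatureMatrix:
    """Concatenate the gene block and (optionally) the covariate block.

    Pass ``covariates=None`` for an expression-only design, or an empty
    ``genes`` list for a covariate-only design.
    """
    genes = list(genes)
    blocks = [expr.data.loc[:, genes]]
    covariate_features: list[str] = []
    if covariates is not None:
        if retained_types is None:
            retained_types = sorted(covariates.cancer_type.unique())
        block = build_covariates(covariates.subset_samples(expr.sample_ids), retained_types)
        if not include_type_indicators:
            block = block[[BURDEN_FEATURE]]
        covariate_features = block.columns.tolist()
        blocks.append(block)
    data = pd.concat(blocks, axis=1)
    return FeatureMatrix(
        data=data, gene_features=genes, covariate_features=covariate_features
    )


def standardize(features: FeatureMatrix, fit_on: Sequence[str]) -> FeatureMatrix:
    """Center/scale gene columns and the burden column to mean 0, SD 1.

    Constants are estimated on ``fit_on`` only (the training partition) and
    applied to every sample.  Cancer-type indicator columns are left
    untouched.  Zero-SD features are dropped with a warning.
    """
    fit_on = list(fit_on)
    if not fit_on:
        raise CohortError("standardize requires a non-empty fitting subset")
    to_scale = list(features.gene_features) + (
        [BURDEN_FEATURE] if BURDEN_FEATURE in features.covariate_features else []
    )
    ref = features.data.loc[fit_on, to_scale]
    means = ref.mean(axis=0)
    sds = ref.std(axis=0, ddof=0)
    constant = sds[sds == 0.0].index.tolist()
    if constant:
        warnings.warn(
            f"dropping {len(constant)} zero-variance features, e.g. {constant[:5]}",
            stacklevel=2,
        )
    keep = [f for f in to_scale if f not in set(constant)]
    data = features.data.drop(columns=constant)
    data.loc[:, keep] = (data[keep] - means[keep]) / sds[keep]
    return FeatureMatrix(
        data=data,
        gene_features=[g for g in features.gene_features if g not in set(constant)],
        covariate_features=[
            c for c in features.covariate_features if c not in set(constant)
        ],
        means={f: float(means[f]) for f in keep},
        sds={f: float(sds[f]) for f in keep},
    )
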