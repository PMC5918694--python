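"""Binary aberration labels from mutation + copy-number evidence, and the
sample/cancer-type filters applied before training.

A sample is labeled aberrant (status 1) when it carries any non-silent
mutation in a target gene, a high copy gain (+2) in a target oncogene, or a
deep copy loss (-2) in a target tumor suppressor.  Hypermutated samples --
extreme outliers of the log10 mutation-burden distribution -- are removed
before training because they carry target-gene mutations by chance; cancer
types with too few events or too low a positive fraction are excluded to keep
the training set reasonably balanced.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_io import (
    CohortError,
    CopyNumberMatrix,
    CovariateTable,
    GeneTargetSpec,
    MutationTable,
    NON_SILENT_CLASSES,
)

logger = logging.getLogger(__name__)


@dataclass
class StatusVector:
    """Per-sample binary aberration status with evidence provenance flags."""

    status: pd.Series
    has_mutation_event: pd.Series
    has_copy_event: pd.Series

    def __post_init__(self):
        self.status = self.status.astype(int)
        self.has_mutation_event = self.has_mutation_event.astype(bool)
        self.has_copy_event = self.has_copy_event.astype(bool)
        expected = (self.has_mutation_event | self.has_copy_event).astype(int)
        if not expected.equals(self.status):
            raise CohortError("status must equal (mutation event OR copy event)")

    @property
    def sample_ids(self) -> list[str]:
        return self.status.index.tolist()

    @property
    def n_positive(self) -> int:
        return int(self.status.sum())

    def subset_samples(self, samples) -> "StatusVector":
        samples = list(samples)
        return StatusVector(
            status=self.status.loc[samples],
            has_mutation_event=self.has_mutation_event.loc[samples],
            has_copy_event=self.has_copy_event.loc[samples],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "status": self.status,
                "has_mutation_event": self.has_mutation_event.astype(int),
                "has_copy_event": self.has_copy_event.astype(int),
            }
        ).rename_axis("sample_id")


@dataclass
class FilterReport:
    """What a filtering step removed and why; retained/removed partition the input."""

    retained_samples: list[str] = field(default_factory=list)
    removed_hypermutators: dict[str, float] = field(default_factory=dict)
    threshold: float | None = None
    retained_cancer_types: list[str] = field(default_factory=list)
    excluded_cancer_types: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "retained_samples": list(self.retained_samples),
            "removed_hypermutators": dict(self.removed_hypermutators),
            "threshold": self.threshold,
            "retained_cancer_types": list(self.retained_cancer_types),
            "excluded_cancer_types": list(self.excluded_cancer_types),
        }


def build_status(
    mutations: MutationTable,
    cnv: CopyNumberMatrix,
    spec: GeneTargetSpec,
    non_silent_classes: frozenset[str] = NON_SILENT_CLASSES,
) -> StatusVector:
    """Integrate mutation and copy-number evidence into binary labels.

    The sample universe is taken from the copy-number matrix rows.  Target
    genes absent from both the mutation table and the copy-number columns
    contribute nothing and trigger a warning, not an error.
    """
    samples = cnv.sample_ids
    sample_index = pd.Index(samples)

    mut_rows = mutations.non_silent(non_silent_classes)
    mut_rows = mut_rows[mut_rows["gene_id"].isin(set(spec.targets))]
    has_mut = pd.Series(False, index=sample_index)
    if len(mut_rows):
        has_mut.loc[mut_rows["sample_id"].unique()] = True

    has_copy = pd.Series(False, index=sample_index)
    onco_cols = [g for g in spec.oncogenes if g in cnv.data.columns]
    ts_cols = [g for g in spec.tumor_suppressors if g in cnv.data.columns]
    if onco_cols:
        has_copy |= (cnv.data[onco_cols] == 2).any(axis=1)
    if ts_cols:
        has_copy |= (cnv.data[ts_cols] == -2).any(axis=1)

    mutated_genes = set(mutations.data["gene_id"].unique())
    for gene in spec.targets:
        if gene not in mutated_genes and gene not in cnv.data.columns:
            warnings.warn(
                f"target gene {gene!r} absent from both mutation table and "
                "copy-number matrix; it contributes no events",
                stacklevel=2,
            )

    return StatusVector(
        status=(has_mut | has_copy).astype(int),
        has_mutation_event=has_mut,
        has_copy_event=has_copy,
    )


def filter_hypermutators(
    covariates: CovariateTable, n_sd: float = 5.0
) -> FilterReport:
    """Remove samples more than ``n_sd`` SDs above the mean log10 burden.

    Burden is log10(mutation_count + 1); the +1 guards zero counts.  With
    fewer than two samples the SD is undefined and nothing is removed.
    """
    counts = covariates.mutation_count
    if len(counts) == 0:
        raise CohortError("cannot filter hypermutators on an empty cohort")
    log_counts = np.log10(counts + 1.0)
    if len(counts) < 2:
        warnings.warn("fewer than 2 samples; hypermutator SD undefined, none removed")
        return FilterReport(retained_samples=list(counts.index), threshold=None)
    threshold = float(log_counts.mean() + n_sd * log_counts.std(ddof=1))
    removed = log_counts[log_counts > threshold]
    retained = log_counts.index.difference(removed.index, sort=False)
    if len(removed):
        logger.info("removed %d hypermutated samples (log10 burden > %.3f)",
                    len(removed), threshold)
    return FilterReport(
        retained_samples=retained.tolist(),
        removed_hypermutators={s: float(v) for s, v in removed.items()},
        threshold=threshold,
    )


def filter_cancer_types(
    status: StatusVector,
    covariates: CovariateTable,
    min_events: int = 15,
    min_proportion: float = 0.05,
) -> FilterReport:
    """Retain cancer types with > ``min_events`` positives and a positive
    fraction of at least ``min_proportion``."""
    samples = status.sample_ids
    types = covariates.cancer_type.loc[samples]
    retained_types: list[str] = []
    excluded: list[dict] = []
    for ctype, members in types.groupby(types):
        n = len(members)
        n_pos = int(status.status.loc[members.index].sum())
        frac = n_pos / n if n else float("nan")
        record = {
            "cancer_type": ctype,
            "n_samples": n,
            "n_events": n_pos,
            "positive_proportion": frac,
        }
        if n > 0 and n_pos > min_events and frac >= min_proportion:
            retained_types.append(ctype)
        else:
            if n == 0:
                record["empty"] = True
            excluded.append(record)
    retained_types = sorted(retained_types)
    retained_samples = [s for s in samples if types.loc[s] in set(retained_types)]
    return FilterReport(
        retained_samples=retained_samples,
        retained_cancer_types=retained_types,
        excluded_cancer_types=excluded,
    )
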