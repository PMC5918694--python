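"""Cohort file I/O and the core data structures shared by the pipeline.

File conventions follow TCGA pan-cancer matrix releases: tab-separated text
with a header row.  Expression and copy-number matrices are samples x genes
with the sample identifier in the first column; somatic mutations arrive as a
long MAF-like table; covariates as one row per sample.  Gene identifiers are
treated as opaque symbols -- no alias resolution is attempted.

Fitted classifiers are persisted as a single self-describing text artifact
(key-value header plus a per-feature weight table) with a format-version tag.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MODEL_FORMAT_TAG = "pathscore-model"
MODEL_FORMAT_VERSION = "v1"

#: Variant classes treated as protein-altering when building aberration labels:
#: any class that changes protein sequence or splicing (missense, truncating,
#: in-frame and frameshift indels, splice-site, nonstop, translation-start).
NON_SILENT_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Splice_Site",
        "Nonstop_Mutation",
        "Translation_Start_Site",
    }
)

SILENT_CLASSES = frozenset(
    {"Silent", "3'UTR", "5'UTR", "3'Flank", "5'Flank", "Intron", "RNA", "IGR"}
)

#: Controlled vocabulary for ``variant_classification``.
VARIANT_CLASSIFICATIONS = NON_SILENT_CLASSES | SILENT_CLASSES

#: Standard MAF column names mapped onto the internal mutation-table schema.
MAF_COLUMN_MAP: dict[str, str] = {
    "Tumor_Sample_Barcode": "sample_id",
    "Hugo_Symbol": "gene_id",
    "Variant_Classification": "variant_classification",
    "HGVSc": "nucleotide_change",
    "HGVSp": "protein_change",
}

_MUTATION_COLUMNS = (
    "sample_id",
    "gene_id",
    "variant_classification",
    "nucleotide_change",
    "protein_change",
)


class CohortError(ValueError):
    """A cohort file or structure violates a structural invariant."""


class ModelFormatError(ValueError):
    """A model artifact is missing, truncated, or of an unknown version."""


def _check_unique(values: Sequence, what: str) -> None:
    index = pd.Index(values)
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()[:5]
        raise CohortError(f"duplicate {what}: {dups}")


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise CohortError(f"input file not found: {path}")
    kwargs.setdefault("float_precision", "round_trip")
    try:
        return pd.read_csv(path, sep="\t", **kwargs)
    except Exception as exc:  # pandas raises several parser error types
        raise CohortError(f"failed to parse TSV {path}: {exc}") from exc


class ExpressionMatrix:
    """Samples x genes matrix of continuous expression values.

    Missing entries are a hard error (no imputation is defined); duplicate
    sample or gene identifiers are rejected.
    """

    def __init__(self, data: pd.DataFrame):
        _check_unique(data.index, "sample identifiers")
        _check_unique(data.columns, "gene identifiers")
        try:
            data = data.astype(float)
        except (TypeError, ValueError) as exc:
            raise CohortError(f"non-numeric expression values: {exc}") from exc
        if data.isna().any().any():
            bad = data.isna().any(axis=1)
            raise CohortError(
                "missing expression values for samples "
                f"{data.index[bad].tolist()[:5]}; rows with missing entries are "
                "rejected, not imputed"
            )
        self.data = data
        self.data.index.name = "sample_id"

    @property
    def sample_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def gene_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(samples)])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        return cls(_read_tsv(path, index_col=0))

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t")


class CopyNumberMatrix:
    """Samples x genes matrix of GISTIC-style threshold calls in {-2..2}."""

    VALID_CALLS = (-2, -1, 0, 1, 2)

    def __init__(self, data: pd.DataFrame):
        _check_unique(data.index, "sample identifiers")
        _check_unique(data.columns, "gene identifiers")
        try:
            data = data.astype(int)
        except (TypeError, ValueError) as exc:
            raise CohortError(f"non-integer copy-number calls: {exc}") from exc
        arr = data.to_numpy()
        bad = ~np.isin(arr, self.VALID_CALLS)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise CohortError(
                f"invalid copy-number call {arr[i, j]} at sample "
                f"{data.index[i]!r}, gene {data.columns[j]!r}; "
                "calls must be one of -2, -1, 0, 1, 2"
            )
        self.data = data
        self.data.index.name = "sample_id"

    @property
    def sample_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def gene_ids(self) -> list[str]:
        return self.data.columns.tolist()

    def subset_samples(self, samples: Sequence[str]) -> "CopyNumberMatrix":
        return CopyNumberMatrix(self.data.loc[list(samples)])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CopyNumberMatrix":
        return cls(_read_tsv(path, index_col=0))

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t")


class MutationTable:
    """Long-format somatic mutation table (one row per sample x variant call).

    Parameters
    ----------
    data
        Frame with columns ``sample_id``, ``gene_id``,
        ``variant_classification`` and optional ``nucleotide_change`` /
        ``protein_change`` (standard MAF headers are renamed on read).
    sample_universe
        When given, rows for samples outside the universe are rejected.
    validate_classes
        Check ``variant_classification`` against the controlled vocabulary.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        sample_universe: Sequence[str] | None = None,
        validate_classes: bool = True,
    ):
        data = data.rename(columns=MAF_COLUMN_MAP).copy()
        for col in ("sample_id", "gene_id", "variant_classification"):
            if col not in data.columns:
                raise CohortError(f"mutation table missing required column {col!r}")
        for col in ("nucleotide_change", "protein_change"):
            if col not in data.columns:
                data[col] = pd.NA
        data = data.loc[:, list(_MUTATION_COLUMNS)].reset_index(drop=True)
        if validate_classes:
            seen = set(data["variant_classification"].dropna().unique())
            unknown = seen - VARIANT_CLASSIFICATIONS
            if unknown:
                raise CohortError(
                    f"unknown variant classifications {sorted(unknown)}; "
                    f"expected members of {sorted(VARIANT_CLASSIFICATIONS)}"
                )
        if sample_universe is not None:
            extra = set(data["sample_id"]) - set(sample_universe)
            if extra:
                raise CohortError(
                    f"mutation table contains {len(extra)} samples outside the "
                    f"cohort sample universe, e.g. {sorted(extra)[:5]}"
                )
        self.data = data

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.data["sample_id"].unique().tolist())

    def subset_samples(self, samples: Sequence[str]) -> "MutationTable":
        keep = self.data["sample_id"].isin(set(samples))
        return MutationTable(self.data.loc[keep], validate_classes=False)

    def non_silent(self, classes: frozenset[str] = NON_SILENT_CLASSES) -> pd.DataFrame:
        return self.data[self.data["variant_classification"].isin(classes)]

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        column_map: Mapping[str, str] | None = None,
        **kwargs,
    ) -> "MutationTable":
        data = _read_tsv(path)
        if column_map:
            data = data.rename(columns=dict(column_map))
        return cls(data, **kwargs)

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


class CovariateTable:
    """Per-sample covariates: cancer type and total non-silent mutation count."""

    def __init__(self, data: pd.DataFrame):
        data = data.copy()
        if data.index.name != "sample_id" and "sample_id" in data.columns:
            data = data.set_index("sample_id")
        _check_unique(data.index, "sample identifiers")
        for col in ("cancer_type", "mutation_count"):
            if col not in data.columns:
                raise CohortError(f"covariate table missing column {col!r}")
        if data["cancer_type"].isna().any() or (data["cancer_type"] == "").any():
            raise CohortError("cancer_type must be non-empty for every sample")
        counts = data["mutation_count"]
        if counts.isna().any() or (counts < 0).any():
            raise CohortError("mutation_count must be a non-negative integer")
        data["mutation_count"] = counts.astype(int)
        self.data = data.loc[:, ["cancer_type", "mutation_count"]]
        self.data.index.name = "sample_id"

    @property
    def sample_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def cancer_type(self) -> pd.Series:
        return self.data["cancer_type"]

    @property
    def mutation_count(self) -> pd.Series:
        return self.data["mutation_count"]

    def subset_samples(self, samples: Sequence[str]) -> "CovariateTable":
        return CovariateTable(self.data.loc[list(samples)])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CovariateTable":
        return cls(_read_tsv(path, index_col=0))

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t")


@dataclass(frozen=True)
class GeneTargetSpec:
    """Target genes defining the aberration of interest.

    ``oncogenes`` count high copy gains (+2) as events; ``tumor_suppressors``
    count deep losses (-2).  Non-silent mutations count for both classes.
    ``pathway_genes`` is an optional wider panel used for multi-hit analyses.
    """

    oncogenes: tuple[str, ...]
    tumor_suppressors: tuple[str, ...] = ()
    pathway_genes: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "oncogenes", tuple(self.oncogenes))
        object.__setattr__(self, "tumor_suppressors", tuple(self.tumor_suppressors))
        object.__setattr__(self, "pathway_genes", tuple(self.pathway_genes))
        overlap = set(self.oncogenes) & set(self.tumor_suppressors)
        if overlap:
            raise CohortError(
                f"genes listed as both oncogene and tumor suppressor: {sorted(overlap)}"
            )
        if not (self.oncogenes or self.tumor_suppressors):
            raise CohortError("at least one target gene is required")

    @property
    def targets(self) -> tuple[str, ...]:
        return tuple(self.oncogenes) + tuple(self.tumor_suppressors)

    @property
    def other_pathway_genes(self) -> tuple[str, ...]:
        """Pathway panel members outside the core target genes."""
        core = set(self.targets)
        return tuple(g for g in self.pathway_genes if g not in core)


@dataclass
class ClassifierModel:
    """A fitted elastic-net logistic classifier.

    ``feature_means`` / ``feature_sds`` hold the training-time standardization
    constants for every standardized feature (gene columns and the mutation
    burden column); cancer-type indicator columns are not standardized and so
    carry no constants.
    """

    gene_weights: dict[str, float]
    covariate_weights: dict[str, float]
    intercept: float
    alpha: float
    l1_ratio: float
    feature_means: dict[str, float]
    feature_sds: dict[str, float]
    target_spec: GeneTargetSpec | None = None
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        missing = [
            g
            for g, w in self.gene_weights.items()
            if w != 0.0 and g not in self.feature_means
        ]
        if missing:
            raise ModelFormatError(
                f"weighted genes lack standardization constants: {missing[:5]}"
            )
        bad_sd = [f for f, s in self.feature_sds.items() if not s > 0]
        if bad_sd:
            raise ModelFormatError(
                f"non-positive standard deviations for features: {bad_sd[:5]}"
            )

    @property
    def nonzero_genes(self) -> list[str]:
        return [g for g, w in self.gene_weights.items() if w != 0.0]

    def prune_zero_genes(self) -> "ClassifierModel":
        """Drop zero-weight genes (and their constants) from the model."""
        keep = {g: w for g, w in self.gene_weights.items() if w != 0.0}
        kept = set(keep) | set(self.covariate_weights)
        return ClassifierModel(
            gene_weights=keep,
            covariate_weights=dict(self.covariate_weights),
            intercept=self.intercept,
            alpha=self.alpha,
            l1_ratio=self.l1_ratio,
            feature_means={f: m for f, m in self.feature_means.items() if f in kept},
            feature_sds={f: s for f, s in self.feature_sds.items() if f in kept},
            target_spec=self.target_spec,
            metadata=dict(self.metadata),
        )


def load_cohort(
    expression_path: str | Path,
    mutation_path: str | Path,
    cnv_path: str | Path,
    covariate_path: str | Path,
    mutation_column_map: Mapping[str, str] | None = None,
) -> tuple[ExpressionMatrix, MutationTable, CopyNumberMatrix, CovariateTable]:
    """Load the four cohort files and restrict all to their shared samples.

    The shared sample set is the intersection of the expression, copy-number
    and covariate tables (a sample with zero mutation rows is legitimate, so
    the mutation table does not constrain the universe).  Sample ordering is
    canonicalized to lexicographic order, so loading the same files twice
    yields identical orderings.
    """
    expr = ExpressionMatrix.from_tsv(expression_path)
    cnv = CopyNumberMatrix.from_tsv(cnv_path)
    cov = CovariateTable.from_tsv(covariate_path)
    muts = MutationTable.from_tsv(mutation_path, column_map=mutation_column_map)

    sets = {
        "expression": set(expr.sample_ids),
        "copy_number": set(cnv.sample_ids),
        "covariates": set(cov.sample_ids),
    }
    shared = sorted(sets["expression"] & sets["copy_number"] & sets["covariates"])
    if not shared:
        raise CohortError("no samples shared across expression, copy-number and covariates")
    for name, ids in sets.items():
        dropped = len(ids) - len(shared)
        if dropped:
            logger.warning("dropping %d %s samples absent from other inputs", dropped, name)
    extra_mut = set(muts.data["sample_id"]) - set(shared)
    if extra_mut:
        logger.warning(
            "dropping mutation rows for %d samples outside the shared cohort", len(extra_mut)
        )
    return (
        expr.subset_samples(shared),
        muts.subset_samples(shared),
        cnv.subset_samples(shared),
        cov.subset_samples(shared),
    )


def _fmt(x: float) -> str:
    # repr() gives the shortest string that round-trips the float exactly
    return repr(float(x))


def save_model(model: ClassifierModel, path: str | Path) -> None:
    """Write a model artifact; zero-weight genes are pruned on save."""
    model = model.prune_zero_genes()
    lines = [f"#{MODEL_FORMAT_TAG}\t{MODEL_FORMAT_VERSION}"]
    lines.append(f"alpha\t{_fmt(model.alpha)}")
    lines.append(f"l1_ratio\t{_fmt(model.l1_ratio)}")
    lines.append(f"intercept\t{_fmt(model.intercept)}")
    spec = model.target_spec
    lines.append("oncogenes\t" + ",".join(spec.oncogenes if spec else ()))
    lines.append("tumor_suppressors\t" + ",".join(spec.tumor_suppressors if spec else ()))
    lines.append("pathway_genes\t" + ",".join(spec.pathway_genes if spec else ()))
    for key in sorted(model.metadata):
        lines.append(f"meta:{key}\t{model.metadata[key]}")
    lines.append("#features")
    lines.append("name\tkind\tweight\tmean\tsd")

    def _row(name: str, kind: str, weight: float) -> str:
        mean = model.feature_means.get(name)
        sd = model.feature_sds.get(name)
        return "\t".join(
            [
                name,
                kind,
                _fmt(weight),
                "" if mean is None else _fmt(mean),
                "" if sd is None else _fmt(sd),
            ]
        )

    for gene in sorted(model.gene_weights):
        lines.append(_row(gene, "gene", model.gene_weights[gene]))
    for cov in sorted(model.covariate_weights):
        lines.append(_row(cov, "covariate", model.covariate_weights[cov]))
    lines.append("#end")
    Path(path).write_text("\n".join(lines) + "\n")


def load_model(path: str | Path) -> ClassifierModel:
    """Read a model artifact written by :func:`save_model`."""
    path = Path(path)
    if not path.exists():
        raise ModelFormatError(f"model file not found: {path}")
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith(f"#{MODEL_FORMAT_TAG}"):
        raise ModelFormatError(f"{path} is not a {MODEL_FORMAT_TAG} artifact")
    version = lines[0].split("\t")[1] if "\t" in lines[0] else ""
    if version != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"unsupported model format version {version!r}; expected {MODEL_FORMAT_VERSION}"
        )
    if not lines[-1].startswith("#end"):
        raise ModelFormatError(f"{path} is truncated (missing #end sentinel)")

    header: dict[str, str] = {}
    metadata: dict[str, str] = {}
    i = 1
    while i < len(lines) and lines[i] != "#features":
        key, _, value = lines[i].partition("\t")
        if key.startswith("meta:"):
            metadata[key[5:]] = value
        else:
            header[key] = value
        i += 1
    if i >= len(lines):
        raise ModelFormatError(f"{path} has no feature table")
    i += 2  # skip '#features' and the column header

    gene_weights: dict[str, float] = {}
    covariate_weights: dict[str, float] = {}
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    for line in lines[i:-1]:
        parts = line.split("\t")
        if len(parts) != 5:
            raise ModelFormatError(f"malformed feature row in {path}: {line!r}")
        name, kind, weight, mean, sd = parts
        w = float(weight)
        if kind == "gene":
            gene_weights[name] = w
        elif kind == "covariate":
            covariate_weights[name] = w
        else:
            raise ModelFormatError(f"unknown feature kind {kind!r} in {path}")
        if mean:
            means[name] = float(mean)
        if sd:
            sds[name] = float(sd)

    def _genes(key: str) -> tuple[str, ...]:
        raw = header.get(key, "")
        return tuple(g for g in raw.split(",") if g)

    spec = None
    if _genes("oncogenes") or _genes("tumor_suppressors"):
        spec = GeneTargetSpec(
            oncogenes=_genes("oncogenes"),
            tumor_suppressors=_genes("tumor_suppressors"),
            pathway_genes=_genes("pathway_genes"),
        )
    try:
        return ClassifierModel(
            gene_weights=gene_weights,
            covariate_weights=covariate_weights,
            intercept=float(header["intercept"]),
            alpha=float(header["alpha"]),
            l1_ratio=float(header["l1_ratio"]),
            feature_means=means,
            feature_sds=sds,
            target_spec=spec,
            metadata=metadata,
        )
    except KeyError as exc:
        raise ModelFormatError(f"model header missing field {exc} in {path}") from exc
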