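"""Apply a trained classifier to external expression profiles (cell lines)
and run the downstream variant-level statistics.

Transfer scoring z-normalizes each gene within the external dataset itself
(not with the training constants), subsets to the classifier's genes, and
applies the logistic transform to the weighted sum.  Covariate terms are
omitted -- external profiles carry no cancer-type or burden covariates.
Downstream analyses: confusion metrics, variant-level mean scores, 2x2
enrichment chi-square, Welch t-tests between score groups, per-drug linear
regressions with a Bonferroni threshold, and multi-hit stratification over a
wider pathway panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .cohort_io import (
    ClassifierModel,
    CohortError,
    CopyNumberMatrix,
    ExpressionMatrix,
    GeneTargetSpec,
    MutationTable,
    NON_SILENT_CLASSES,
)

logger = logging.getLogger(__name__)


class CoverageError(RuntimeError):
    """External data covers too few classifier genes to score reliably."""


@dataclass
class TransferScoreTable:
    """Per-profile transfer scores with gene-coverage accounting."""

    scores: pd.Series  # profile_id -> score in (0,1)
    n_model_genes_found: int
    n_model_genes_total: int
    threshold: float = 0.5

    @property
    def coverage(self) -> float:
        return self.n_model_genes_found / self.n_model_genes_total

    @property
    def hard_labels(self) -> pd.Series:
        return (self.scores > self.threshold).astype(int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"score": self.scores, "predicted": self.hard_labels}
        ).rename_axis("profile_id")


def score_external(
    model: ClassifierModel,
    expr: ExpressionMatrix,
    min_coverage: float = 0.9,
    threshold: float = 0.5,
) -> TransferScoreTable:
    """Score external profiles with the model's gene weights.

    Genes are z-scored within the external dataset; model genes missing from
    the data (or with zero variance) contribute 0.  Scoring is refused when
    fewer than ``min_coverage`` of the model's weighted genes are present.
    """
    gene_w = {g: w for g, w in model.gene_weights.items() if w != 0.0}
    if not gene_w:
        raise CohortError("model has no nonzero gene weights")
    present = [g for g in sorted(gene_w) if g in set(expr.gene_ids)]
    coverage = len(present) / len(gene_w)
    if coverage < min_coverage:
        missing = sorted(set(gene_w) - set(present))
        raise CoverageError(
            f"only {len(present)}/{len(gene_w)} model genes "
            f"({coverage:.1%}) found in external data (minimum "
            f"{min_coverage:.0%}); missing e.g. {missing[:10]}"
        )
    X = expr.data[present]
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    # zero-variance genes contribute nothing (divide-by-zero -> NaN -> 0)
    Z = ((X - mu) / sd.replace(0.0, np.nan)).fillna(0.0)
    w = np.array([gene_w[g] for g in present])
    total = Z.to_numpy() @ w + model.intercept
    scores = pd.Series(expit(total), index=expr.sample_ids, name="score")
    return TransferScoreTable(
        scores=scores,
        n_model_genes_found=len(present),
        n_model_genes_total=len(gene_w),
        threshold=threshold,
    )


@dataclass
class ConfusionMetrics:
    """Confusion counts at a fixed threshold with derived percentages.

    Ratios whose denominator is empty are NaN and flagged.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def precision_pct(self) -> float:
        denom = self.tp + self.fp
        return 100.0 * self.tp / denom if denom else float("nan")

    @property
    def npv_pct(self) -> float:
        denom = self.tn + self.fn
        return 100.0 * self.tn / denom if denom else float("nan")

    @property
    def accuracy_pct(self) -> float:
        return 100.0 * (self.tp + self.tn) / self.n

    @property
    def undefined(self) -> list[str]:
        flags = []
        if self.tp + self.fp == 0:
            flags.append("precision")
        if self.tn + self.fn == 0:
            flags.append("npv")
        return flags


def confusion_metrics(scores, labels, threshold: float = 0.5) -> ConfusionMetrics:
    """Standard confusion counts of thresholded scores against binary labels."""
    scores = pd.Series(scores)
    labels = pd.Series(labels)
    if not scores.index.equals(labels.index):
        if set(scores.index) <= set(labels.index):
            labels = labels.loc[scores.index]
        elif len(scores) == len(labels):
            labels = pd.Series(labels.to_numpy(), index=scores.index)
        else:
            raise CohortError("scores and labels cannot be aligned")
    pred = (scores.to_numpy(dtype=float) > threshold).astype(int)
    y = labels.to_numpy(dtype=int)
    return ConfusionMetrics(
        tp=int(((pred == 1) & (y == 1)).sum()),
        fp=int(((pred == 1) & (y == 0)).sum()),
        tn=int(((pred == 0) & (y == 0)).sum()),
        fn=int(((pred == 0) & (y == 1)).sum()),
    )


def aggregate_variant_scores(
    scores,
    mutations: MutationTable,
    level: str = "protein",
    genes: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Mean classifier score per distinct (gene, change) variant key.

    ``level`` selects the nucleotide- or protein-level change identifier.
    Mutation rows lacking that field, or for unscored samples, are skipped
    (the skipped counts are logged).
    """
    if level not in {"nucleotide", "protein"}:
        raise CohortError(f"level must be 'nucleotide' or 'protein', got {level!r}")
    scores = pd.Series(scores) if not isinstance(scores, pd.Series) else scores
    col = "nucleotide_change" if level == "nucleotide" else "protein_change"
    rows = mutations.data
    if genes is not None:
        rows = rows[rows["gene_id"].isin(set(genes))]
    n_total = len(rows)
    rows = rows[rows["sample_id"].isin(set(scores.index))]
    n_unscored = n_total - len(rows)
    rows = rows[rows[col].notna()]
    n_missing_field = n_total - n_unscored - len(rows)
    if n_unscored or n_missing_field:
        logger.info(
            "variant aggregation skipped %d rows for unscored samples and %d "
            "rows lacking the %s field",
            n_unscored,
            n_missing_field,
            col,
        )
    if not len(rows):
        return pd.DataFrame(columns=["gene", "change", "n_samples", "mean_score"])
    merged = rows.assign(score=rows["sample_id"].map(scores))
    agg = (
        merged.groupby(["gene_id", col])["score"]
        .agg(n_samples="size", mean_score="mean")
        .reset_index()
        .rename(columns={"gene_id": "gene", col: "change"})
    )
    return agg.sort_values(["gene", "change"]).reset_index(drop=True)


def enrichment_chi2(
    group_a: tuple[int, int], group_b: tuple[int, int]
) -> tuple[float, int, float]:
    """Pearson chi-square (no continuity correction) on the 2x2 table built
    from two (successes, total) groups."""
    (k_a, n_a), (k_b, n_b) = group_a, group_b
    if n_a <= 0 or n_b <= 0:
        raise CohortError("both groups must have positive totals")
    table = np.array([[k_a, n_a - k_a], [k_b, n_b - k_b]], dtype=float)
    if (table < 0).any():
        raise CohortError("successes cannot exceed totals")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise CohortError("chi-square undefined: a table margin is zero")
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(dof), float(p)


def score_group_test(scores_a, scores_b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test between two score groups.

    Returns (t, Welch-Satterthwaite df, two-sided p).  Two zero-variance
    groups with equal means give t = 0, p = 1 by convention.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise CohortError("both groups need at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        return float(np.inf) if a.mean() > b.mean() else float(-np.inf), float(
            len(a) + len(b) - 2
        ), 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def drug_response_regression(
    scores,
    activity_table: pd.DataFrame,
    group_labels,
    family_alpha: float = 0.05,
    min_cell_size: int = 3,
) -> pd.DataFrame:
    """Per-(drug, group) linear regression of drug activity on classifier
    score, with a Bonferroni significance threshold of
    ``family_alpha / (n_drugs * n_groups)``.

    ``activity_table`` has columns (profile_id, drug, activity);
    ``group_labels`` maps profile_id to a group (e.g. mutant / wild-type).
    Cells with fewer than ``min_cell_size`` profiles are flagged, not fit.
    """
    for col in ("profile_id", "drug", "activity"):
        if col not in activity_table.columns:
            raise CohortError(f"activity table missing column {col!r}")
    scores = pd.Series(scores)
    groups = pd.Series(group_labels)
    drugs = sorted(activity_table["drug"].unique())
    levels = sorted(groups.unique())
    threshold = family_alpha / (len(drugs) * len(levels))
    rows = []
    for drug in drugs:
        sub = activity_table[activity_table["drug"] == drug]
        sub = sub[sub["profile_id"].isin(scores.index)]
        for level in levels:
            ids = [
                p
                for p in sub["profile_id"]
                if p in groups.index and groups.loc[p] == level
            ]
            cell = sub[sub["profile_id"].isin(ids)]
            row = {"drug": drug, "group": level, "n": len(cell)}
            if len(cell) < min_cell_size:
                row.update(
                    slope=np.nan, stderr=np.nan, r=np.nan, p=np.nan,
                    significant=False, flagged=True,
                )
            else:
                x = scores.loc[cell["profile_id"]].to_numpy()
                yv = cell["activity"].to_numpy(dtype=float)
                fit = stats.linregress(x, yv)
                row.update(
                    slope=float(fit.slope),
                    stderr=float(fit.stderr),
                    r=float(fit.rvalue),
                    p=float(fit.pvalue),
                    significant=bool(fit.pvalue < threshold),
                    flagged=False,
                )
            rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["bonferroni_threshold"] = threshold
    return out


def multi_hit_stratification(
    scores,
    mutations: MutationTable,
    cnv: CopyNumberMatrix,
    spec: GeneTargetSpec,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Classifier scores stratified by core-gene status and the number of
    hits in other pathway members.

    For every sample: core status is 1 when it carries a non-silent mutation
    in a core target gene or a high-level copy event there; "other hits" are
    counted separately for mutations (non-silent calls in pathway genes
    outside the core set) and copy events (|call| = 2 in those genes), then
    bucketed 0 / 1 / 2 / 3+.  Each (evidence, core status, bucket) cell
    reports n, the fraction scoring above ``threshold``, and the mean score.
    """
    if not spec.other_pathway_genes:
        raise CohortError("spec.pathway_genes must extend beyond the core targets")
    scores = pd.Series(scores)
    samples = scores.index.tolist()
    core = set(spec.targets)
    other = set(spec.other_pathway_genes)

    ns = mutations.non_silent()
    ns = ns[ns["sample_id"].isin(set(samples))]
    core_mut = set(ns[ns["gene_id"].isin(core)]["sample_id"])
    core_copy: set[str] = set()
    onco_cols = [g for g in spec.oncogenes if g in cnv.data.columns]
    ts_cols = [g for g in spec.tumor_suppressors if g in cnv.data.columns]
    sub_cnv = cnv.data.loc[[s for s in samples if s in cnv.data.index]]
    if onco_cols:
        core_copy |= set(sub_cnv.index[(sub_cnv[onco_cols] == 2).any(axis=1)])
    if ts_cols:
        core_copy |= set(sub_cnv.index[(sub_cnv[ts_cols] == -2).any(axis=1)])
    core_status = pd.Series(
        [1 if s in (core_mut | core_copy) else 0 for s in samples], index=samples
    )

    other_mut_counts = (
        ns[ns["gene_id"].isin(other)]
        .groupby("sample_id")["gene_id"]
        .nunique()
        .reindex(samples, fill_value=0)
    )
    other_cols = [g for g in sorted(other) if g in cnv.data.columns]
    if other_cols:
        other_copy_counts = (
            (sub_cnv[other_cols].abs() == 2).sum(axis=1).reindex(samples, fill_value=0)
        )
    else:
        other_copy_counts = pd.Series(0, index=samples)

    def bucket(k: int) -> str:
        return str(k) if k < 3 else "3+"

    rows = []
    for evidence, counts in (
        ("mutation", other_mut_counts),
        ("copy", other_copy_counts),
    ):
        frame = pd.DataFrame(
            {
                "core_status": core_status,
                "bucket": counts.map(bucket),
                "score": scores,
            }
        )
        for (st, bk), cell in frame.groupby(["core_status", "bucket"]):
            rows.append(
                {
                    "evidence": evidence,
                    "core_status": int(st),
                    "bucket": bk,
                    "n": len(cell),
                    "fraction_above_threshold": float(
                        (cell["score"] > threshold).mean()
                    ),
                    "mean_score": float(cell["score"].mean()),
                }
            )
    return pd.DataFrame(rows)
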