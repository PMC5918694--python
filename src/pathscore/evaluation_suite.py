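"""Performance metrics and the benchmarking battery.

Covers AUROC/AUPR computation, per-cancer-type evaluation, within-type
versus pan-cancer model comparison, the shuffled-expression null control,
data-type and feature ablations, cross-gene (phenocopy) evaluation, and a
per-gene differential-expression comparison.

AUROC is the Mann-Whitney rank-concordance probability (ties count one
half); AUPR is the average-precision estimator (step-wise precision at each
positive's rank), whose random baseline equals the positive prevalence.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score, roc_curve
from sklearn.metrics import precision_recall_curve
from statsmodels.stats.multitest import multipletests

from .cohort_io import (
    CohortError,
    CopyNumberMatrix,
    CovariateTable,
    ExpressionMatrix,
    GeneTargetSpec,
    MutationTable,
)
from .pipeline import PipelineResult, score_cohort, train_pipeline
from .status_labels import StatusVector
from .train import TrainingConfig

logger = logging.getLogger(__name__)

ABLATIONS = (
    "mutation_only_y",
    "copy_only_y",
    "keep_target_genes_in_X",
    "drop_rasopathy_genes",
    "expression_only_X",
    "covariate_only_X",
)


def _align(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = pd.Series(scores)
    labels = pd.Series(labels)
    if not scores.index.equals(labels.index):
        if set(scores.index) <= set(labels.index):
            labels = labels.loc[scores.index]
        elif len(scores) == len(labels):
            labels = pd.Series(labels.to_numpy(), index=scores.index)
        else:
            raise CohortError("scores and labels cannot be aligned")
    return scores.to_numpy(dtype=float), labels.to_numpy(dtype=int)


def auroc(scores, labels) -> float:
    """Probability a random positive outranks a random negative (ties 1/2)."""
    s, y = _align(scores, labels)
    if len(np.unique(y)) < 2:
        raise CohortError("AUROC undefined: labels contain a single class")
    return float(roc_auc_score(y, s))


def aupr(scores, labels) -> float:
    """Average precision: precision at each positive's rank, averaged."""
    s, y = _align(scores, labels)
    if y.sum() == 0:
        raise CohortError("AUPR undefined: no positive labels")
    return float(average_precision_score(y, s))


def curves(scores, labels) -> dict[str, list[float]]:
    """ROC and PR curve points for report export."""
    s, y = _align(scores, labels)
    fpr, tpr, _ = roc_curve(y, s)
    precision, recall, _ = precision_recall_curve(y, s)
    return {
        "fpr": fpr.tolist(),
        "tpr": tpr.tolist(),
        "precision": precision.tolist(),
        "recall": recall.tolist(),
    }


def per_cancer_type_eval(
    scores, labels, covariates: CovariateTable
) -> pd.DataFrame:
    """AUROC/AUPR within each cancer type; single-class types are flagged
    not-evaluable instead of raising."""
    scores = pd.Series(scores)
    labels = pd.Series(labels).loc[scores.index]
    types = covariates.cancer_type.loc[scores.index]
    rows = []
    for ctype, members in types.groupby(types):
        idx = members.index
        y = labels.loc[idx]
        row = {
            "cancer_type": ctype,
            "n": int(len(idx)),
            "n_positive": int(y.sum()),
            "evaluable": bool(y.nunique() == 2),
        }
        if row["evaluable"]:
            row["auroc"] = auroc(scores.loc[idx], y)
            row["aupr"] = aupr(scores.loc[idx], y)
        else:
            row["auroc"] = np.nan
            row["aupr"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("cancer_type").sort_index()


def shuffle_expression(expr: ExpressionMatrix, seed: int) -> ExpressionMatrix:
    """Permute each gene's values across samples, destroying sample linkage
    while preserving every gene's marginal distribution."""
    rng = np.random.default_rng(seed)
    values = expr.values.copy()
    for j in range(values.shape[1]):
        rng.shuffle(values[:, j])
    return ExpressionMatrix(
        pd.DataFrame(values, index=expr.sample_ids, columns=expr.gene_ids)
    )


def shuffled_null(
    expression: ExpressionMatrix,
    mutations: MutationTable,
    copy_number: CopyNumberMatrix,
    covariates: CovariateTable,
    spec: GeneTargetSpec,
    config: TrainingConfig | None = None,
    shuffle_seed: int = 0,
    **pipeline_kwargs,
) -> PipelineResult:
    """Train the full pipeline on a within-gene-shuffled expression matrix.

    Labels and covariates stay intact, so the result measures how well the
    model can do without any real expression signal; expect test AUROC near
    0.5 and AUPR near the positive prevalence when covariates are
    uninformative.
    """
    shuffled = shuffle_expression(expression, shuffle_seed)
    return train_pipeline(
        shuffled, mutations, copy_number, covariates, spec, config, **pipeline_kwargs
    )


def ablation_battery(
    expression: ExpressionMatrix,
    mutations: MutationTable,
    copy_number: CopyNumberMatrix,
    covariates: CovariateTable,
    spec: GeneTargetSpec,
    config: TrainingConfig | None = None,
    which: tuple[str, ...] = ABLATIONS,
    **pipeline_kwargs,
) -> dict[str, PipelineResult]:
    """Rerun the pipeline once per ablation, each with a single change.

    All runs share the same partitioning seed, so ablations that leave the
    labels unchanged have bit-identical sample splits.  Ablations that cannot
    run (e.g. copy-only labels with zero positives) are skipped and recorded
    as ``None``.
    """
    from .features import RASOPATHY_PANEL

    unknown = set(which) - set(ABLATIONS)
    if unknown:
        raise CohortError(f"unknown ablations: {sorted(unknown)}")
    variants: dict[str, dict] = {
        "mutation_only_y": {"status_evidence": "mutation"},
        "copy_only_y": {"status_evidence": "copy"},
        "keep_target_genes_in_X": {"drop_targets": False},
        "drop_rasopathy_genes": {"extra_drop_genes": RASOPATHY_PANEL},
        "expression_only_X": {"include_covariates": False},
        "covariate_only_X": {"include_expression": False},
    }
    results: dict[str, PipelineResult] = {}
    for name in which:
        kwargs = {**pipeline_kwargs, **variants[name]}
        try:
            results[name] = train_pipeline(
                expression, mutations, copy_number, covariates, spec, config, **kwargs
            )
        except CohortError as exc:
            logger.warning("ablation %s skipped: %s", name, exc)
            results[name] = None
    return results


def align_gene_weights(
    results: dict[str, PipelineResult], genes: list[str] | None = None
) -> pd.DataFrame:
    """Gene-weight vectors across models with dropped genes re-inserted as
    zero weights, for cross-model coefficient comparison."""
    weight_maps = {
        name: res.model.gene_weights
        for name, res in results.items()
        if res is not None
    }
    if genes is None:
        genes = sorted({g for m in weight_maps.values() for g in m})
    return pd.DataFrame(
        {name: [m.get(g, 0.0) for g in genes] for name, m in weight_maps.items()},
        index=genes,
    )


def within_type_models(
    expression: ExpressionMatrix,
    mutations: MutationTable,
    copy_number: CopyNumberMatrix,
    covariates: CovariateTable,
    spec: GeneTargetSpec,
    config: TrainingConfig | None = None,
    pan_result: PipelineResult | None = None,
    **pipeline_kwargs,
) -> tuple[dict[str, PipelineResult], pd.DataFrame]:
    """Independently grid-searched models per cancer type, compared against
    the pan-cancer model's per-type cross-validation AUROC.

    Types failing the event-count/proportion filter on their own are skipped
    and recorded with NaN metrics.
    """
    if pan_result is None:
        pan_result = train_pipeline(
            expression, mutations, copy_number, covariates, spec, config,
            **pipeline_kwargs,
        )
    per_type: dict[str, PipelineResult] = {}
    rows = []
    pan_cv = pan_result.cv_scores
    pan_status = pan_result.status.status
    pan_types = covariates.cancer_type
    for ctype in pan_result.retained_types:
        samples = [s for s in pan_types.index if pan_types.loc[s] == ctype]
        try:
            res = train_pipeline(
                expression.subset_samples([s for s in samples if s in expression.data.index]),
                mutations.subset_samples(samples),
                copy_number.subset_samples([s for s in samples if s in copy_number.data.index]),
                covariates.subset_samples([s for s in samples if s in covariates.data.index]),
                spec,
                config,
                include_type_indicators=False,
                **pipeline_kwargs,
            )
        except CohortError as exc:
            logger.warning("within-type model for %s skipped: %s", ctype, exc)
            per_type[ctype] = None
            rows.append({"cancer_type": ctype, "within_cv_auroc": np.nan,
                         "pan_cv_auroc": np.nan, "skipped": True})
            continue
        per_type[ctype] = res
        pan_idx = [s for s in pan_cv.index if pan_types.loc[s] == ctype]
        pan_auroc = (
            auroc(pan_cv.loc[pan_idx], pan_status.loc[pan_idx])
            if pan_status.loc[pan_idx].nunique() == 2
            else np.nan
        )
        rows.append(
            {
                "cancer_type": ctype,
                "within_cv_auroc": res.metrics["cv"]["auroc"],
                "pan_cv_auroc": pan_auroc,
                "skipped": False,
            }
        )
    return per_type, pd.DataFrame(rows).set_index("cancer_type")


def cross_gene_eval(
    model,
    other_status: StatusVector,
    expression: ExpressionMatrix,
    covariates: CovariateTable | None = None,
    exclude_samples: tuple[str, ...] = (),
) -> dict:
    """Score an existing model against labels built from a different target
    spec (phenocopy evaluation, e.g. a Ras model scored on NF1-loss labels).

    ``exclude_samples`` optionally removes samples positive for the model's
    own targets so the evaluation isolates the alternate gene's events.
    """
    shared = [
        s
        for s in expression.sample_ids
        if s in set(other_status.sample_ids) and s not in set(exclude_samples)
    ]
    if not shared:
        raise CohortError("no overlapping samples between model input and labels")
    expr = expression.subset_samples(shared)
    scores = score_cohort(model, expr, covariates.subset_samples(shared) if covariates else None)
    labels = other_status.status.loc[shared]
    result = {
        "n": len(shared),
        "n_positive": int(labels.sum()),
        "auroc": auroc(scores, labels) if labels.nunique() == 2 else np.nan,
        "aupr": aupr(scores, labels) if labels.sum() > 0 else np.nan,
    }
    if covariates is not None:
        result["per_cancer_type"] = per_cancer_type_eval(
            scores, labels, covariates.subset_samples(shared)
        )
    return result


def differential_expression(
    expr: ExpressionMatrix,
    status,
    covariates: CovariateTable,
) -> pd.DataFrame:
    """Per-gene linear model of zero-one-normalized expression on status,
    adjusted for cancer type.

    Each gene is min-max rescaled to [0,1], then fit by ordinary least
    squares against status plus cancer-type indicators (one type is absorbed
    into the intercept).  Returns the status coefficient, its t statistic,
    two-sided p value and Benjamini-Hochberg q value per gene; genes constant
    across samples are flagged and carry NaN statistics.
    """
    labels = status.status if isinstance(status, StatusVector) else pd.Series(status)
    labels = labels.loc[expr.sample_ids]
    if labels.nunique() < 2:
        raise CohortError("differential expression requires both classes")
    X = expr.data
    rng_span = X.max(axis=0) - X.min(axis=0)
    constant = rng_span == 0.0
    Y = (X - X.min(axis=0)) / rng_span.replace(0.0, np.nan)

    types = covariates.cancer_type.loc[expr.sample_ids]
    type_levels = sorted(types.unique())
    design_cols = [np.ones(len(labels)), labels.to_numpy(dtype=float)]
    for level in type_levels[1:]:  # first level absorbed by the intercept
        design_cols.append((types == level).to_numpy(dtype=float))
    D = np.column_stack(design_cols)
    n, p = D.shape
    dof = n - np.linalg.matrix_rank(D)
    if dof <= 0:
        raise CohortError("not enough samples for the cancer-type-adjusted model")

    Ymat = Y.fillna(0.0).to_numpy()
    DtD_inv = np.linalg.pinv(D.T @ D)
    beta = DtD_inv @ D.T @ Ymat
    resid = Ymat - D @ beta
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(sigma2 * DtD_inv[1, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[1] / se
    pvals = 2.0 * stats.t.sf(np.abs(t), dof)

    result = pd.DataFrame(
        {
            "coef": beta[1],
            "t": t,
            "p": pvals,
            "constant": constant.to_numpy(),
        },
        index=X.columns,
    )
    result.loc[result["constant"], ["coef", "t", "p"]] = np.nan
    ok = result["p"].notna()
    q = pd.Series(np.nan, index=result.index)
    if ok.any():
        q.loc[ok] = multipletests(result.loc[ok, "p"], method="fdr_bh")[1]
    result["q"] = q
    return result.rename_axis("gene")
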