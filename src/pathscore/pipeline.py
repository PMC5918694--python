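"""End-to-end training pipeline: filtering, labeling, feature assembly,
grid-searched elastic-net fitting, and partition metrics.

Order of operations: hypermutator removal -> status construction ->
cancer-type filter -> MAD gene selection -> target-gene dropping ->
covariate encoding -> stratified train/test split -> standardization fitted
on the training partition -> cross-validated grid search -> final refit on
the full training partition -> one evaluation on the held-out test set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort_io import (
    ClassifierModel,
    CohortError,
    CopyNumberMatrix,
    CovariateTable,
    ExpressionMatrix,
    GeneTargetSpec,
    MutationTable,
)
from .features import (
    BURDEN_FEATURE,
    FeatureMatrix,
    assemble_features,
    drop_target_genes,
    select_mad_genes,
    standardize,
)
from .status_labels import (
    FilterReport,
    StatusVector,
    build_status,
    filter_cancer_types,
    filter_hypermutators,
)
from .train import (
    GridSearchResult,
    SplitAssignment,
    TrainingConfig,
    fit_sgd_elastic_net,
    grid_search_cv,
    predict_scores,
    stratified_split,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Everything one training run produced."""

    model: ClassifierModel
    split: SplitAssignment
    grid: GridSearchResult
    status: StatusVector
    features: FeatureMatrix
    metrics: dict[str, dict[str, float]]
    train_scores: pd.Series
    cv_scores: pd.Series
    test_scores: pd.Series
    hypermutator_report: FilterReport
    cancer_type_report: FilterReport
    selected_genes: list[str]
    retained_types: list[str]

    @property
    def best_alpha(self) -> float:
        return self.grid.best_alpha

    @property
    def best_l1_ratio(self) -> float:
        return self.grid.best_l1_ratio


def _partition_metrics(scores: pd.Series, labels: pd.Series) -> dict[str, float]:
    from .evaluation_suite import auroc, aupr

    labels = labels.loc[scores.index]
    out = {
        "n": int(len(labels)),
        "n_positive": int(labels.sum()),
    }
    if labels.nunique() == 2:
        out["auroc"] = auroc(scores, labels)
        out["aupr"] = aupr(scores, labels)
    else:
        out["auroc"] = float("nan")
        out["aupr"] = float("nan")
    return out


def train_pipeline(
    expression: ExpressionMatrix,
    mutations: MutationTable,
    copy_number: CopyNumberMatrix,
    covariates: CovariateTable,
    spec: GeneTargetSpec,
    config: TrainingConfig | None = None,
    n_mad_genes: int = 8000,
    extra_drop_genes: tuple[str, ...] = (),
    include_expression: bool = True,
    include_covariates: bool = True,
    include_type_indicators: bool = True,
    drop_targets: bool = True,
    status_evidence: str = "both",
    min_events: int = 15,
    min_proportion: float = 0.05,
    status_override: StatusVector | None = None,
) -> PipelineResult:
    """Run the full training procedure on one cohort.

    ``status_evidence`` restricts label evidence to ``"mutation"`` or
    ``"copy"`` for the data-type ablations (default ``"both"``).
    ``include_expression`` / ``include_covariates`` select the feature blocks
    for the expression-only and covariate-only ablations.
    """
    if config is None:
        config = TrainingConfig()
    if status_evidence not in {"both", "mutation", "copy"}:
        raise CohortError(f"unknown status_evidence {status_evidence!r}")

    # 1. hypermutator removal (burden distribution over the full cohort)
    hyper_report = filter_hypermutators(covariates)
    kept = hyper_report.retained_samples
    expression = expression.subset_samples(kept)
    copy_number = copy_number.subset_samples(kept)
    covariates = covariates.subset_samples(kept)
    mutations = mutations.subset_samples(kept)

    # 2. status construction
    if status_override is not None:
        status = status_override.subset_samples(kept)
    else:
        status = build_status(mutations, copy_number, spec)
    if status_evidence == "mutation":
        status = StatusVector(
            status=status.has_mutation_event.astype(int),
            has_mutation_event=status.has_mutation_event,
            has_copy_event=pd.Series(False, index=status.status.index),
        )
    elif status_evidence == "copy":
        status = StatusVector(
            status=status.has_copy_event.astype(int),
            has_mutation_event=pd.Series(False, index=status.status.index),
            has_copy_event=status.has_copy_event,
        )
    if status.n_positive == 0:
        raise CohortError("no positive samples under the requested label evidence")

    # 3. cancer-type filter
    type_report = filter_cancer_types(
        status, covariates, min_events=min_events, min_proportion=min_proportion
    )
    retained_types = type_report.retained_cancer_types
    if not retained_types:
        raise CohortError("no cancer type passed the event-count/proportion filter")
    kept = type_report.retained_samples
    expression = expression.subset_samples(kept)
    covariates = covariates.subset_samples(kept)
    status = status.subset_samples(kept)

    # 4. gene selection and target dropping
    if include_expression:
        k = min(n_mad_genes, len(expression.gene_ids))
        genes = select_mad_genes(expression, k)
        if drop_targets:
            genes = drop_target_genes(genes, spec, extra_drop=extra_drop_genes)
        elif extra_drop_genes:
            genes = [g for g in genes if g not in set(extra_drop_genes)]
    else:
        genes = []

    # 5. covariates + split + standardization
    features = assemble_features(
        expression,
        genes,
        covariates if include_covariates else None,
        retained_types=retained_types,
        include_type_indicators=include_type_indicators,
    )
    split = stratified_split(status, covariates, config)
    features = standardize(features, fit_on=split.train_ids)

    # 6. grid search, final refit, metrics
    grid = grid_search_cv(features, status, split, config, target_spec=spec)
    model = fit_sgd_elastic_net(
        features,
        status,
        grid.best_alpha,
        grid.best_l1_ratio,
        seed=config.seed,
        sample_ids=split.train_ids,
        max_epochs=config.max_epochs,
        tol=config.tol,
        learning_rate=config.learning_rate,
        target_spec=spec,
    )
    train_scores = predict_scores(model, features.subset_samples(split.train_ids))
    test_scores = predict_scores(model, features.subset_samples(split.test_ids))
    metrics = {
        "train": _partition_metrics(train_scores, status.status),
        "cv": _partition_metrics(grid.cv_scores, status.status),
        "test": _partition_metrics(test_scores, status.status),
    }
    return PipelineResult(
        model=model,
        split=split,
        grid=grid,
        status=status,
        features=features,
        metrics=metrics,
        train_scores=train_scores,
        cv_scores=grid.cv_scores,
        test_scores=test_scores,
        hypermutator_report=hyper_report,
        cancer_type_report=type_report,
        selected_genes=genes,
        retained_types=retained_types,
    )


def score_cohort(
    model: ClassifierModel,
    expression: ExpressionMatrix,
    covariates: CovariateTable | None = None,
) -> pd.Series:
    """Apply a trained model to cohort samples using its stored constants.

    Gene columns are standardized with the training-time means/SDs.  Samples
    from cancer types the model never saw get all-zero type indicators, which
    is how the excluded-cancer-type evaluation is run.  With
    ``covariates=None`` all covariate terms contribute zero.
    """
    gene_w = {g: w for g, w in model.gene_weights.items() if w != 0.0}
    missing = sorted(set(gene_w) - set(expression.gene_ids))
    if missing:
        raise CohortError(f"expression matrix lacks model genes: {missing[:10]}")
    genes = sorted(gene_w)
    X = expression.data[genes]
    mu = np.array([model.feature_means[g] for g in genes])
    sd = np.array([model.feature_sds[g] for g in genes])
    z = (X.to_numpy() - mu) / sd
    total = z @ np.array([gene_w[g] for g in genes]) + model.intercept

    if covariates is not None and model.covariate_weights:
        cov = covariates.subset_samples(expression.sample_ids)
        for name, w in model.covariate_weights.items():
            if w == 0.0:
                continue
            if name == BURDEN_FEATURE:
                x = np.log10(cov.mutation_count.to_numpy() + 1.0)
                if name in model.feature_means:
                    x = (x - model.feature_means[name]) / model.feature_sds[name]
            else:
                x = (cov.cancer_type == name).to_numpy(dtype=float)
            total = total + w * x
    return pd.Series(expit(total), index=expression.sample_ids, name="score")
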