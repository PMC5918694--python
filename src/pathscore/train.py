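"""Elastic-net penalized logistic regression trained by stochastic gradient
descent, with stratified partitioning and cross-validated grid search.

The model minimizes

    mean logistic loss + alpha * (l1_ratio * ||w||_1 + (1 - l1_ratio)/2 * ||w||_2^2)

over gene and covariate weights ``w`` with an unpenalized intercept.  The
default hyperparameter grids span l1_ratio in {0.15 .. 0.4} and alpha in
{0.1 .. 0.3}; at these strengths most gene weights are driven exactly to
zero, yielding a sparse, interpretable signature.  Partitions are stratified
jointly by cancer type and aberration status so that the held-out test set
and every cross-validation fold mirror the training composition.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.linear_model import SGDClassifier

from .cohort_io import ClassifierModel, CohortError, CovariateTable, GeneTargetSpec
from .features import BURDEN_FEATURE, FeatureMatrix
from .status_labels import StatusVector

logger = logging.getLogger(__name__)

DEFAULT_L1_RATIO_GRID = (0.15, 0.155, 0.16, 0.2, 0.25, 0.3, 0.4)
DEFAULT_ALPHA_GRID = (0.1, 0.13, 0.15, 0.18, 0.2, 0.25, 0.3)


@dataclass(frozen=True)
class TrainingConfig:
    """Partitioning, grid and SGD settings for one training run."""

    test_fraction: float = 0.10
    n_cv_folds: int = 5
    l1_ratio_grid: tuple[float, ...] = DEFAULT_L1_RATIO_GRID
    alpha_grid: tuple[float, ...] = DEFAULT_ALPHA_GRID
    seed: int = 0
    max_epochs: int = 30
    tol: float = 1e-3
    learning_rate: str = "optimal"

    def __post_init__(self):
        if not self.l1_ratio_grid or not self.alpha_grid:
            raise CohortError("hyperparameter grids must be non-empty")
        if not 0.0 < self.test_fraction <= 0.5:
            raise CohortError("test_fraction must lie in (0, 0.5]")
        if self.n_cv_folds < 2:
            raise CohortError("at least 2 cross-validation folds are required")


@dataclass
class SplitAssignment:
    """Train/test partition plus within-train fold indices (0-based)."""

    partition: pd.Series  # sample_id -> "train" | "test"
    fold: pd.Series  # sample_id -> fold index for train samples, -1 for test

    @property
    def train_ids(self) -> list[str]:
        return self.partition.index[self.partition == "train"].tolist()

    @property
    def test_ids(self) -> list[str]:
        return self.partition.index[self.partition == "test"].tolist()

    def fold_ids(self, k: int) -> list[str]:
        return self.fold.index[self.fold == k].tolist()

    @property
    def n_folds(self) -> int:
        return int(self.fold.max()) + 1


def stratified_split(
    status: StatusVector,
    covariates: CovariateTable,
    config: TrainingConfig,
) -> SplitAssignment:
    """Assign samples to train/test and CV folds, stratified by
    (cancer type x status).

    Deterministic given the config seed.  Strata of size 1 go to train; if the
    requested test fraction would empty a stratum from training, the test
    allocation is capped with a warning.
    """
    rng = np.random.default_rng(config.seed)
    samples = status.sample_ids
    strata = pd.DataFrame(
        {
            "cancer_type": covariates.cancer_type.loc[samples],
            "status": status.status.loc[samples],
        }
    )
    partition = pd.Series("train", index=strata.index, name="partition")
    fold = pd.Series(-1, index=strata.index, dtype=int, name="fold")

    for (_ctype, _st), members in strata.groupby(["cancer_type", "status"], sort=True):
        ids = sorted(members.index.tolist())
        rng.shuffle(ids)
        n = len(ids)
        if n == 1:
            logger.info("stratum of size 1 (%s, %s) assigned to train", _ctype, _st)
            n_test = 0
        else:
            n_test = int(round(config.test_fraction * n))
            if n_test >= n:
                warnings.warn(
                    f"test fraction would empty stratum ({_ctype}, {_st}); capped",
                    stacklevel=2,
                )
                n_test = n - 1
        test_ids = ids[:n_test]
        train_ids = ids[n_test:]
        partition.loc[test_ids] = "test"
        offset = int(rng.integers(config.n_cv_folds))
        for i, sid in enumerate(train_ids):
            fold.loc[sid] = (i + offset) % config.n_cv_folds
    return SplitAssignment(partition=partition, fold=fold)


def _as_status_series(status) -> pd.Series:
    if isinstance(status, StatusVector):
        return status.status
    return pd.Series(status)


def elastic_net_objective(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray,
    intercept: float,
    alpha: float,
    l1_ratio: float,
) -> float:
    """Mean logistic loss plus the elastic-net penalty (intercept unpenalized)."""
    z = X @ weights + intercept
    # log(1 + exp(-margin)) computed stably via logaddexp
    margin = np.where(y > 0, z, -z)
    loss = np.logaddexp(0.0, -margin).mean()
    penalty = alpha * (
        l1_ratio * np.abs(weights).sum()
        + 0.5 * (1.0 - l1_ratio) * (weights**2).sum()
    )
    return float(loss + penalty)


def fit_sgd_elastic_net(
    features: FeatureMatrix,
    status,
    alpha: float,
    l1_ratio: float,
    seed: int,
    sample_ids=None,
    max_epochs: int = 100,
    tol: float = 1e-3,
    learning_rate: str = "optimal",
    target_spec: GeneTargetSpec | None = None,
) -> ClassifierModel:
    """Fit one elastic-net logistic model by SGD on (a subset of) the samples.

    Expects standardized features.  Covariate columns are penalized along
    with the gene columns; only the intercept is unpenalized.
    """
    y_all = _as_status_series(status)
    data = features.data if sample_ids is None else features.data.loc[list(sample_ids)]
    y = y_all.loc[data.index].to_numpy()
    if len(np.unique(y)) < 2:
        raise CohortError("training subset contains a single class")
    X = data.to_numpy()
    clf = SGDClassifier(
        loss="log_loss",
        penalty="elasticnet",
        alpha=alpha,
        l1_ratio=l1_ratio,
        max_iter=max_epochs,
        tol=tol,
        learning_rate=learning_rate,
        random_state=seed,
        fit_intercept=True,
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*Maximum number of iteration.*")
        clf.fit(X, y)
    coef = clf.coef_.ravel()
    intercept = float(clf.intercept_[0])
    if not (np.all(np.isfinite(coef)) and np.isfinite(intercept)):
        raise CohortError(
            "non-finite weights after SGD optimization "
            f"(alpha={alpha}, l1_ratio={l1_ratio}); check feature scaling"
        )
    names = features.feature_names
    n_genes = len(features.gene_features)
    return ClassifierModel(
        gene_weights={g: float(w) for g, w in zip(names[:n_genes], coef[:n_genes])},
        covariate_weights={
            c: float(w) for c, w in zip(names[n_genes:], coef[n_genes:])
        },
        intercept=intercept,
        alpha=float(alpha),
        l1_ratio=float(l1_ratio),
        feature_means=dict(features.means),
        feature_sds=dict(features.sds),
        target_spec=target_spec,
        metadata={"seed": str(seed)},
    )


def predict_scores(model: ClassifierModel, features: FeatureMatrix) -> pd.Series:
    """Sigmoid of the weighted feature sum; expects standardized features.

    Every model feature with a nonzero weight must be present; missing genes
    raise an error naming them.
    """
    weights = {**model.gene_weights, **model.covariate_weights}
    cols = set(features.data.columns)
    missing = sorted(f for f, w in weights.items() if w != 0.0 and f not in cols)
    if missing:
        raise CohortError(f"features missing model genes/covariates: {missing[:10]}")
    used = [f for f in features.data.columns if f in weights]
    w = np.array([weights[f] for f in used])
    z = features.data[used].to_numpy() @ w + model.intercept
    return pd.Series(expit(z), index=features.data.index, name="score")


@dataclass
class GridSearchResult:
    best_alpha: float
    best_l1_ratio: float
    table: pd.DataFrame  # columns: alpha, l1_ratio, mean_cv_auroc, n_folds
    cv_scores: pd.Series  # out-of-fold scores at the best cell


def grid_search_cv(
    features: FeatureMatrix,
    status,
    split: SplitAssignment,
    config: TrainingConfig,
    target_spec: GeneTargetSpec | None = None,
) -> GridSearchResult:
    """Mean cross-validation AUROC for every grid cell; best cell maximizes it.

    Each fold's predictions come from a model trained on the other folds, so
    no sample is scored by a model that saw it.  Folds whose evaluation part
    contains a single class are skipped with a warning.  Ties are broken by
    smaller alpha, then smaller l1_ratio.
    """
    from .evaluation_suite import auroc  # local import to avoid a cycle

    y = _as_status_series(status)
    folds = [split.fold_ids(k) for k in range(config.n_cv_folds)]
    train_ids = split.train_ids

    def fold_aurocs(alpha: float, l1_ratio: float, collect: dict | None = None):
        values = []
        for k, eval_ids in enumerate(folds):
            if not eval_ids:
                continue
            y_eval = y.loc[eval_ids]
            if y_eval.nunique() < 2:
                warnings.warn(
                    f"fold {k} has a single class; AUROC undefined, fold skipped",
                    stacklevel=3,
                )
                continue
            fit_ids = [s for s in train_ids if s not in set(eval_ids)]
            model = fit_sgd_elastic_net(
                features,
                y,
                alpha,
                l1_ratio,
                seed=config.seed + k,
                sample_ids=fit_ids,
                max_epochs=config.max_epochs,
                tol=config.tol,
                learning_rate=config.learning_rate,
            )
            scores = predict_scores(model, features.subset_samples(eval_ids))
            values.append(auroc(scores, y_eval))
            if collect is not None:
                collect.update(scores.to_dict())
        return values

    rows = []
    for alpha in sorted(config.alpha_grid):
        for l1_ratio in sorted(config.l1_ratio_grid):
            values = fold_aurocs(alpha, l1_ratio)
            rows.append(
                {
                    "alpha": alpha,
                    "l1_ratio": l1_ratio,
                    "mean_cv_auroc": float(np.mean(values)) if values else np.nan,
                    "n_folds": len(values),
                }
            )
    table = pd.DataFrame(rows)
    if table["mean_cv_auroc"].isna().all():
        raise CohortError("no grid cell produced an evaluable cross-validation fold")
    best = table.sort_values(
        ["mean_cv_auroc", "alpha", "l1_ratio"], ascending=[False, True, True]
    ).iloc[0]

    collected: dict[str, float] = {}
    fold_aurocs(best["alpha"], best["l1_ratio"], collect=collected)
    cv_scores = pd.Series(collected, name="cv_score")
    return GridSearchResult(
        best_alpha=float(best["alpha"]),
        best_l1_ratio=float(best["l1_ratio"]),
        table=table,
        cv_scores=cv_scores,
    )
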