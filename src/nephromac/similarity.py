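"""Cross-dataset cell-type similarity by L2-regularized logistic regression.

A binary classifier is trained on a reference dataset (e.g. two macrophage
fates) and applied to query cells; the predicted probability of the
positive class is the similarity score. Regularization strength is chosen
by k-fold cross-validation with the 1-SE rule (the largest penalty whose
mean CV binomial deviance is within one standard error of the minimum),
the whole procedure is repeated over independently shuffled fold
partitions, and the final score is the average over iterations.

Expression values are standardized per gene to mean 0 / sd 1 — in the
training set with training statistics and in the query with the query's
own statistics, so the score compares relative expression profiles across
datasets with different depth and scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .core_io import ExpressionMatrix, ValidationError


@dataclass
class SimilarityConfig:
    alpha: float = 0.0  # elastic-net mixing; 0 = pure ridge (the only mode)
    n_folds: int = 10
    lambda_rule: str = "1se"  # or "min"
    n_iterations: int = 50
    gene_filter: list[str] | None = None
    n_lambda: int = 50
    lambda_min_ratio: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha != 0.0:
            raise ValidationError("only pure L2 (alpha=0) is supported")
        if self.n_folds < 2:
            raise ValidationError("n_folds must be >= 2")
        if self.n_iterations < 1:
            raise ValidationError("n_iterations must be >= 1")
        if self.lambda_rule not in ("1se", "min"):
            raise ValidationError("lambda_rule must be '1se' or 'min'")


@dataclass
class IterationFit:
    coef: np.ndarray
    intercept: float
    selected_lambda: float


@dataclass
class SimilarityEnsemble:
    gene_ids: list[str]
    train_mean: np.ndarray
    train_sd: np.ndarray
    positive_class: str
    prevalence: float
    lambda_path: np.ndarray
    iterations: list[IterationFit] = field(default_factory=list)


def _binomial_deviance(y: np.ndarray, p: np.ndarray) -> float:
    """Mean binomial deviance, -2/n * log-likelihood, probabilities clipped."""
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _fit_ridge_path(
    X: np.ndarray, y: np.ndarray, lambdas: np.ndarray
) -> list[tuple[np.ndarray, float]]:
    """Fit the ridge-logistic path from largest to smallest penalty.

    The objective per observation is mean log-loss + (lam/2)||w||^2, i.e.
    sklearn's C equals 1 / (n * lam). Warm starts carry coefficients down
    the path.
    """
    n = len(y)
    # default penalty is L2; C is reset per path point below
    model = LogisticRegression(
        solver="lbfgs", warm_start=True, max_iter=1000, tol=1e-6
    )
    fits = []
    for lam in lambdas:  # descending
        model.C = 1.0 / (n * lam)
        model.fit(X, y)
        fits.append((model.coef_[0].copy(), float(model.intercept_[0])))
    return fits


def make_lambda_path(
    X: np.ndarray, y: np.ndarray, n_lambda: int, min_ratio: float
) -> np.ndarray:
    """Descending log-spaced penalty path.

    The top of the path is the strength at which the gradient of the
    unpenalized loss at the null model is dominated by the penalty
    (max_j |x_j'(y - ybar)| / n, inflated so coefficients are numerically
    negligible there — ridge shrinks smoothly and never hits exact zero).
    """
    resid = y - y.mean()
    lam_max = np.abs(X.T @ resid).max() / len(y) / 1e-3
    lam_max = max(lam_max, 1e-6)
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambda)


def select_lambda_1se(
    lambdas: np.ndarray, mean_dev: np.ndarray, se_dev: np.ndarray, rule: str
) -> tuple[float, int]:
    """Largest penalty whose mean CV deviance is within 1 SE of the minimum.

    ``lambdas`` must be descending; ties in the deviance resolve toward the
    stronger penalty (the parsimonious end), so a flat CV curve returns the
    top of the path.
    """
    i_min = int(np.argmin(mean_dev))
    if rule == "min":
        return float(lambdas[i_min]), i_min
    cutoff = mean_dev[i_min] + se_dev[i_min]
    eligible = np.flatnonzero(mean_dev <= cutoff)
    i_sel = int(eligible[0])  # descending path: first eligible = largest lambda
    return float(lambdas[i_sel]), i_sel


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mean) / sd_safe, mean, sd


def fit_similarity(
    reference: ExpressionMatrix,
    labels: np.ndarray,
    config: SimilarityConfig | None = None,
) -> SimilarityEnsemble:
    """Train the cross-validated ridge-logistic ensemble on a reference.

    ``labels`` holds exactly two classes; the lexicographically larger one
    is the positive class. Each iteration reshuffles the stratified fold
    partition (seeded from ``config.seed + iteration``), selects its own
    penalty by the 1-SE rule, and refits on the full training set at that
    penalty.
    """
    config = config or SimilarityConfig()
    labels = np.asarray(labels).astype(str)
    if len(labels) != reference.n_cells:
        raise ValidationError("one label per reference cell required")
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise ValidationError(f"need exactly 2 classes, got {classes}")
    y = (labels == classes[1]).astype(float)
    counts = [int((y == 0).sum()), int((y == 1).sum())]
    if min(counts) < config.n_folds:
        raise ValidationError(
            f"smallest class has {min(counts)} cells < {config.n_folds} folds; "
            "stratified CV would leave a class out of some fold — reduce "
            "n_folds or provide more cells"
        )

    genes = list(reference.gene_ids)
    if config.gene_filter is not None:
        allowed = set(config.gene_filter)
        genes = [g for g in genes if g in allowed]
    gidx = reference.gene_index()
    X_full = reference.dense().T  # cells x genes
    X = X_full[:, [gidx[g] for g in genes]]
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    genes = [g for g, k in zip(genes, keep) if k]
    if len(genes) < 2:
        raise ValidationError("fewer than 2 informative genes after filtering")
    X = X[:, keep]
    Xs, mean, sd = _standardize(X)

    lambdas = make_lambda_path(Xs, y, config.n_lambda, config.lambda_min_ratio)
    ensemble = SimilarityEnsemble(
        gene_ids=genes,
        train_mean=mean,
        train_sd=sd,
        positive_class=classes[1],
        prevalence=float(y.mean()),
        lambda_path=lambdas,
    )
    for it in range(config.n_iterations):
        rng_seed = (config.seed + it) % (2**31 - 1)
        skf = StratifiedKFold(
            n_splits=config.n_folds, shuffle=True, random_state=rng_seed
        )
        fold_dev = np.empty((config.n_folds, len(lambdas)))
        for f, (tr, te) in enumerate(skf.split(Xs, y)):
            fits = _fit_ridge_path(Xs[tr], y[tr], lambdas)
            for j, (coef, icpt) in enumerate(fits):
                logit = Xs[te] @ coef + icpt
                p = 1.0 / (1.0 + np.exp(-logit))
                fold_dev[f, j] = _binomial_deviance(y[te], p)
        mean_dev = fold_dev.mean(axis=0)
        se_dev = fold_dev.std(axis=0, ddof=1) / np.sqrt(config.n_folds)
        lam, _ = select_lambda_1se(lambdas, mean_dev, se_dev, config.lambda_rule)
        coef, icpt = _fit_ridge_path(Xs, y, np.array([lam]))[0]
        ensemble.iterations.append(IterationFit(coef, icpt, lam))
    return ensemble


def score_query(
    ensemble: SimilarityEnsemble,
    query: ExpressionMatrix,
    *,
    standardize_with: str = "query",
) -> np.ndarray:
    """Per-query-cell similarity in [0, 1] to the positive reference class.

    The query is standardized per gene with its own statistics by default
    (``standardize_with="train"`` reuses the training mean/sd instead).
    Ensemble genes absent from the query contribute 0 after
    standardization. The score is the mean predicted positive-class
    probability over iterations.
    """
    gidx = query.gene_index()
    present = [g for g in ensemble.gene_ids if g in gidx]
    if not present:
        raise ValidationError("no overlap between ensemble genes and query genes")
    Xq_full = query.dense().T
    n_cells = query.n_cells
    Z = np.zeros((n_cells, len(ensemble.gene_ids)))
    for j, g in enumerate(ensemble.gene_ids):
        if g not in gidx:
            continue
        col = Xq_full[:, gidx[g]]
        if standardize_with == "query":
            sd = col.std(ddof=0)
            Z[:, j] = (col - col.mean()) / sd if sd > 0 else 0.0
        elif standardize_with == "train":
            sd = ensemble.train_sd[j]
            Z[:, j] = (col - ensemble.train_mean[j]) / sd if sd > 0 else 0.0
        else:
            raise ValidationError("standardize_with must be 'query' or 'train'")
    probs = np.zeros(n_cells)
    for fit in ensemble.iterations:
        logit = Z @ fit.coef + fit.intercept
        probs += 1.0 / (1.0 + np.exp(-logit))
    return probs / len(ensemble.iterations)
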