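"""Kernel ridge regression with one shared kernel and many distance targets.

Training all T targets needs a single symmetric factorization: with kernel
matrix K over the training features, alpha = (K + lambda I)^-1 Y is solved
once for the whole N x T label matrix, one coefficient column per target.
Hyperparameters (kernel family, sigma, lambda) are shared across targets
and picked by grid search with nested fivefold cross-validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial.distance import cdist

__all__ = [
    "KernelModel",
    "HyperparameterGrid",
    "default_grid",
    "kernel_matrix",
    "fit",
    "predict",
    "kfold_indices",
    "grid_search_cv",
    "nested_cv_search",
    "learning_curve",
]

logger = logging.getLogger(__name__)

KERNEL_FAMILIES = ("laplacian", "gaussian")


def kernel_matrix(
    x_a: np.ndarray, x_b: np.ndarray, family: str, sigma: float
) -> np.ndarray:
    """Pairwise kernel values.

    laplacian: exp(-||xi - xj||_1 / sigma)
    gaussian:  exp(-||xi - xj||_2^2 / (2 sigma^2))
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    x_a = np.atleast_2d(np.asarray(x_a, dtype=np.float64))
    x_b = np.atleast_2d(np.asarray(x_b, dtype=np.float64))
    if not (np.isfinite(x_a).all() and np.isfinite(x_b).all()):
        raise ValueError("features must be finite")
    if x_a.shape[1] != x_b.shape[1]:
        raise ValueError("feature dimensions do not match")
    if family == "laplacian":
        return np.exp(-cdist(x_a, x_b, metric="cityblock") / sigma)
    if family == "gaussian":
        return np.exp(-cdist(x_a, x_b, metric="sqeuclidean") / (2.0 * sigma**2))
    raise ValueError(f"unknown kernel family {family!r}")


@dataclass
class KernelModel:
    """A fitted multi-target KRR model (shared kernel, per-target column)."""

    kernel_family: str
    sigma: float
    lam: float
    training_features: np.ndarray
    coefficients: np.ndarray  # N x T
    target_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.coefficients.shape[0] != self.training_features.shape[0]:
            raise ValueError("coefficient rows must match training molecules")
        if self.target_names and len(self.target_names) != self.n_targets:
            raise ValueError("one target name per coefficient column required")

    @property
    def n_train(self) -> int:
        return self.training_features.shape[0]

    @property
    def n_targets(self) -> int:
        return self.coefficients.shape[1]


def _solve_spd(k: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """(K + lam I)^-1 Y via Cholesky, escalating jitter on failure."""
    n = k.shape[0]
    for jitter in (0.0, 1e-10, 1e-8, 1e-6):
        try:
            c = cho_factor(k + (lam + jitter) * np.eye(n), lower=True)
            if jitter:
                logger.debug("kernel factorization needed jitter %g", jitter)
            return cho_solve(c, y)
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError(
        "kernel matrix not positive definite even with 1e-6 jitter"
    )


def fit(
    x: np.ndarray,
    y: np.ndarray,
    family: str,
    sigma: float,
    lam: float,
    target_names: list[str] | None = None,
) -> KernelModel:
    """Fit all targets with one factorization: alpha = (K + lam I)^-1 Y."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if y.ndim == 1:
        y = y[:, None]
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    k = kernel_matrix(x, x, family, sigma)
    alpha = _solve_spd(k, y, lam)
    return KernelModel(
        kernel_family=family,
        sigma=float(sigma),
        lam=float(lam),
        training_features=x,
        coefficients=alpha,
        target_names=list(target_names or []),
    )


def predict(model: KernelModel, x_query: np.ndarray) -> np.ndarray:
    """Predicted targets, shaped (n_queries, T)."""
    x_query = np.atleast_2d(np.asarray(x_query, dtype=np.float64))
    if x_query.shape[1] != model.training_features.shape[1]:
        raise ValueError(
            f"query dimension {x_query.shape[1]} does not match "
            f"training dimension {model.training_features.shape[1]}"
        )
    k = kernel_matrix(x_query, model.training_features, model.kernel_family, model.sigma)
    return k @ model.coefficients


# ---------------------------------------------------------------------------
# Hyperparameter search
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HyperparameterGrid:
    sigma_values: tuple[float, ...]
    lambda_values: tuple[float, ...]
    kernel_families: tuple[str, ...] = KERNEL_FAMILIES

    def __post_init__(self) -> None:
        if not (self.sigma_values and self.lambda_values and self.kernel_families):
            raise ValueError("grid lists must be nonempty")

    def points(self):
        for fam in self.kernel_families:
            for s in self.sigma_values:
                for l in self.lambda_values:
                    yield fam, float(s), float(l)


def default_grid(
    x: np.ndarray,
    n_sigma: int = 13,
    families: tuple[str, ...] = KERNEL_FAMILIES,
    max_pairs: int = 2000,
) -> HyperparameterGrid:
    """Scale-free default grid anchored on the median feature distance.

    Sigma spans [0.05, 20] x the median nonzero pairwise distance of the
    (sub-sampled) training features, log-spaced; lambda covers the decades
    1e-10 .. 1e-3.
    """
    x = np.asarray(x, dtype=np.float64)
    n = x.shape[0]
    if n * (n - 1) // 2 > max_pairs:
        # deterministic thinning keeps the grid reproducible
        step = max(1, n // int(np.sqrt(2 * max_pairs) + 1))
        x = x[::step]
    metric = "cityblock" if "laplacian" in families else "sqeuclidean"
    d = cdist(x, x, metric="cityblock" if metric == "cityblock" else "euclidean")
    vals = d[np.triu_indices_from(d, k=1)]
    nz = vals[vals > 0]
    med = float(np.median(nz)) if nz.size else 1.0
    sigmas = tuple(np.geomspace(0.05 * med, 20.0 * med, n_sigma))
    lambdas = tuple(10.0 ** np.arange(-10.0, -2.0))
    return HyperparameterGrid(sigmas, lambdas, families)


def kfold_indices(n: int, k: int, rng: np.random.Generator):
    """Seeded shuffled k-fold split; yields (train_idx, test_idx)."""
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)
    for i in range(k):
        test = folds[i]
        train = np.concatenate([folds[j] for j in range(k) if j != i])
        yield train, test


def grid_search_cv(
    x: np.ndarray,
    y: np.ndarray,
    grid: HyperparameterGrid,
    k: int,
    rng: np.random.Generator,
):
    """Plain k-fold grid search; returns (best point, score DataFrame).

    The score is the mean absolute error over all targets and folds; the
    winning point minimizes it (ties go to the first grid point).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if y.ndim == 1:
        y = y[:, None]
    splits = list(kfold_indices(x.shape[0], k, rng))
    rows = []
    best = None
    for fam, sigma, lam in grid.points():
        maes = []
        for train, test in splits:
            try:
                m = fit(x[train], y[train], fam, sigma, lam)
                pred = predict(m, x[test])
                maes.append(float(np.mean(np.abs(pred - y[test]))))
            except np.linalg.LinAlgError:
                maes.append(np.nan)
        score = float(np.nanmean(maes)) if not all(np.isnan(maes)) else np.nan
        rows.append(
            {"family": fam, "sigma": sigma, "lambda": lam, "cv_mae": score}
        )
        if not np.isnan(score) and (best is None or score < best[0]):
            best = (score, (fam, sigma, lam))
    if best is None:
        raise RuntimeError("hyperparameter grid exhausted with all-NaN scores")
    return best[1], pd.DataFrame(rows)


def nested_cv_search(
    x: np.ndarray,
    y: np.ndarray,
    grid: HyperparameterGrid,
    k_outer: int = 5,
    k_inner: int = 5,
    seed: int = 0,
):
    """Nested fivefold cross-validation for hyperparameters and an unbiased MAE.

    Inner folds pick the (family, sigma, lambda) minimizing the mean MAE
    over all targets; each outer fold scores that pick on unseen data.  The
    returned hyperparameters come from an inner-style search on the full
    data and are meant for a final refit.

    Returns
    -------
    best : (family, sigma, lambda)
    outer_table : DataFrame with one row per outer fold (selected point,
        outer MAE) plus the full-data selection.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if y.ndim == 1:
        y = y[:, None]
    n = x.shape[0]
    if n < 25:
        raise ValueError("nested fivefold CV needs at least 25 samples")
    rng = np.random.default_rng(seed)
    rows = []
    for fold, (train, test) in enumerate(kfold_indices(n, k_outer, rng)):
        inner_rng = np.random.default_rng(seed + 1000 + fold)
        (fam, sigma, lam), _ = grid_search_cv(
            x[train], y[train], grid, k_inner, inner_rng
        )
        m = fit(x[train], y[train], fam, sigma, lam)
        mae = float(np.mean(np.abs(predict(m, x[test]) - y[test])))
        rows.append(
            {
                "fold": fold,
                "family": fam,
                "sigma": sigma,
                "lambda": lam,
                "outer_mae": mae,
            }
        )
    final_rng = np.random.default_rng(seed + 2000)
    best, _ = grid_search_cv(x, y, grid, k_inner, final_rng)
    table = pd.DataFrame(rows)
    logger.info(
        "nested CV: outer MAE %.4g +- %.2g; selected %s",
        table["outer_mae"].mean(),
        table["outer_mae"].std(ddof=0),
        best,
    )
    return best, table


def learning_curve(
    x: np.ndarray,
    y: np.ndarray,
    train_sizes,
    n_repeats: int,
    seed: int,
    test_fraction: float = 0.2,
    family: str = "laplacian",
    sigma: float | None = None,
    lam: float = 1e-8,
    grid: HyperparameterGrid | None = None,
) -> pd.DataFrame:
    """Held-out MAE versus training-set size.

    A fixed seeded test set is split off first; for each size the model is
    trained on ``n_repeats`` random subsets of the remaining pool.  When a
    grid is supplied, hyperparameters are re-selected per subset by 5-fold
    grid search; otherwise the supplied (family, sigma, lam) are used, with
    sigma defaulting to the median-distance heuristic.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if y.ndim == 1:
        y = y[:, None]
    n = x.shape[0]
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = max(1, int(round(test_fraction * n)))
    test, pool = perm[:n_test], perm[n_test:]
    if max(train_sizes) > len(pool):
        raise ValueError(
            f"largest training size {max(train_sizes)} exceeds pool {len(pool)}"
        )
    if sigma is None and grid is None:
        d = cdist(x[pool], x[pool], metric="cityblock")
        nz = d[np.triu_indices_from(d, k=1)]
        nz = nz[nz > 0]
        sigma = float(np.median(nz)) if nz.size else 1.0
    rows = []
    for size in train_sizes:
        maes = []
        for rep in range(n_repeats):
            sub = rng.choice(pool, size=size, replace=False)
            if grid is not None:
                sub_rng = np.random.default_rng(seed + 7919 * rep + size)
                (fam_r, sig_r, lam_r), _ = grid_search_cv(
                    x[sub], y[sub], grid, 5, sub_rng
                )
            else:
                fam_r, sig_r, lam_r = family, sigma, lam
            m = fit(x[sub], y[sub], fam_r, sig_r, lam_r)
            maes.append(float(np.mean(np.abs(predict(m, x[test]) - y[test]))))
        maes = np.array(maes)
        rows.append(
            {
                "n_train": int(size),
                "mae_mean": float(maes.mean()),
                "mae_std": float(maes.std(ddof=1)) if len(maes) > 1 else 0.0,
                "n_repeats": int(n_repeats),
            }
        )
    return pd.DataFrame(rows)
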