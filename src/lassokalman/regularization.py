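"""Data-driven sparsity parameter and initial condition.

The l1 weight lambda of the projection step is chosen by generalized
cross-validation on each gene's pooled static regression: fit the actual
LASSO at each candidate lambda, take the number of nonzero coefficients
as the effective parameter count d(lambda), and minimize

    GCV(lambda) = (RSS / N) / (1 - d(lambda) / N)^2

over a coarse logarithmic grid followed by a fine search around the
coarse minimizer.  The same pooled regression, solved as an l1-penalized
least-squares problem, provides the static-network initial condition
that seeds the tracker.

Conventions: the static regression objective is normalized per sample,

    (1/N) ||y - X a||_2^2 + lambda ||a||_1,

so that lambda lives on the same scale as in the projection objective
``||a_tilde - a||_2^2 + lambda ||a||_1`` used by the tracker: for an
(approximately) orthonormal-per-sample design (X^T X = N I, e.g.
standard-normal snapshots) both shrink each coefficient by the soft
threshold lambda/2.  The smallest lambda with an all-zero solution is
``(2/N) ||X^T y||_inf``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import Lasso

from .model import EpochObservations, pooled_gene_problem

logger = logging.getLogger(__name__)

__all__ = [
    "GcvResult",
    "StaticFit",
    "lambda_max",
    "lasso_fit",
    "gcv_statistic",
    "select_lambda",
    "default_coarse_grid",
    "initial_condition",
    "static_fit",
]


@dataclass
class GcvResult:
    """Outcome of the two-stage (coarse then fine) GCV search."""

    lambda_grid_coarse: np.ndarray
    gcv_coarse: np.ndarray
    lambda_grid_fine: np.ndarray
    gcv_fine: np.ndarray
    lambda_star: float

    @property
    def gcv_star(self) -> float:
        """GCV value at the selected lambda (a prediction-MSE estimate)."""
        return float(np.min(self.gcv_fine[np.isfinite(self.gcv_fine)]))


@dataclass
class StaticFit:
    """Per-gene static estimate with its selected sparsity weights.

    ``p0_scales[i]`` estimates the error variance of gene i's initial
    coefficients: prediction MSE (the GCV minimum) divided by the pooled
    sample count, the standard-normal-design approximation of the
    least-squares coefficient variance.  It is only computed when the
    pooled problem is overdetermined (N >= p); otherwise it is NaN and
    callers fall back to their diffuse default.
    """

    lambdas: np.ndarray
    A0: np.ndarray
    p0_scales: np.ndarray

    def __iter__(self):
        # unpacks like the (lambdas, A0) pair most callers want
        return iter((self.lambdas, self.A0))


def lambda_max(design: np.ndarray, response: np.ndarray) -> float:
    """Smallest lambda for which the LASSO solution is identically zero."""
    X = np.atleast_2d(np.asarray(design, dtype=float))
    return 2.0 * float(np.max(np.abs(X.T @ response))) / X.shape[0]


def lasso_fit(design: np.ndarray, response: np.ndarray, lambda_: float) -> np.ndarray:
    """Coefficients minimizing ``(1/N) ||y - X a||_2^2 + lambda ||a||_1``
    (no intercept).  Backed by coordinate descent; lambda maps to the
    coordinate-descent penalty ``alpha = lambda / 2``."""
    X = np.atleast_2d(np.asarray(design, dtype=float))
    y = np.asarray(response, dtype=float)
    if lambda_ < 0:
        raise ValueError("lambda_ must be nonnegative")
    if lambda_ == 0:
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        return coef
    if lambda_ >= lambda_max(X, y):
        return np.zeros(X.shape[1])
    model = Lasso(
        alpha=lambda_ / 2.0,
        fit_intercept=False,
        max_iter=5000,
        tol=1e-8,
    )
    model.fit(X, y)
    return model.coef_.copy()


def gcv_statistic(
    design: np.ndarray, response: np.ndarray, lambda_: float
) -> float:
    """Generalized cross-validation score of the LASSO fit at ``lambda_``.

    Returns +inf when the effective parameter count d(lambda) reaches the
    sample count N (saturated fit), so that saturated models can never be
    selected.
    """
    X = np.atleast_2d(np.asarray(design, dtype=float))
    y = np.asarray(response, dtype=float)
    N = X.shape[0]
    if N < 1:
        raise ValueError("need at least one sample")
    coef = lasso_fit(X, y, lambda_)
    return _gcv_from_coef(X, y, coef)


def _gcv_from_coef(X: np.ndarray, y: np.ndarray, coef: np.ndarray) -> float:
    N = X.shape[0]
    d = int(np.count_nonzero(coef))
    if d >= N:
        logger.debug("saturated LASSO fit (d=%d >= N=%d); GCV set to inf", d, N)
        return float("inf")
    rss = float(np.sum((y - X @ coef) ** 2))
    return (rss / N) / (1.0 - d / N) ** 2


def default_coarse_grid(
    design: np.ndarray, response: np.ndarray, n_points: int = 20
) -> np.ndarray:
    """Log-spaced grid on [1e-4 * lambda_max, lambda_max]."""
    lmax = lambda_max(design, response)
    if lmax <= 0:
        # degenerate data (e.g. zero response): any lambda gives the zero
        # solution; return a token grid
        return np.array([0.0, 1.0])
    return np.geomspace(1e-4 * lmax, lmax, n_points)


def _gcv_on_grid(
    X: np.ndarray,
    y: np.ndarray,
    grid: np.ndarray,
    gram: np.ndarray | None = None,
) -> np.ndarray:
    """GCV along a lambda grid, sharing one warm-started coordinate-descent
    model across the grid (descending lambda) for speed.  ``gram`` may
    supply a precomputed X^T X (reused across genes, which share the
    design)."""
    lmax = lambda_max(X, y)
    out = np.empty(len(grid))
    order = np.argsort(grid)[::-1]  # warm start from sparsest fit
    model = Lasso(
        alpha=1.0,
        fit_intercept=False,
        max_iter=5000,
        tol=1e-8,
        warm_start=True,
        precompute=gram if gram is not None else False,
    )
    for idx in order:
        lam = grid[idx]
        if lam >= lmax:
            coef = np.zeros(X.shape[1])
        elif lam == 0:
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        else:
            model.set_params(alpha=lam / 2.0)
            model.fit(X, y)
            coef = model.coef_
        out[idx] = _gcv_from_coef(X, y, coef)
    return out


def _argmin_prefer_larger(grid: np.ndarray, values: np.ndarray) -> int:
    """Index of the minimum; ties broken toward larger lambda (sparser)."""
    finite = np.where(np.isfinite(values))[0]
    if finite.size == 0:
        raise ValueError(
            "GCV is infinite on the whole grid; the data cannot support "
            "sparsity-parameter selection"
        )
    best = np.min(values[finite])
    candidates = finite[np.isclose(values[finite], best, rtol=1e-12, atol=0.0)]
    return int(candidates[np.argmax(grid[candidates])])


def select_lambda(
    design: np.ndarray,
    response: np.ndarray,
    coarse_grid: np.ndarray | None = None,
    refine_factor: int = 20,
    gram: np.ndarray | None = None,
) -> GcvResult:
    """Two-stage GCV search: coarse grid, then a fine grid spanning the two
    coarse neighbours of the coarse minimizer."""
    X = np.atleast_2d(np.asarray(design, dtype=float))
    y = np.asarray(response, dtype=float)
    if coarse_grid is None:
        coarse_grid = default_coarse_grid(X, y)
    grid = np.asarray(coarse_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("coarse grid must be nonempty")
    if np.any(grid < 0):
        raise ValueError("coarse grid must be nonnegative")
    if grid.size > 1 and np.any(np.diff(grid) <= 0):
        raise ValueError("coarse grid must be strictly increasing")

    gcv_coarse = _gcv_on_grid(X, y, grid, gram=gram)
    i = _argmin_prefer_larger(grid, gcv_coarse)
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    if refine_factor < 1:
        raise ValueError("refine_factor must be a positive integer")
    if lo == hi or refine_factor == 1:
        fine = np.array([grid[i]])
    else:
        # keep the coarse minimizer itself in the fine grid so the refined
        # search can never lose the coarse optimum (e.g. when every other
        # fine point saturates d >= N)
        fine = np.union1d(np.linspace(lo, hi, refine_factor), [grid[i]])
    gcv_fine = _gcv_on_grid(X, y, fine, gram=gram)
    try:
        j = _argmin_prefer_larger(fine, gcv_fine)
    except ValueError:
        # every fine point saturated (possible near d = N); keep the
        # coarse optimum
        fine = np.array([grid[i]])
        gcv_fine = gcv_coarse[[i]]
        j = 0
    return GcvResult(
        lambda_grid_coarse=grid,
        gcv_coarse=gcv_coarse,
        lambda_grid_fine=fine,
        gcv_fine=gcv_fine,
        lambda_star=float(fine[j]),
    )


def initial_condition(
    obs: EpochObservations, lambda_init: float
) -> np.ndarray:
    """Static-network estimate used to seed the tracker.

    Pools every epoch's columns into one regression per gene and solves
    the l1-penalized least-squares problem at ``lambda_init``; the rows
    stack into the initial connectivity matrix.
    """
    p = obs.n_genes
    if sum(obs.m_per_epoch) < 1:
        raise ValueError("need at least one pooled sample")
    A0 = np.zeros((p, p))
    for i in range(p):
        design, response = pooled_gene_problem(obs, i)
        A0[i] = lasso_fit(design, response, lambda_init)
    return A0


def static_fit(
    obs: EpochObservations,
    coarse_grid: np.ndarray | None = None,
    refine_factor: int = 20,
    lambda_override: float | None = None,
) -> StaticFit:
    """Per-gene GCV lambda selection plus the matching static estimate.

    Returns a :class:`StaticFit` whose ``lambdas[i]`` is gene i's selected
    sparsity weight (or ``lambda_override`` for every gene when given),
    row i of ``A0`` is the static LASSO estimate at that weight, and
    ``p0_scales[i]`` the estimated error variance of that row (NaN when
    the pooled problem is underdetermined).
    """
    p = obs.n_genes
    lambdas = np.zeros(p)
    A0 = np.zeros((p, p))
    p0_scales = np.full(p, np.nan)
    # all genes share the pooled design X, so its Gram matrix is computed
    # once and reused by every coordinate-descent fit
    design, _ = pooled_gene_problem(obs, 0)
    gram = design.T @ design
    N = design.shape[0]
    for i in range(p):
        design, response = pooled_gene_problem(obs, i)
        if lambda_override is not None:
            lambdas[i] = lambda_override
            gcv_min = gcv_statistic(design, response, lambda_override)
        else:
            res = select_lambda(
                design,
                response,
                coarse_grid=coarse_grid,
                refine_factor=refine_factor,
                gram=gram,
            )
            lambdas[i] = res.lambda_star
            gcv_min = res.gcv_star
        A0[i] = lasso_fit(design, response, lambdas[i])
        if N >= p and np.isfinite(gcv_min):
            p0_scales[i] = max(gcv_min / N, 1e-6)
    return StaticFit(lambdas=lambdas, A0=A0, p0_scales=p0_scales)
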