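"""LASSO-Kalman filter and forward-backward smoother.

Each gene's incoming-edge vector a_i(k) follows a random walk,

    a_i(k+1) = a_i(k) + w_i(k),        w_i ~ N(0, Q)
    y_i(k)   = X^T(k) a_i(k) + v_i(k), v_i ~ N(0, R)

and is tracked with a Kalman filter whose unconstrained update is, at
every epoch, projected onto the set of sparse vectors by solving

    min_a ||a_tilde - a||_2^2 + lambda ||a||_1,

whose exact minimizer is elementwise soft-thresholding at lambda/2.
A forward and a backward constrained filter are fused per epoch by
inverse-covariance weighting to form the smoothed estimate; smoothing can
only reduce the posterior variance.

The reported (read-out) estimate at each epoch is, by default, the
projection of the current estimate at the *universal threshold*
``sqrt(2 log p * P_jj)`` implied by its own posterior covariance — the
soft-threshold level that suppresses all p noise coordinates with high
probability while keeping edges that the data actually support.  The
recursions themselves are projected at the data-selected lambda, so the
lambda = 0 limit of the internal state is exactly the classical Kalman
filter (``readout='plain'`` turns the calibrated read-out off and reports
the raw in-loop estimates).

The p per-gene trackers are independent and run in parallel; results do
not depend on the worker count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from joblib import Parallel, delayed

from .model import EpochObservations, extract_gene_problem

logger = logging.getLogger(__name__)

__all__ = [
    "TrackOptions",
    "GeneTrackState",
    "GeneTrajectory",
    "NetworkTrajectory",
    "TrackingError",
    "predict",
    "update",
    "lasso_project",
    "universal_threshold",
    "filter_gene",
    "smooth_gene",
    "track_network",
]

#: ridge added to a covariance before inversion when it is numerically singular
_COV_JITTER = 1e-10


class TrackingError(RuntimeError):
    """Numerical failure inside a gene tracker (gene/epoch in the message)."""


@dataclass
class TrackOptions:
    """Noise model and sparsity settings for the per-gene tracker.

    Parameters
    ----------
    lambda_
        Sparsity weight of the l1 projection; 0 gives the classical
        (unconstrained) Kalman filter.
    q_scale
        Process-noise covariance Q = q_scale * I.  Controls how fast the
        network is allowed to rewire between epochs.
    r_scale
        Observation-noise covariance R = r_scale * I.
    p0_scale
        Initial state covariance P0 = p0_scale * I.
    p0_backward_scale
        Diffuse prior covariance for the backward filter started at the
        last epoch.
    readout
        ``'calibrated'`` (default) reports, at every epoch, the projection
        of the current estimate at the universal threshold
        ``sqrt(2 log p * P_jj)`` given by its own posterior covariance;
        ``'plain'`` reports the in-loop (lambda-projected) estimates
        unchanged, which for lambda = 0 is the classical Kalman filter.
    lasso_tol, lasso_max_iter
        Convergence control for the iterative proximal solver kept behind
        the same interface as the closed form (see ``lasso_project``).
    """

    lambda_: float = 0.0
    q_scale: float = 1e-3
    r_scale: float = 1e-1
    p0_scale: float = 1.0
    p0_backward_scale: float = 1e3
    readout: str = "calibrated"
    lasso_tol: float = 1e-10
    lasso_max_iter: int = 1000

    def __post_init__(self) -> None:
        if self.lambda_ < 0:
            raise ValueError("lambda_ must be nonnegative")
        for name in ("q_scale", "r_scale", "p0_scale", "p0_backward_scale"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and nonnegative")
        if self.r_scale <= 0:
            raise ValueError("r_scale must be positive")
        if self.readout not in ("calibrated", "plain"):
            raise ValueError("readout must be 'calibrated' or 'plain'")


@dataclass
class GeneTrackState:
    """Kalman state for one gene: edge-weight vector a, covariance P and
    the noise covariances Q (process) and R-scale (observation)."""

    gene_index: int
    a: np.ndarray
    P: np.ndarray
    Q: np.ndarray
    r_scale: float

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        self.Q = np.asarray(self.Q, dtype=float)

    def validate(self) -> "GeneTrackState":
        """Assert symmetry (tolerance 1e-8) and positive semi-definiteness
        (eigenvalue floor -1e-8) of P and Q.  Called once when a tracker
        starts; the recursions preserve both properties and skip the
        O(p^3) eigenvalue check per step."""
        for name, M in (("P", self.P), ("Q", self.Q)):
            if not np.allclose(M, M.T, atol=1e-8):
                raise ValueError(f"{name} must be symmetric")
            if np.linalg.eigvalsh(M).min() < -1e-8:
                raise ValueError(f"{name} must be positive semi-definite")
        return self


@dataclass
class GeneTrajectory:
    """Filtered and smoothed tracks of one gene over all epochs."""

    gene_index: int
    filtered: list[np.ndarray] = field(default_factory=list)
    filtered_cov: list[np.ndarray] = field(default_factory=list)
    smoothed: list[np.ndarray] = field(default_factory=list)
    smoothed_cov: list[np.ndarray] = field(default_factory=list)


@dataclass
class NetworkTrajectory:
    """Sequence of p x p signed connectivity matrices, one per epoch.

    ``matrices`` holds the smoothed estimates when smoothing was run and
    the filtered estimates otherwise; ``filtered_matrices`` always holds
    the forward-filter-only estimates.  ``failures`` maps gene index to
    the error message for genes whose tracker failed (their rows are
    zero).
    """

    matrices: list[np.ndarray]
    filtered_matrices: list[np.ndarray]
    failures: dict[int, str] = field(default_factory=dict)

    @property
    def n_epochs(self) -> int:
        return len(self.matrices)

    @property
    def n_genes(self) -> int:
        return self.matrices[0].shape[0]


def _symmetrize(P: np.ndarray) -> np.ndarray:
    return (P + P.T) / 2.0


def predict(state: GeneTrackState) -> GeneTrackState:
    """Time update under the random-walk model: a unchanged, P <- P + Q."""
    return replace(state, a=state.a.copy(), P=_symmetrize(state.P + state.Q))


def update(
    state: GeneTrackState,
    design: np.ndarray,
    response: np.ndarray,
    epoch: int | None = None,
) -> GeneTrackState:
    """Measurement update (unconstrained minimum-mean-square estimate).

    With H = design (m_k x p) and R = r_scale * I, the gain is
    ``K = P H^T (H P H^T + R)^-1``; the innovation system is solved with a
    linear solver rather than an explicit inverse.
    """
    H = np.atleast_2d(np.asarray(design, dtype=float))
    y = np.atleast_1d(np.asarray(response, dtype=float))
    m = H.shape[0]
    PHt = state.P @ H.T
    S = H @ PHt + state.r_scale * np.eye(m)
    try:
        # K^T = S^-1 (P H^T)^T since S is symmetric
        K = np.linalg.solve(S, PHt.T).T
    except np.linalg.LinAlgError as exc:
        where = f" at epoch {epoch}" if epoch is not None else ""
        raise TrackingError(
            f"singular innovation covariance for gene {state.gene_index}{where}"
        ) from exc
    a = state.a + K @ (y - H @ state.a)
    P = _symmetrize((np.eye(len(state.a)) - K @ H) @ state.P)
    return replace(state, a=a, P=P)


def _soft_threshold(a: np.ndarray, thresh: float) -> np.ndarray:
    return np.sign(a) * np.maximum(np.abs(a) - thresh, 0.0)


def lasso_project(
    a_unconstrained: np.ndarray,
    cov: np.ndarray | None,
    lambda_: float,
    opts: TrackOptions | None = None,
    method: str = "closed_form",
) -> np.ndarray:
    """Project an unconstrained estimate onto the set of sparse vectors.

    Solves ``min_a ||a_tilde - a||_2^2 + lambda ||a||_1``.  The objective is
    separable, so the exact minimizer is soft-thresholding at lambda/2
    (``method='closed_form'``).  ``method='iterative'`` runs proximal
    gradient descent to ``opts.lasso_tol`` behind the same interface; it is
    the hook for a future Mahalanobis-weighted variant and must agree with
    the closed form for the identity-weighted objective.  The covariance is
    passed through unmodified by the projection and is therefore not an
    argument of the returned value.
    """
    if lambda_ < 0:
        raise ValueError("lambda_ must be nonnegative")
    a_tilde = np.asarray(a_unconstrained, dtype=float)
    if method == "closed_form":
        return _soft_threshold(a_tilde, lambda_ / 2.0)
    if method == "iterative":
        opts = opts or TrackOptions()
        # proximal gradient on f(a) = ||a_tilde - a||^2 (Lipschitz L = 2)
        a = a_tilde.copy()
        step = 0.5  # 1/L
        for _ in range(opts.lasso_max_iter):
            grad = 2.0 * (a - a_tilde)
            a_new = _soft_threshold(a - step * grad, step * lambda_)
            if np.max(np.abs(a_new - a)) < opts.lasso_tol:
                a = a_new
                break
            a = a_new
        return a
    raise ValueError(f"unknown projection method: {method!r}")


def universal_threshold(P: np.ndarray) -> np.ndarray:
    """Per-coordinate soft-threshold level ``sqrt(2 log p * P_jj)``.

    For p independent noise coordinates with standard deviations
    ``sqrt(P_jj)`` this is the classical universal threshold: the smallest
    level at which pure noise is set to zero with high probability.
    """
    p = P.shape[0]
    return np.sqrt(2.0 * np.log(p) * np.clip(np.diag(P), 0.0, None))


def _readout(a_unconstrained: np.ndarray, P: np.ndarray, opts: TrackOptions) -> np.ndarray:
    # The calibrated read-out is a hard threshold: it keeps the
    # unconstrained estimate unchanged where it exceeds its own posterior
    # uncertainty level (a coefficient-wise significance test at the
    # universal level) and zeroes it elsewhere.  Unlike the soft operator
    # used inside the recursions it leaves surviving edge weights
    # unbiased.
    if opts.readout == "calibrated":
        a = a_unconstrained.copy()
        a[np.abs(a) <= universal_threshold(P)] = 0.0
        return a
    return _soft_threshold(a_unconstrained, opts.lambda_ / 2.0)


def _initial_state(
    gene_index: int, p: int, opts: TrackOptions, a0: np.ndarray | None
) -> GeneTrackState:
    a = np.zeros(p) if a0 is None else np.asarray(a0, dtype=float).copy()
    return GeneTrackState(
        gene_index=gene_index,
        a=a,
        P=opts.p0_scale * np.eye(p),
        Q=opts.q_scale * np.eye(p),
        r_scale=opts.r_scale,
    ).validate()


def _forward_pass(
    problems: list[tuple[np.ndarray, np.ndarray]],
    opts: TrackOptions,
    a0: np.ndarray | None,
    gene_index: int,
) -> tuple[list[np.ndarray], list[np.ndarray], list[np.ndarray]]:
    """Forward constrained filter.

    Returns (internal constrained states, covariances, reported
    estimates).  The internal state fed to the next epoch is the
    lambda-projected update; the reported estimate applies the read-out
    projection (see ``TrackOptions.readout``) to the unconstrained
    update.
    """
    p = problems[0][0].shape[1]
    state = _initial_state(gene_index, p, opts, a0)
    internal, covs, reported = [], [], []
    for k, (design, response) in enumerate(problems):
        state = predict(state)
        state = update(state, design, response, epoch=k)
        reported.append(_readout(state.a, state.P, opts))
        state = replace(
            state, a=lasso_project(state.a, state.P, opts.lambda_, opts)
        )
        internal.append(state.a.copy())
        covs.append(state.P.copy())
    return internal, covs, reported


def filter_gene(
    problems: list[tuple[np.ndarray, np.ndarray]],
    opts: TrackOptions,
    a0: np.ndarray | None = None,
    gene_index: int = 0,
) -> GeneTrajectory:
    """Forward constrained filter: predict, update, project per epoch."""
    _, covs, reported = _forward_pass(problems, opts, a0, gene_index)
    return GeneTrajectory(
        gene_index=gene_index, filtered=reported, filtered_cov=covs
    )


def _backward_predicted(
    problems: list[tuple[np.ndarray, np.ndarray]],
    opts: TrackOptions,
    gene_index: int,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Backward constrained filter, returning at each epoch k the estimate
    built from epochs k+1..n only (its "predicted" value at k), so that
    fusing with the forward filtered estimate does not count epoch k's
    data twice.  The backward filter starts from a diffuse prior at the
    last epoch."""
    p = problems[0][0].shape[1]
    n = len(problems)
    state = GeneTrackState(
        gene_index=gene_index,
        a=np.zeros(p),
        P=opts.p0_backward_scale * np.eye(p),
        Q=opts.q_scale * np.eye(p),
        r_scale=opts.r_scale,
    )
    a_pred: list[np.ndarray] = [None] * n  # type: ignore[list-item]
    P_pred: list[np.ndarray] = [None] * n  # type: ignore[list-item]
    for k in range(n - 1, -1, -1):
        a_pred[k] = state.a.copy()
        P_pred[k] = state.P.copy()
        design, response = problems[k]
        state = update(state, design, response, epoch=k)
        state = replace(
            state, a=lasso_project(state.a, state.P, opts.lambda_, opts)
        )
        state = predict(state)  # random walk is time-symmetric
    return a_pred, P_pred


def _safe_inv(P: np.ndarray, gene_index: int, epoch: int) -> np.ndarray:
    try:
        return np.linalg.inv(P)
    except np.linalg.LinAlgError:
        logger.warning(
            "regularizing singular covariance for gene %d at epoch %d",
            gene_index,
            epoch,
        )
        return np.linalg.inv(P + _COV_JITTER * np.eye(P.shape[0]))


def smooth_gene(
    problems: list[tuple[np.ndarray, np.ndarray]],
    opts: TrackOptions,
    a0: np.ndarray | None = None,
    gene_index: int = 0,
) -> GeneTrajectory:
    """Forward-backward smoother for one gene.

    Runs the forward constrained filter and a backward constrained filter
    (same equations with the epochs reversed), then fuses the forward
    filtered estimate with the backward predicted estimate per epoch by
    inverse-covariance (information) weighting:

        P_s = (P_f^-1 + P_b^-1)^-1,
        a_s = P_s (P_f^-1 a_f + P_b^-1 a_b),

    followed by a final l1 (read-out) projection of the fused state.
    Because the fused information matrix dominates the filtered one, every
    smoothed posterior variance is bounded by its filtered counterpart.
    """
    internal, covs, reported = _forward_pass(problems, opts, a0, gene_index)
    traj = GeneTrajectory(
        gene_index=gene_index, filtered=reported, filtered_cov=covs
    )
    a_b, P_b = _backward_predicted(problems, opts, gene_index)
    for k in range(len(problems)):
        Jf = _safe_inv(covs[k], gene_index, k)
        Jb = _safe_inv(P_b[k], gene_index, k)
        Ps = np.linalg.inv(Jf + Jb)
        Ps = _symmetrize(Ps)
        a_s = Ps @ (Jf @ internal[k] + Jb @ a_b[k])
        traj.smoothed.append(_readout(a_s, Ps, opts))
        traj.smoothed_cov.append(Ps)
    return traj


def _track_one(
    obs: EpochObservations,
    gene_index: int,
    opts: TrackOptions,
    lambda_i: float,
    p0_i: float,
    a0_i: np.ndarray | None,
    smooth: bool,
) -> GeneTrajectory | tuple[int, str]:
    gene_opts = replace(
        opts,
        lambda_=lambda_i,
        p0_scale=opts.p0_scale if np.isnan(p0_i) else p0_i,
    )
    problems = extract_gene_problem(obs, gene_index)
    try:
        if smooth:
            return smooth_gene(problems, gene_opts, a0=a0_i, gene_index=gene_index)
        return filter_gene(problems, gene_opts, a0=a0_i, gene_index=gene_index)
    except TrackingError as exc:
        return (gene_index, str(exc))


def track_network(
    obs: EpochObservations,
    opts: TrackOptions,
    init: np.ndarray | None = None,
    lambdas: np.ndarray | float | None = None,
    p0_scales: np.ndarray | None = None,
    smooth: bool = True,
    n_jobs: int = 1,
) -> NetworkTrajectory:
    """Track every gene and stack row i of A(k) from gene i's estimate.

    Parameters
    ----------
    init
        p x p initial connectivity matrix (row i seeds gene i's state), or
        ``None`` for a zero start.
    lambdas
        Per-gene sparsity weights (length p), a scalar for all genes, or
        ``None`` to use ``opts.lambda_``.
    p0_scales
        Per-gene initial covariance scales (length p; NaN entries fall
        back to ``opts.p0_scale``), or ``None`` for ``opts.p0_scale``
        everywhere.
    smooth
        Run the forward-backward smoother (default); ``False`` stops after
        the forward constrained filter.
    n_jobs
        Worker processes for the per-gene trackers.  Genes are independent,
        so the result is identical for any worker count.
    """
    p = obs.n_genes
    n = obs.n_epochs
    if lambdas is None:
        lam = np.full(p, opts.lambda_)
    else:
        lam = np.broadcast_to(np.asarray(lambdas, dtype=float), (p,)).copy()
    if init is not None and np.asarray(init).shape != (p, p):
        raise ValueError(f"init must be {p}x{p}")
    if p0_scales is None:
        p0 = np.full(p, np.nan)
    else:
        p0 = np.broadcast_to(np.asarray(p0_scales, dtype=float), (p,)).copy()

    results = Parallel(n_jobs=n_jobs)(
        delayed(_track_one)(
            obs,
            i,
            opts,
            lam[i],
            p0[i],
            None if init is None else np.asarray(init)[i],
            smooth,
        )
        for i in range(p)
    )

    matrices = [np.zeros((p, p)) for _ in range(n)]
    filtered = [np.zeros((p, p)) for _ in range(n)]
    failures: dict[int, str] = {}
    for i, res in enumerate(results):
        if isinstance(res, tuple):
            failures[res[0]] = res[1]
            logger.error("gene %d failed: %s", res[0], res[1])
            continue
        rows = res.smoothed if smooth else res.filtered
        for k in range(n):
            matrices[k][i] = rows[k]
            filtered[k][i] = res.filtered[k]
    return NetworkTrajectory(
        matrices=matrices, filtered_matrices=filtered, failures=failures
    )
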