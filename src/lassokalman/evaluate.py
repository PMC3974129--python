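"""Evaluation of recovered time-varying networks.

Two complementary scores:

* an edge-error rate that counts an estimated edge wrong when it falls
  outside an alpha-vicinity of the true weight, ``|a - a_hat| > alpha |a|``
  (for a true zero, any nonzero estimate errs);
* presence/absence confusion metrics after binarizing both truth and
  estimate at a magnitude threshold, pooled over all epochs and entries.

Also provides the Monte-Carlo benchmark harness (ensemble scoring of the
smoothed, filter-only and classical-Kalman variants; error-vs-size and
error-vs-observations sweeps) and temporal graph statistics: per-gene
degree trajectories, the discrete power-law exponent of the degree
distribution and the mean clustering coefficient.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import zeta

from .model import EpochObservations
from .regularization import static_fit
from .simulate import SimConfig, scenario_table1, simulate
from .tracker import NetworkTrajectory, TrackOptions, track_network

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionReport",
    "edge_error_rate",
    "confusion_counts",
    "confusion_metrics",
    "infer_trajectory",
    "benchmark_confusion",
    "sweep_network_size",
    "sweep_observation_count",
    "degree_trajectories",
    "powerlaw_exponent",
    "clustering_coefficient",
]

#: edges with absolute strength below this are treated as absent
DEFAULT_PRESENCE_THRESHOLD = 1e-3
#: half-width of the relative error tolerance band around a true edge
DEFAULT_ALPHA = 0.2

#: tracker variants scored in the benchmark ensemble
METHODS = ("smoothed", "filtered", "classical")


@dataclass
class ConfusionReport:
    """Pooled presence/absence confusion summary.

    tp/tn/fp/fn are percentages of all scored entries (they sum to 100);
    the derived ratios are ``None`` when their denominator is zero.
    """

    tp: float
    tn: float
    fp: float
    fn: float
    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    precision: float | None

    @classmethod
    def from_counts(cls, tp: int, tn: int, fp: int, fn: int) -> "ConfusionReport":
        total = tp + tn + fp + fn
        if total == 0:
            raise ValueError("no scored entries")

        def ratio(num: int, den: int) -> float | None:
            return num / den if den > 0 else None

        return cls(
            tp=100.0 * tp / total,
            tn=100.0 * tn / total,
            fp=100.0 * fp / total,
            fn=100.0 * fn / total,
            sensitivity=ratio(tp, tp + fn),
            specificity=ratio(tn, tn + fp),
            accuracy=(tp + tn) / total,
            precision=ratio(tp, tp + fp),
        )


def edge_error_rate(
    true_A: np.ndarray, est_A: np.ndarray, alpha: float = DEFAULT_ALPHA
) -> float:
    """Fraction of entries outside the alpha-vicinity of the true value.

    Entry (i, j) errs when ``|a_ij - a_hat_ij| > alpha |a_ij|``; for a true
    zero this degenerates to "any nonzero estimate errs".
    """
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    t = np.asarray(true_A, dtype=float)
    e = np.asarray(est_A, dtype=float)
    if t.shape != e.shape:
        raise ValueError(f"shape mismatch: {t.shape} vs {e.shape}")
    errors = np.abs(t - e) > alpha * np.abs(t)
    return float(errors.mean())


def confusion_counts(
    true_seq: list[np.ndarray],
    est_seq: list[np.ndarray],
    presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD,
) -> tuple[int, int, int, int]:
    """Pooled (tp, tn, fp, fn) entry counts after binarizing both
    sequences at ``|entry| > presence_threshold``."""
    if len(true_seq) != len(est_seq):
        raise ValueError("sequences must have equal length")
    tp = tn = fp = fn = 0
    for T, E in zip(true_seq, est_seq):
        if T.shape != E.shape:
            raise ValueError(f"shape mismatch: {T.shape} vs {E.shape}")
        t = np.abs(T) > presence_threshold
        e = np.abs(E) > presence_threshold
        tp += int(np.sum(t & e))
        tn += int(np.sum(~t & ~e))
        fp += int(np.sum(~t & e))
        fn += int(np.sum(t & ~e))
    return tp, tn, fp, fn


def confusion_metrics(
    true_seq: list[np.ndarray],
    est_seq: list[np.ndarray],
    presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD,
) -> ConfusionReport:
    """Presence/absence confusion report pooled over all epochs; sign and
    strength of the interactions are ignored."""
    return ConfusionReport.from_counts(
        *confusion_counts(true_seq, est_seq, presence_threshold)
    )


def infer_trajectory(
    obs: EpochObservations,
    opts: TrackOptions | None = None,
    method: str = "smoothed",
    n_jobs: int = 1,
) -> NetworkTrajectory:
    """Full inference pipeline on one observation set.

    Selects a per-gene sparsity weight by GCV on the pooled static
    regression, seeds the tracker with the static l1 estimate, then runs

    * ``'smoothed'``  — LASSO-Kalman forward-backward smoother,
    * ``'filtered'``  — forward LASSO-Kalman filter only,
    * ``'classical'`` — unconstrained (lambda = 0, plain read-out),
      unsmoothed Kalman filter, same initial condition.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    opts = opts or TrackOptions()
    fit = static_fit(obs)
    lambdas = fit.lambdas
    if method == "classical":
        lambdas = np.zeros_like(lambdas)
        opts = dataclasses.replace(opts, readout="plain")
    return track_network(
        obs,
        opts,
        init=fit.A0,
        lambdas=lambdas,
        p0_scales=fit.p0_scales,
        smooth=(method == "smoothed"),
        n_jobs=n_jobs,
    )


def benchmark_confusion(
    n_networks: int,
    seed: int = 0,
    presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD,
    opts: TrackOptions | None = None,
    methods: tuple[str, ...] = METHODS,
    **sim_overrides,
) -> dict[str, ConfusionReport]:
    """Confusion metrics for each tracker variant on an ensemble of
    ten-gene / five-epoch / seven-observation benchmark networks, pooled
    over all networks, epochs and entries.

    The static fit (lambda selection + initial condition) is shared by the
    variants of each instance; the classical variant tracks with
    lambda = 0 and a plain read-out from the same start.  When ``opts`` is
    not given, the process/observation covariances are set to the values
    the generator actually uses (the known-covariance assumption).
    """
    base_cfg = SimConfig(p=10, n_epochs=5, m_per_epoch=7, **sim_overrides)
    opts = opts or base_cfg.matched_track_options()
    classical_opts = dataclasses.replace(opts, readout="plain")
    counts = {m: np.zeros(4, dtype=np.int64) for m in methods}
    for networks, obs in scenario_table1(n_networks, seed=seed, **sim_overrides):
        fit = static_fit(obs)
        for method in methods:
            lam = (
                np.zeros_like(fit.lambdas)
                if method == "classical"
                else fit.lambdas
            )
            traj = track_network(
                obs,
                classical_opts if method == "classical" else opts,
                init=fit.A0,
                lambdas=lam,
                p0_scales=fit.p0_scales,
                smooth=(method == "smoothed"),
            )
            counts[method] += np.asarray(
                confusion_counts(networks, traj.matrices, presence_threshold),
                dtype=np.int64,
            )
    return {
        m: ConfusionReport.from_counts(*counts[m].tolist()) for m in methods
    }


def _mean_trajectory_error(
    networks: list[np.ndarray],
    traj: NetworkTrajectory,
    alpha: float,
) -> float:
    """Edge-error rate averaged over epochs."""
    return float(
        np.mean(
            [edge_error_rate(T, E, alpha) for T, E in zip(networks, traj.matrices)]
        )
    )


def _rep_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


def sweep_network_size(
    sizes: list[int],
    obs_fraction: float = 0.7,
    reps: int = 5,
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
    opts: TrackOptions | None = None,
    n_jobs: int = 1,
    **sim_overrides,
) -> dict[int, float]:
    """Mean edge-error rate versus network size p, with m = obs_fraction*p
    observation columns per epoch."""
    out = {}
    for p in sizes:
        if p < 2:
            raise ValueError("network sizes must be >= 2")
        m = max(1, int(round(obs_fraction * p)))
        errs = []
        for s in _rep_seeds(seed + p, reps):
            cfg = SimConfig(p=p, m_per_epoch=m, seed=int(s), **sim_overrides)
            networks, obs = simulate(cfg)
            traj = infer_trajectory(
                obs, opts=opts or cfg.matched_track_options(), n_jobs=n_jobs
            )
            errs.append(_mean_trajectory_error(networks, traj, alpha))
        out[p] = float(np.mean(errs))
        logger.info("size sweep p=%d m=%d: error %.4f", p, m, out[p])
    return out


def sweep_observation_count(
    p: int,
    m_values: list[int],
    reps: int = 5,
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
    opts: TrackOptions | None = None,
    n_jobs: int = 1,
    **sim_overrides,
) -> dict[int, float]:
    """Mean edge-error rate versus observations per epoch at fixed p.

    Replicates are seed-matched across m values so the error trend in m is
    a paired comparison.
    """
    seeds = _rep_seeds(seed, reps)
    out = {}
    for m in m_values:
        if m < 1:
            raise ValueError("m values must be >= 1")
        errs = []
        for s in seeds:
            cfg = SimConfig(p=p, m_per_epoch=int(m), seed=int(s), **sim_overrides)
            networks, obs = simulate(cfg)
            traj = infer_trajectory(
                obs, opts=opts or cfg.matched_track_options(), n_jobs=n_jobs
            )
            errs.append(_mean_trajectory_error(networks, traj, alpha))
        out[int(m)] = float(np.mean(errs))
        logger.info("observation sweep m=%d: error %.4f", m, out[int(m)])
    return out


def _binary_graph(
    est: np.ndarray, presence_threshold: float
) -> nx.Graph:
    """Symmetrized, binarized (undirected) graph of one network snapshot."""
    adj = np.abs(np.asarray(est, dtype=float)) > presence_threshold
    np.fill_diagonal(adj, False)  # self-loops are degradation, not edges
    adj = adj | adj.T
    G = nx.from_numpy_array(adj.astype(int))
    return G


def degree_trajectories(
    est_seq: list[np.ndarray],
    presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD,
) -> np.ndarray:
    """Genes x epochs matrix of degrees on the symmetrized binarized
    snapshots; rows can then be ordered by the onset of their first
    increase to visualize transient vs permanent hub genes."""
    cols = []
    for est in est_seq:
        G = _binary_graph(est, presence_threshold)
        cols.append([G.degree(i) for i in range(est.shape[0])])
    return np.asarray(cols, dtype=int).T


def powerlaw_exponent(
    est: np.ndarray,
    presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD,
) -> float:
    """Maximum-likelihood exponent of a discrete power law (xmin = 1)
    fitted to the positive degrees of the binarized snapshot.

    Maximizes ``-n log zeta(g) - g sum(log d)`` over g in (1, 20].
    Raises ``ValueError`` for degenerate degree sequences (fewer than two
    distinct positive degrees), where the fit is undefined.
    """
    G = _binary_graph(est, presence_threshold)
    degrees = np.array([d for _, d in G.degree() if d > 0], dtype=float)
    if degrees.size == 0 or np.unique(degrees).size < 2:
        raise ValueError("degenerate degree sequence; power-law fit undefined")
    n = degrees.size
    slog = float(np.sum(np.log(degrees)))

    def nll(g: float) -> float:
        return n * np.log(zeta(g, 1)) + g * slog

    res = minimize_scalar(nll, bounds=(1.0001, 20.0), method="bounded")
    return float(res.x)


def clustering_coefficient(
    est: np.ndarray,
    presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD,
) -> float:
    """Mean local clustering coefficient of the binarized snapshot; nodes
    of degree < 2 contribute 0 to the mean."""
    G = _binary_graph(est, presence_threshold)
    return float(nx.average_clustering(G, count_zeros=True))
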