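"""Synthetic time-varying sparse networks and observations.

Generates ground-truth connectivity sequences A(1..n) — sparse signed
off-diagonal interactions, negative diagonal self-degradation, slow
rewiring between epochs — and observation blocks Y(k) = A(k) X(k) + V(k)
with standard-normal expression snapshots X(k) and i.i.d. Gaussian
observation noise.  Everything is reproducible from the configured seed.

Defaults emulate a desk-scale benchmark: ten-gene networks, five epochs,
seven observation columns per epoch, 20% off-diagonal density, edge
magnitudes in [0.5, 1.5], 20% of edges rewired per epoch and observation
noise sd 0.1.  These generation parameters are package assumptions (see
the methods note) — the density in particular bounds what any
presence/absence score on this benchmark can look like.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .model import Epoch, EpochObservations
from .tracker import TrackOptions

__all__ = [
    "SimConfig",
    "generate_network_sequence",
    "generate_observations",
    "simulate",
    "scenario_table1",
]


@dataclass
class SimConfig:
    """Generation parameters for one synthetic network benchmark.

    ``sparsity`` is the expected fraction of nonzero off-diagonal entries;
    ``rewire_fraction`` the fraction of existing edges replaced between
    consecutive epochs; edge magnitudes are uniform on
    ``[edge_low, edge_high]`` with random sign; diagonal entries (self-
    degradation rates, entering negated) are uniform on
    ``[-diag_high, -diag_low]``.
    """

    p: int = 10
    n_epochs: int = 5
    m_per_epoch: int = 7
    sparsity: float = 0.2
    edge_low: float = 0.5
    edge_high: float = 1.5
    rewire_fraction: float = 0.2
    obs_noise_sd: float = 0.1
    state_noise_sd: float = 0.0
    diag_low: float = 0.1
    diag_high: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p < 2:
            raise ValueError("p must be >= 2")
        if self.n_epochs < 1 or self.m_per_epoch < 1:
            raise ValueError("n_epochs and m_per_epoch must be >= 1")
        if not 0 < self.sparsity <= 1:
            raise ValueError("sparsity must be in (0, 1]")
        if not 0 <= self.rewire_fraction <= 1:
            raise ValueError("rewire_fraction must be in [0, 1]")
        if self.edge_low > self.edge_high:
            raise ValueError("edge_low must be <= edge_high")
        if self.obs_noise_sd < 0 or self.state_noise_sd < 0:
            raise ValueError("noise standard deviations must be nonnegative")

    def matched_track_options(self, **overrides) -> TrackOptions:
        """Tracker options with the noise covariances the generator
        actually uses (the known-covariance assumption of the model).

        ``r_scale`` is the observation-noise variance; ``q_scale`` is the
        per-entry variance of the state increment a(k+1) - a(k) implied by
        the rewiring law: 2 * n_rewired entries change per epoch, each by
        an edge weight with second moment E[w^2] for uniform magnitudes on
        [edge_low, edge_high].
        """
        ew2 = (
            self.edge_low**2 + self.edge_low * self.edge_high + self.edge_high**2
        ) / 3.0
        nnz = self.sparsity * self.p * (self.p - 1)
        q = 2.0 * round(self.rewire_fraction * nnz) * ew2 / self.p**2
        q += self.state_noise_sd**2
        kwargs = dict(
            q_scale=max(q, 1e-8), r_scale=max(self.obs_noise_sd**2, 1e-8)
        )
        kwargs.update(overrides)
        return TrackOptions(**kwargs)


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    # independent, reproducible streams for networks vs observations
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, stream]))


def _random_edges(
    rng: np.random.Generator, count: int, cfg: SimConfig
) -> np.ndarray:
    mag = rng.uniform(cfg.edge_low, cfg.edge_high, size=count)
    sign = rng.choice([-1.0, 1.0], size=count)
    return mag * sign


def generate_network_sequence(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> list[np.ndarray]:
    """Epoch-1 network with i.i.d. Bernoulli(sparsity) off-diagonal support,
    then per epoch a copy of the previous matrix with
    ``round(rewire_fraction * nnz)`` edges deleted and re-created at
    random vacant positions with fresh random weights.  Diagonals carry
    the (negated) self-degradation rates and drift with the state noise
    only through rewiring (they are never deleted)."""
    rng = _rng(cfg, 0) if rng is None else rng
    p = cfg.p
    A = np.zeros((p, p))
    off = ~np.eye(p, dtype=bool)
    support = rng.random((p, p)) < cfg.sparsity
    support &= off
    A[support] = _random_edges(rng, int(support.sum()), cfg)
    A[np.diag_indices(p)] = -rng.uniform(cfg.diag_low, cfg.diag_high, size=p)

    seq = [A]
    for _ in range(1, cfg.n_epochs):
        A = seq[-1].copy()
        edges = np.argwhere((A != 0) & off)
        n_rewire = int(round(cfg.rewire_fraction * len(edges)))
        if n_rewire > 0 and len(edges) > 0:
            drop = rng.choice(len(edges), size=n_rewire, replace=False)
            for r, c in edges[drop]:
                A[r, c] = 0.0
            vacant = np.argwhere((A == 0) & off)
            add = rng.choice(len(vacant), size=min(n_rewire, len(vacant)), replace=False)
            weights = _random_edges(rng, len(add), cfg)
            for (r, c), w in zip(vacant[add], weights):
                A[r, c] = w
        if cfg.state_noise_sd > 0:
            jitter = rng.normal(0.0, cfg.state_noise_sd, size=(p, p))
            A = np.where(A != 0, A + jitter, A)
        seq.append(A)
    return seq


def generate_observations(
    networks: list[np.ndarray],
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> EpochObservations:
    """Per epoch k: draw ``m_per_epoch`` standard-normal expression columns
    X(k) and set ``Y(k) = A(k) X(k) + V(k)`` with V ~ N(0, obs_noise_sd^2)."""
    rng = _rng(cfg, 1) if rng is None else rng
    p = cfg.p
    epochs = []
    for A in networks:
        if A.shape != (p, p):
            raise ValueError(f"network shape {A.shape} does not match p={p}")
        X = rng.standard_normal((p, cfg.m_per_epoch))
        V = (
            rng.normal(0.0, cfg.obs_noise_sd, size=(p, cfg.m_per_epoch))
            if cfg.obs_noise_sd > 0
            else np.zeros((p, cfg.m_per_epoch))
        )
        epochs.append(Epoch(X=X, Y=A @ X + V))
    return EpochObservations(epochs=epochs)


def simulate(cfg: SimConfig) -> tuple[list[np.ndarray], EpochObservations]:
    """Convenience wrapper: networks plus matching observations."""
    networks = generate_network_sequence(cfg)
    obs = generate_observations(networks, cfg)
    return networks, obs


def scenario_table1(
    n_networks: int, seed: int = 0, **overrides
) -> Iterator[tuple[list[np.ndarray], EpochObservations]]:
    """Stream of independent ten-gene / five-epoch / seven-observation
    benchmark instances (the ensemble used for confusion-matrix scoring).

    Yields ``(networks, observations)`` pairs lazily so arbitrarily large
    ensembles run in bounded memory.
    """
    if n_networks < 1:
        raise ValueError("n_networks must be >= 1")
    base = dict(p=10, n_epochs=5, m_per_epoch=7)
    base.update(overrides)
    child_seeds = np.random.SeedSequence(seed).generate_state(n_networks) % (2**31)
    for s in child_seeds:
        cfg = SimConfig(seed=int(s), **base)
        yield simulate(cfg)
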