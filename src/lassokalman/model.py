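"""Per-gene linear observation model for time-varying network inference.

The expression of gene *i* is modelled by a linear ODE,

    dx_i/dt = -lam_i(t) x_i(t) + sum_j w_ij(t) x_j(t) + b_i u(t) + noise,

where ``w_ij`` is the (signed) influence of gene *j* on gene *i*, ``lam_i``
the self-degradation rate and ``u`` a known external perturbation.
Absorbing the degradation into the interaction matrix
(``a_ij = w_ij - lam_i * delta_ij``) and moving the perturbation to the
left-hand side gives, per time epoch *k* with ``m_k`` observation columns,

    Y(k) = A(k) X(k) + V(k),

which decomposes into p independent regressions, one per row of A(k).
This module builds the (X, Y) epoch data from a raw expression series:
derivative estimation, perturbation correction and epoch grouping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ExpressionSeries",
    "Epoch",
    "EpochObservations",
    "estimate_derivatives",
    "build_observations",
    "extract_gene_problem",
    "pooled_gene_problem",
    "uniform_epoch_assignment",
]


@dataclass
class ExpressionSeries:
    """A p-gene expression time course with optional external perturbation.

    Parameters
    ----------
    values
        Expression matrix, genes in rows, samples in columns (p x T).
    time_labels
        One label per sample. Numeric labels define the time grid used for
        derivative estimation; non-numeric labels imply unit spacing.
    perturbation_u
        Known perturbation signal u(t), length T, or ``None``.
    perturbation_b
        Per-gene perturbation coefficients b_i, length p. Required when
        ``perturbation_u`` is given.
    gene_ids
        Optional gene identifiers (length p).
    """

    values: np.ndarray
    time_labels: list
    perturbation_u: np.ndarray | None = None
    perturbation_b: np.ndarray | None = None
    gene_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        p, T = self.values.shape
        if p < 2 or T < 2:
            raise ValueError(f"need at least 2 genes and 2 samples, got {p}x{T}")
        if len(self.time_labels) != T:
            raise ValueError("time_labels length must match the sample count")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"missing/non-finite expression value at gene {bad[0]}, sample {bad[1]}"
            )
        if self.perturbation_u is not None:
            self.perturbation_u = np.asarray(self.perturbation_u, dtype=float)
            if self.perturbation_b is None:
                raise ValueError("perturbation_u given without perturbation_b")
            self.perturbation_b = np.asarray(self.perturbation_b, dtype=float)
            if self.perturbation_u.shape != (T,):
                raise ValueError("perturbation_u must have one entry per sample")
            if self.perturbation_b.shape != (p,):
                raise ValueError("perturbation_b must have one entry per gene")
        if self.gene_ids is not None and len(self.gene_ids) != p:
            raise ValueError("gene_ids length must match the gene count")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def numeric_times(self) -> np.ndarray | None:
        """Time labels as floats, or ``None`` when they are not numeric."""
        try:
            t = np.asarray([float(x) for x in self.time_labels])
        except (TypeError, ValueError):
            return None
        return t


@dataclass
class Epoch:
    """One time epoch: m_k expression snapshots X and responses Y (p x m_k)."""

    X: np.ndarray
    Y: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        if self.X.shape != self.Y.shape:
            raise ValueError(f"X and Y shapes differ: {self.X.shape} vs {self.Y.shape}")

    @property
    def m(self) -> int:
        return self.X.shape[1]


@dataclass
class EpochObservations:
    """Sequence of per-epoch (X, Y) observation blocks for one network."""

    epochs: list[Epoch] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("at least one epoch is required")
        p = self.epochs[0].X.shape[0]
        for k, ep in enumerate(self.epochs):
            if ep.X.shape[0] != p:
                raise ValueError(f"epoch {k} has {ep.X.shape[0]} genes, expected {p}")
            if ep.m < 1:
                raise ValueError(f"epoch {k} is empty (m_k must be >= 1)")

    @property
    def n_genes(self) -> int:
        return self.epochs[0].X.shape[0]

    @property
    def n_epochs(self) -> int:
        return len(self.epochs)

    @property
    def m_per_epoch(self) -> list[int]:
        return [ep.m for ep in self.epochs]


def estimate_derivatives(series: ExpressionSeries) -> np.ndarray:
    """First-order forward-difference estimate of dx/dt, shape p x (T-1).

    Uses the actual time deltas when the labels are numeric (they must then
    be strictly increasing) and unit spacing otherwise.  The last sample has
    no forward neighbour and is dropped.
    """
    x = series.values
    t = series.numeric_times()
    if t is None:
        dt = np.ones(series.n_samples - 1)
    else:
        dt = np.diff(t)
        bad = np.where(dt <= 0)[0]
        if bad.size:
            raise ValueError(
                f"time labels must be strictly increasing; offending index {bad[0] + 1}"
            )
    return np.diff(x, axis=1) / dt


def uniform_epoch_assignment(n_usable: int, samples_per_epoch: int) -> list[int]:
    """Group usable samples into contiguous blocks of equal size.

    Trailing samples that do not fill a complete block join the last epoch,
    so every epoch has at least ``samples_per_epoch`` members.
    """
    if samples_per_epoch < 1:
        raise ValueError("samples_per_epoch must be >= 1")
    if n_usable < samples_per_epoch:
        raise ValueError("fewer usable samples than one epoch block")
    n_epochs = n_usable // samples_per_epoch
    assignment = [min(j // samples_per_epoch, n_epochs - 1) for j in range(n_usable)]
    return assignment


def build_observations(
    series: ExpressionSeries, epoch_assignment: list[int]
) -> EpochObservations:
    """Assemble per-epoch (X, Y) blocks from an expression series.

    For usable sample j (all but the last, lost to the forward difference)
    assigned to epoch k, the corresponding column of Y(k) is
    ``xdot(:, j) - b * u(j)`` and the column of X(k) is ``x(:, j)``.
    Epoch ids must be a contiguous non-decreasing sequence starting at 0.
    """
    xdot = estimate_derivatives(series)
    n_usable = xdot.shape[1]
    assignment = np.asarray(epoch_assignment, dtype=int)
    if assignment.shape != (n_usable,):
        raise ValueError(
            f"epoch assignment must cover all {n_usable} usable samples, "
            f"got {assignment.size}"
        )
    if assignment[0] != 0 or np.any(np.diff(assignment) < 0) or np.any(
        np.diff(assignment) > 1
    ):
        raise ValueError(
            "epoch ids must be contiguous, non-decreasing and start at 0"
        )

    y = xdot.copy()
    if series.perturbation_u is not None:
        u = series.perturbation_u[:n_usable]
        y -= np.outer(series.perturbation_b, u)

    x = series.values[:, :n_usable]
    epochs = []
    for k in range(assignment[-1] + 1):
        cols = np.where(assignment == k)[0]
        if cols.size == 0:
            raise ValueError(f"epoch {k} is empty; every epoch needs m_k >= 1")
        epochs.append(Epoch(X=x[:, cols], Y=y[:, cols]))
    return EpochObservations(epochs=epochs)


def extract_gene_problem(
    obs: EpochObservations, gene_index: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Observation sequence for the tracker of one gene.

    Per epoch k: design ``X(k)^T`` (m_k x p) and response = row
    ``gene_index`` of Y(k).  This is the decomposition of
    ``Y(k) = A(k) X(k) + V(k)`` into p independent regressions.
    """
    p = obs.n_genes
    if not 0 <= gene_index < p:
        raise IndexError(f"gene_index {gene_index} out of range [0, {p})")
    return [(ep.X.T.copy(), ep.Y[gene_index].copy()) for ep in obs.epochs]


def pooled_gene_problem(
    obs: EpochObservations, gene_index: int
) -> tuple[np.ndarray, np.ndarray]:
    """All epochs of one gene's problem stacked into a single static
    regression (design: total samples x p), used for the static network
    estimate and for sparsity-parameter selection."""
    problems = extract_gene_problem(obs, gene_index)
    design = np.vstack([d for d, _ in problems])
    response = np.concatenate([r for _, r in problems])
    return design, response
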