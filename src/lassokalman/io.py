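"""Readers, writers, run configuration and the end-to-end pipeline.

File conventions:

* expression matrices — tab-delimited, first column gene identifiers,
  header row of time labels, genes in rows;
* perturbation signal — two-column TSV (time label, u);
* recovered networks — per epoch a full adjacency TSV plus a thresholded
  signed edge list in SIF form (``source activates|represses target``)
  with a companion edge-attribute file of weights;
* reports and the reproducibility manifest — JSON.

Epochs are 0-based in code and 1-based in file names and reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluate import (
    DEFAULT_ALPHA,
    DEFAULT_PRESENCE_THRESHOLD,
    confusion_metrics,
    edge_error_rate,
)
from .model import (
    ExpressionSeries,
    build_observations,
    uniform_epoch_assignment,
)
from .regularization import static_fit
from .simulate import SimConfig, simulate
from .tracker import NetworkTrajectory, TrackOptions, track_network

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_perturbation_tsv",
    "read_adjacency_tsv",
    "write_network_snapshots",
    "load_config",
    "save_config",
    "run_pipeline",
]


def read_expression_tsv(path: str | Path) -> ExpressionSeries:
    """Read a gene-by-time expression matrix.

    Rejects ragged rows, non-numeric cells (named by row and column) and
    duplicate gene identifiers.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate gene identifier: {dup!r}")
    values = np.empty(df.shape)
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = df.iat[i, j]
            try:
                values[i, j] = float(cell)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric cell at row {i + 2}, column {j + 2}: {cell!r}"
                ) from None
    return ExpressionSeries(
        values=values,
        time_labels=list(df.columns),
        gene_ids=list(df.index),
    )


def write_expression_tsv(series: ExpressionSeries, path: str | Path) -> None:
    ids = series.gene_ids or [f"g{i}" for i in range(series.n_genes)]
    df = pd.DataFrame(series.values, index=ids, columns=series.time_labels)
    df.to_csv(path, sep="\t", index_label="gene", float_format="%.17g")


def read_perturbation_tsv(path: str | Path) -> np.ndarray:
    """Perturbation signal u(t) from a two-column (time, u) TSV."""
    df = pd.read_csv(path, sep="\t", header=0)
    if df.shape[1] != 2:
        raise ValueError("perturbation file must have exactly two columns")
    return df.iloc[:, 1].to_numpy(dtype=float)


def read_adjacency_tsv(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float)


def _gene_names(p: int, gene_ids: list[str] | None) -> list[str]:
    return gene_ids if gene_ids is not None else [f"g{i}" for i in range(p)]


def write_network_snapshots(
    traj: NetworkTrajectory,
    out_dir: str | Path,
    presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD,
    gene_ids: list[str] | None = None,
) -> list[Path]:
    """Per epoch: full adjacency TSV, SIF edge list of the thresholded
    signed network, and an edge-attribute file of the weights."""
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise ValueError(f"cannot create output directory {out_dir}: {exc}") from exc
    names = _gene_names(traj.n_genes, gene_ids)
    written = []
    for k, A in enumerate(traj.matrices, start=1):
        adj = out_dir / f"network_epoch{k:02d}.tsv"
        pd.DataFrame(A, index=names, columns=names).to_csv(
            adj, sep="\t", index_label="gene", float_format="%.17g"
        )
        sif = out_dir / f"network_epoch{k:02d}.sif"
        attrs = out_dir / f"network_epoch{k:02d}_weights.txt"
        with open(sif, "w") as fsif, open(attrs, "w") as fattr:
            fattr.write("weight\n")
            for i in range(traj.n_genes):
                for j in range(traj.n_genes):
                    w = A[i, j]
                    if abs(w) <= presence_threshold:
                        continue
                    tag = "activates" if w > 0 else "represses"
                    # source regulator is gene j, target is gene i
                    fsif.write(f"{names[j]}\t{tag}\t{names[i]}\n")
                    fattr.write(f"{names[j]} ({tag}) {names[i]} = {w:.17g}\n")
        written += [adj, sif, attrs]
    return written


@dataclass
class RunConfig:
    """Configuration of one end-to-end run, serializable to YAML.

    Either ``expression_path`` (real-data mode) or ``simulation`` (a
    mapping of ``SimConfig`` overrides; synthetic mode with known truth)
    must be set.
    """

    expression_path: str | None = None
    perturbation_path: str | None = None
    perturbation_b: list[float] | None = None
    samples_per_epoch: int = 3
    simulation: dict | None = None
    tracking: dict = field(default_factory=dict)
    lambda_: float | None = None  # fixed sparsity weight; None = GCV per gene
    refine_factor: int = 20
    presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD
    alpha: float = DEFAULT_ALPHA
    out_dir: str = "lassokalman_out"
    n_jobs: int = 1
    log_level: str = "INFO"
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.expression_path is None) == (self.simulation is None):
            raise ValueError(
                "exactly one of expression_path or simulation must be set"
            )
        unknown = set(self.tracking) - {
            f.name for f in dataclasses.fields(TrackOptions)
        }
        if unknown:
            raise ValueError(f"unknown tracking keys: {sorted(unknown)}")
        if self.simulation is not None:
            unknown = set(self.simulation) - {
                f.name for f in dataclasses.fields(SimConfig)
            }
            if unknown:
                raise ValueError(f"unknown simulation keys: {sorted(unknown)}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute ingest -> observation build -> initial estimate -> lambda
    selection -> tracking -> evaluation (when truth is known) -> export.

    Returns a summary dict (also written as ``report.json``); a manifest
    with the config hash, seed and library versions makes the run
    reproducible byte-for-byte.
    """
    logging.basicConfig(level=cfg.log_level, stream=sys.stderr)
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    truth = None
    gene_ids = None
    sim_cfg = None
    if cfg.simulation is not None:
        logger.info("stage: simulate")
        sim_kwargs = dict(cfg.simulation)
        sim_kwargs.setdefault("seed", cfg.seed)
        sim_cfg = SimConfig(**sim_kwargs)
        truth, obs = simulate(sim_cfg)
        for k, A in enumerate(truth, start=1):
            pd.DataFrame(A).to_csv(
                out_dir / f"truth_epoch{k:02d}.tsv",
                sep="\t",
                index_label="gene",
                float_format="%.17g",
            )
    else:
        logger.info("stage: ingest")
        path = Path(cfg.expression_path)
        if not path.exists():
            raise FileNotFoundError(f"expression file not found: {path}")
        series = read_expression_tsv(path)
        gene_ids = series.gene_ids
        if cfg.perturbation_path is not None:
            u = read_perturbation_tsv(cfg.perturbation_path)
            b = np.asarray(cfg.perturbation_b, dtype=float)
            series = ExpressionSeries(
                values=series.values,
                time_labels=series.time_labels,
                perturbation_u=u,
                perturbation_b=b,
                gene_ids=series.gene_ids,
            )
        logger.info("stage: observations")
        assignment = uniform_epoch_assignment(
            series.n_samples - 1, cfg.samples_per_epoch
        )
        obs = build_observations(series, assignment)

    logger.info("stage: initial condition and lambda selection")
    if sim_cfg is not None and not cfg.tracking:
        # known-covariance assumption: noise covariances from the generator
        opts = sim_cfg.matched_track_options()
    else:
        opts = TrackOptions(**cfg.tracking)
    fit = static_fit(
        obs, refine_factor=cfg.refine_factor, lambda_override=cfg.lambda_
    )

    logger.info("stage: tracking (%d genes, %d epochs)", obs.n_genes, obs.n_epochs)
    traj = track_network(
        obs,
        opts,
        init=fit.A0,
        lambdas=fit.lambdas,
        p0_scales=fit.p0_scales,
        smooth=True,
        n_jobs=cfg.n_jobs,
    )
    if traj.failures:
        logger.error("stage tracking: %d gene(s) failed", len(traj.failures))

    logger.info("stage: export")
    write_network_snapshots(
        traj, out_dir, presence_threshold=cfg.presence_threshold, gene_ids=gene_ids
    )

    report: dict = {
        "n_genes": obs.n_genes,
        "n_epochs": obs.n_epochs,
        "m_per_epoch": obs.m_per_epoch,
        "lambda_mean": float(np.mean(fit.lambdas)),
        "failures": {str(k): v for k, v in traj.failures.items()},
    }
    if truth is not None:
        logger.info("stage: evaluate")
        cm = confusion_metrics(truth, traj.matrices, cfg.presence_threshold)
        report["confusion"] = dataclasses.asdict(cm)
        report["edge_error_rate"] = float(
            np.mean(
                [
                    edge_error_rate(T, E, cfg.alpha)
                    for T, E in zip(truth, traj.matrices)
                ]
            )
        )

    manifest = {
        "config": cfg.to_dict(),
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "versions": {
            "lassokalman": __version__,
            "numpy": np.__version__,
            "python": sys.version.split()[0],
        },
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
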