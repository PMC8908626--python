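"""Synthetic UMI count matrices with known cluster structure and a planted
signature-positive subpopulation.

Counts follow a gamma-Poisson (negative binomial) law per gene x cell with a
log-normal library size per cell. Each cluster carries its own up-shifted
marker genes; a configurable fraction of cells is "signature positive" and
has the signature genes up-shifted by ``pos_log2fc``. Positives can be spread
uniformly across clusters or concentrated so that one cluster consists
exactly of the positive cells. Mitochondrial genes receive a Dirichlet-
perturbed share of each cell's library around ``mito_fraction_mu`` so that
QC filtering has realistic targets.

Everything is driven by a single integer seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import CountMatrix, read_mtx, write_mtx

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_counts",
    "write_ground_truth",
    "read_ground_truth",
    "read_mtx",
    "write_mtx",
]

SPREAD = "spread"
CONCENTRATED = "concentrated"

# concentration of the Beta draw for per-cell mito fraction; high enough that
# only a small tail of cells exceeds a 10% mito cutoff at mu = 0.05
_MITO_BETA_CONC = 80.0


@dataclass
class SimConfig:
    """Parameters of the synthetic scRNA-seq generator."""

    n_cells: int = 500
    n_genes: int = 1000
    n_clusters: int = 3
    cluster_props: tuple | None = None  # default: uniform
    libsize_mu: float = float(np.log(5000.0))  # log-mean of library size
    libsize_sigma: float = 0.25
    dispersion: float = 2.0  # NB inverse-dispersion (gamma shape)
    n_marker_genes_per_cluster: int = 25
    marker_log2fc: float = 2.0
    signature_genes: int = 30
    pos_fraction: float = 0.3
    pos_log2fc: float = 1.5
    pos_placement: str = SPREAD  # "spread" or "concentrated"
    pos_cluster: int = 0  # target cluster when concentrated
    mito_genes: int = 20
    mito_fraction_mu: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.n_genes < 1 or self.n_clusters < 1:
            raise ValueError("n_cells, n_genes and n_clusters must be positive")
        if self.cluster_props is None:
            self.cluster_props = tuple([1.0 / self.n_clusters] * self.n_clusters)
        props = np.asarray(self.cluster_props, dtype=float)
        if len(props) != self.n_clusters:
            raise ValueError("cluster_props length must equal n_clusters")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("cluster_props must sum to 1 within 1e-9")
        if not 0.0 <= self.pos_fraction <= 1.0:
            raise ValueError("pos_fraction must lie in [0, 1]")
        if self.pos_log2fc <= 0 or self.marker_log2fc <= 0:
            raise ValueError("log2 fold changes must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.signature_genes < 1:
            raise ValueError("signature_genes must be >= 1")
        if self.pos_placement not in (SPREAD, CONCENTRATED):
            raise ValueError(f"unknown pos_placement {self.pos_placement!r}")
        if self.pos_placement == CONCENTRATED and not (
            0 <= self.pos_cluster < self.n_clusters
        ):
            raise ValueError(
                f"pos_cluster {self.pos_cluster} out of range for "
                f"{self.n_clusters} clusters"
            )
        if not 0.0 < self.mito_fraction_mu < 1.0:
            raise ValueError("mito_fraction_mu must lie in (0, 1)")
        special = (
            self.mito_genes
            + self.n_clusters * self.n_marker_genes_per_cluster
            + self.signature_genes
        )
        if special > self.n_genes:
            raise ValueError(
                f"mito + marker + signature genes ({special}) exceed n_genes "
                f"({self.n_genes})"
            )


@dataclass
class GroundTruth:
    """Latent truth accompanying a simulated matrix."""

    cluster: np.ndarray  # per-cell true cluster id
    positive: np.ndarray  # per-cell boolean positivity flag
    gene_role: np.ndarray  # per-gene: "mito" | "marker:<k>" | "signature" | "background"
    cell_ids: np.ndarray = field(default=None)
    gene_ids: np.ndarray = field(default=None)

    @property
    def signature_gene_ids(self) -> list:
        return [g for g, r in zip(self.gene_ids, self.gene_role) if r == "signature"]

    def marker_gene_ids(self, k: int) -> list:
        tag = f"marker:{k}"
        return [g for g, r in zip(self.gene_ids, self.gene_role) if r == tag]


def _gene_layout(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Assign roles and identifiers to gene indices (pairwise disjoint blocks)."""
    roles = np.array(["background"] * config.n_genes, dtype=object)
    i = 0
    roles[i : i + config.mito_genes] = "mito"
    i += config.mito_genes
    for k in range(config.n_clusters):
        roles[i : i + config.n_marker_genes_per_cluster] = f"marker:{k}"
        i += config.n_marker_genes_per_cluster
    roles[i : i + config.signature_genes] = "signature"
    ids = np.array(
        [
            ("MT-" if roles[g] == "mito" else "") + f"G{g + 1:06d}"
            for g in range(config.n_genes)
        ],
        dtype=object,
    )
    return roles, ids


def simulate_counts(config: SimConfig) -> tuple[CountMatrix, GroundTruth]:
    """Draw a genes x cells UMI matrix plus its ground truth.

    Deterministic for a fixed config (identical config + seed give
    bit-identical output). See the module docstring for the generative model.
    """
    rng = np.random.default_rng(config.seed)
    n, g = config.n_cells, config.n_genes
    props = np.asarray(config.cluster_props, dtype=float)

    roles, gene_ids = _gene_layout(config)
    cell_ids = np.array([f"CELL{c + 1:06d}" for c in range(n)], dtype=object)

    n_pos = int(round(config.pos_fraction * n))
    positive = np.zeros(n, dtype=bool)
    pos_idx = rng.choice(n, size=n_pos, replace=False)
    positive[pos_idx] = True

    if config.pos_placement == CONCENTRATED and config.n_clusters > 1:
        # the designated cluster consists exactly of the positive cells;
        # negatives are spread over the remaining clusters
        k = config.pos_cluster
        neg_props = props.copy()
        neg_props[k] = 0.0
        neg_props = neg_props / neg_props.sum()
        cluster = rng.choice(config.n_clusters, size=n, p=neg_props)
        cluster[positive] = k
    else:
        cluster = rng.choice(config.n_clusters, size=n, p=props)

    # per-gene baseline expression weight, shared across cells
    base = rng.lognormal(mean=0.0, sigma=1.0, size=g)

    mito = roles == "mito"
    sig = roles == "signature"
    nonmito = ~mito

    # per-cluster program over non-mito genes
    cluster_w = np.tile(base, (config.n_clusters, 1))
    for k in range(config.n_clusters):
        cluster_w[k, roles == f"marker:{k}"] *= 2.0**config.marker_log2fc
    w = cluster_w[cluster].T  # genes x cells
    w[np.ix_(sig, positive)] *= 2.0**config.pos_log2fc
    w[mito, :] = 0.0
    w /= w.sum(axis=0, keepdims=True)

    libsize = rng.lognormal(mean=config.libsize_mu, sigma=config.libsize_sigma, size=n)

    if config.mito_genes > 0:
        mu = config.mito_fraction_mu
        frac = rng.beta(mu * _MITO_BETA_CONC, (1.0 - mu) * _MITO_BETA_CONC, size=n)
        mito_split = rng.dirichlet(np.ones(config.mito_genes), size=n).T
        p = np.empty((g, n))
        p[nonmito] = w[nonmito] * (1.0 - frac)
        p[mito] = mito_split * frac
    else:
        p = w

    mean = p * libsize  # genes x cells expected counts
    theta = config.dispersion
    lam = rng.gamma(shape=theta, scale=mean / theta)
    counts = rng.poisson(lam).astype(np.int64)

    matrix = CountMatrix(counts, gene_ids, cell_ids)
    truth = GroundTruth(
        cluster=cluster,
        positive=positive,
        gene_role=roles,
        cell_ids=cell_ids,
        gene_ids=gene_ids,
    )
    return matrix, truth


def write_ground_truth(truth: GroundTruth, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "cell_id": truth.cell_ids,
            "cluster": truth.cluster,
            "positive": truth.positive.astype(int),
        }
    ).to_csv(path, sep="\t", index=False)
    return path


def read_ground_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
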