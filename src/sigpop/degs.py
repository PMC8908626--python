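"""Cluster-vs-rest differential expression, dot-plot statistics, and
derivation of a custom population signature from a cluster's DEGs.

Conventions follow the de-facto single-cell marker-finding defaults: genes
are pre-filtered on detection fraction (``min_pct``) and natural-log fold
change (``min_logfc``); the test is a two-sided Wilcoxon rank-sum on
log-normalized values; p-values are Bonferroni-adjusted over the tested
genes. Fold change is ``ln((mean(expm1(in)) + 1) / (mean(expm1(out)) + 1))``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import NormalizedMatrix
from .fea import GeneSignature, PositivityCall
from .preprocess import Clustering
from .stats import rank_sum_test

__all__ = [
    "DEGRecord",
    "DerivedSignature",
    "find_degs",
    "derive_signature",
    "dotplot_stats",
    "compare_pos_neg",
    "degs_frame",
]


@dataclass
class DEGRecord:
    gene: str
    cluster: int
    log_fc: float
    p_value: float
    p_adjusted: float
    pct_in: float
    pct_out: float


@dataclass
class DerivedSignature:
    """A GeneSignature plus how it was derived (for provenance)."""

    signature: GeneSignature
    source_cluster: int
    max_genes: int
    p_cutoff: float
    logfc_cutoff: float

    def provenance(self) -> dict:
        return {
            "source_cluster": self.source_cluster,
            "max_genes": self.max_genes,
            "p_cutoff": self.p_cutoff,
            "logfc_cutoff": self.logfc_cutoff,
            "n_genes": len(self.signature),
            "log_fc_scale": "natural log",
        }

    def write(self, gmt_path: str | Path) -> None:
        from .fea import write_gmt

        write_gmt([self.signature], gmt_path)
        sidecar = Path(gmt_path).with_suffix(".provenance.json")
        sidecar.write_text(json.dumps(self.provenance(), indent=2))


def _group_stats(values: np.ndarray, in_mask: np.ndarray) -> tuple:
    """(log_fc, pct_in, pct_out) per gene, vectorized over rows."""
    in_vals = values[:, in_mask]
    out_vals = values[:, ~in_mask]
    pct_in = (in_vals > 0).mean(axis=1)
    pct_out = (out_vals > 0).mean(axis=1)
    log_fc = np.log(
        (np.expm1(in_vals).mean(axis=1) + 1.0) / (np.expm1(out_vals).mean(axis=1) + 1.0)
    )
    return log_fc, pct_in, pct_out


def find_degs(
    norm: NormalizedMatrix,
    clustering: Clustering,
    cluster_k: int,
    min_pct: float = 0.1,
    min_logfc: float = 0.25,
) -> list[DEGRecord]:
    """Cluster-vs-rest DEGs by Wilcoxon rank-sum on log-normalized values.

    Records are sorted by adjusted p, then |log_fc| descending, then gene id.
    """
    in_mask = clustering.labels == cluster_k
    if in_mask.sum() < 3 or (~in_mask).sum() < 3:
        raise ValueError("cluster and complement must each contain >= 3 cells")
    log_fc, pct_in, pct_out = _group_stats(norm.values, in_mask)
    testable = (np.maximum(pct_in, pct_out) >= min_pct) & (np.abs(log_fc) >= min_logfc)
    idx = np.nonzero(testable)[0]
    if len(idx) == 0:
        raise ValueError("no genes pass the detection/fold-change pre-filters")
    # Bonferroni over all genes in the matrix, not just those surviving the
    # pre-filters: the fold-change filter selects for small p, so adjusting
    # over the survivors alone would not control the family-wise error rate.
    n_tested = norm.n_genes
    records = []
    for i in idx:
        row = norm.values[i]
        _, p = rank_sum_test(row[in_mask], row[~in_mask])
        records.append(
            DEGRecord(
                gene=str(norm.gene_ids[i]),
                cluster=cluster_k,
                log_fc=float(log_fc[i]),
                p_value=p,
                p_adjusted=min(1.0, p * n_tested),
                pct_in=float(pct_in[i]),
                pct_out=float(pct_out[i]),
            )
        )
    records.sort(key=lambda r: (r.p_adjusted, -abs(r.log_fc), r.gene))
    return records


def derive_signature(
    degs: list[DEGRecord],
    max_genes: int = 50,
    p_cutoff: float = 0.05,
    logfc_cutoff: float = 0.25,
) -> DerivedSignature:
    """Top up-regulated DEGs as a custom population signature.

    Members must have positive log fold change above ``logfc_cutoff`` and
    adjusted p below ``p_cutoff``; the ``find_degs`` sort order (with the
    gene-id tiebreak) makes the derivation deterministic.
    """
    if max_genes < 1:
        raise ValueError("max_genes must be >= 1")
    passing = [
        r for r in degs if r.log_fc > logfc_cutoff and r.p_adjusted < p_cutoff
    ]
    if not passing:
        raise ValueError("no up-regulated DEG passes the cutoffs")
    chosen = passing[:max_genes]
    cluster = chosen[0].cluster
    sig = GeneSignature(
        name=f"cluster{cluster}_population_signature",
        genes=frozenset(r.gene for r in chosen),
        source="derived",
    )
    return DerivedSignature(sig, cluster, max_genes, p_cutoff, logfc_cutoff)


def dotplot_stats(
    norm: NormalizedMatrix, clustering: Clustering, genes: list[str]
) -> pd.DataFrame:
    """Per (gene, cluster) mean log-normalized expression and fraction of
    expressing (count > 0) cells."""
    index = {g: i for i, g in enumerate(norm.gene_ids)}
    unknown = [g for g in genes if g not in index]
    if unknown:
        raise KeyError(f"genes not in matrix: {unknown}")
    rows = []
    for gname in genes:
        vals = norm.values[index[gname]]
        for k in range(clustering.n_clusters):
            in_k = clustering.labels == k
            v = vals[in_k]
            rows.append(
                {
                    "gene": gname,
                    "cluster": k,
                    "mean_expression": float(v.mean()),
                    "pct_expressing": float((v > 0).mean()),
                }
            )
    return pd.DataFrame(rows)


def compare_pos_neg(
    norm: NormalizedMatrix, call: PositivityCall, genes: list[str]
) -> pd.DataFrame:
    """Positive-vs-negative expression comparison for the listed genes.

    Same statistics as :func:`find_degs` (Wilcoxon, expm1-mean log fold
    change) but grouped by the positivity call instead of a cluster label.
    """
    pos = np.asarray(call.positive, dtype=bool)
    if not pos.any() or pos.all():
        raise ValueError("both positive and negative classes must be non-empty")
    index = {g: i for i, g in enumerate(norm.gene_ids)}
    unknown = [g for g in genes if g not in index]
    if unknown:
        raise KeyError(f"genes not in matrix: {unknown}")
    rows = []
    for gname in genes:
        vals = norm.values[index[gname]]
        mean_pos = float(vals[pos].mean())
        mean_neg = float(vals[~pos].mean())
        log_fc = float(
            np.log((np.expm1(vals[pos]).mean() + 1.0) / (np.expm1(vals[~pos]).mean() + 1.0))
        )
        _, p = rank_sum_test(vals[pos], vals[~pos])
        rows.append(
            {
                "gene": gname,
                "mean_pos": mean_pos,
                "mean_neg": mean_neg,
                "log_fc": log_fc,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def degs_frame(records: list[DEGRecord]) -> pd.DataFrame:
    """DEG records as a table (log_fc column is natural log)."""
    return pd.DataFrame([r.__dict__ for r in records])
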