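"""Functional enrichment analysis: per-cell signature scores, one-vs-rest
cluster AUC enrichment, positivity calls and cross-condition abundance shifts.

A cell's signature score is the mean of its gene-wise standardized expression
over the signature genes (sum available via ``method="sum"``). A cluster is
called enriched for a signature when its one-vs-rest AUC exceeds
``auc_threshold`` (default 0.7) and the two-sided Wilcoxon rank-sum p-value
is below ``p_threshold`` (default 0.01). Positivity is a strict score > 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data import ScaledMatrix
from .preprocess import Clustering
from .stats import auc_from_labels, rank_sum_test

__all__ = [
    "GeneSignature",
    "ScoreVector",
    "EnrichmentResult",
    "PositivityCall",
    "read_gmt",
    "write_gmt",
    "read_gene_list",
    "score_cells",
    "cluster_auc",
    "cluster_enrichment",
    "classify_cells",
    "abundance_shift",
]

logger = logging.getLogger(__name__)

AUC_THRESHOLD = 0.7
P_THRESHOLD = 0.01


@dataclass
class GeneSignature:
    """A named, order-irrelevant set of gene identifiers."""

    name: str
    genes: frozenset
    source: str = "custom"

    def __post_init__(self) -> None:
        self.genes = frozenset(self.genes)
        if not self.genes:
            raise ValueError(f"signature {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class ScoreVector:
    """Per-cell signature scores plus the matched/missing gene bookkeeping."""

    signature: str
    scores: np.ndarray
    cell_ids: np.ndarray
    matched_genes: list
    missing_genes: list


@dataclass
class EnrichmentResult:
    signature: str
    cluster: int
    auc: float
    p_value: float
    enriched: bool
    p_bh: float | None = None  # informational only; the rule uses the raw p


@dataclass
class PositivityCall:
    signature: str
    positive: np.ndarray
    cell_ids: np.ndarray
    threshold: float = 0.0

    @property
    def positive_fraction(self) -> float:
        return float(self.positive.mean())


def read_gmt(path: str | Path) -> list[GeneSignature]:
    """Parse a GMT file: ``name <tab> description <tab> gene...`` per line."""
    sigs = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                if line.strip():
                    raise ValueError(f"malformed GMT line: {line!r}")
                continue
            name, source = parts[0], parts[1] or "custom"
            genes = [g for g in parts[2:] if g]
            sigs.append(GeneSignature(name, frozenset(genes), source))
    return sigs


def write_gmt(signatures: list[GeneSignature], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for sig in signatures:
            genes = "\t".join(sorted(sig.genes))
            fh.write(f"{sig.name}\t{sig.source}\t{genes}\n")
    return path


def read_gene_list(path: str | Path, name: str | None = None) -> GeneSignature:
    """One gene identifier per line."""
    path = Path(path)
    genes = [line.strip() for line in open(path) if line.strip()]
    return GeneSignature(name or path.stem, frozenset(genes), source="list")


def score_cells(
    scaled: ScaledMatrix, signature: GeneSignature, method: str = "mean"
) -> ScoreVector:
    """Per-cell signature score over the gene-wise standardized matrix.

    Missing signature genes are dropped with a logged warning; an error is
    raised only when no signature gene is present in the matrix.
    """
    if method not in ("mean", "sum"):
        raise ValueError(f"unknown scoring method {method!r}")
    index = {g: i for i, g in enumerate(scaled.gene_ids)}
    matched = sorted(g for g in signature.genes if g in index)
    missing = sorted(g for g in signature.genes if g not in index)
    if not matched:
        raise ValueError(
            f"signature {signature.name!r}: none of its {len(signature)} genes "
            "are present in the matrix"
        )
    if missing:
        logger.warning(
            "signature %r: %d of %d genes missing from the matrix",
            signature.name,
            len(missing),
            len(signature),
        )
    rows = scaled.values[[index[g] for g in matched]]
    scores = rows.mean(axis=0) if method == "mean" else rows.sum(axis=0)
    return ScoreVector(signature.name, scores, scaled.cell_ids, matched, missing)


def cluster_auc(scores: ScoreVector, clustering: Clustering, cluster_k: int) -> float:
    """One-vs-rest AUC of the signature score for cluster ``cluster_k``."""
    in_mask = clustering.labels == cluster_k
    if not in_mask.any() or in_mask.all():
        raise ValueError(f"cluster {cluster_k} is empty or contains every cell")
    return auc_from_labels(scores.scores, in_mask)


def cluster_enrichment(
    scores: ScoreVector,
    clustering: Clustering,
    auc_threshold: float = AUC_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
) -> list[EnrichmentResult]:
    """One-vs-rest AUC + Wilcoxon for every cluster; the enrichment call is
    ``auc > auc_threshold AND p < p_threshold`` on the raw p-value.

    A Benjamini-Hochberg column across clusters is attached for information
    only.
    """
    if clustering.n_clusters < 2:
        raise ValueError("cluster_enrichment requires at least 2 clusters")
    results = []
    for k in range(clustering.n_clusters):
        in_mask = clustering.labels == k
        auc = cluster_auc(scores, clustering, k)
        _, p = rank_sum_test(scores.scores[in_mask], scores.scores[~in_mask])
        results.append(
            EnrichmentResult(
                signature=scores.signature,
                cluster=k,
                auc=auc,
                p_value=p,
                enriched=bool(auc > auc_threshold and p < p_threshold),
            )
        )
    # BH over the cluster family
    ps = np.array([r.p_value for r in results])
    order = np.argsort(ps)
    m = len(ps)
    bh = np.empty(m)
    running = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, ps[i] * m / (rank_idx + 1))
        bh[i] = running
    for r, q in zip(results, bh):
        r.p_bh = float(q)
    return results


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "signature": [r.signature for r in results],
            "cluster": [r.cluster for r in results],
            "auc": [r.auc for r in results],
            "p": [r.p_value for r in results],
            "p_bh": [r.p_bh for r in results],
            "enriched": [r.enriched for r in results],
        }
    )


def classify_cells(scores: ScoreVector, threshold: float = 0.0) -> PositivityCall:
    """Positive iff score strictly exceeds the threshold (default 0)."""
    if not np.all(np.isfinite(scores.scores)):
        raise ValueError("scores must be finite")
    return PositivityCall(
        signature=scores.signature,
        positive=scores.scores > threshold,
        cell_ids=scores.cell_ids,
        threshold=threshold,
    )


def abundance_shift(
    clustering: Clustering, condition: np.ndarray | pd.Series
) -> pd.DataFrame:
    """Per-cluster abundance change between two conditions.

    For each cluster k: ``prop_X = n_{k,X} / n_X`` and
    ``percent_change = 100 * (prop_B - prop_A) / prop_A`` where A and B are
    the two condition labels in sorted order; p comes from a two-proportion
    chi-squared on the 2x2 cluster-membership x condition table with Yates
    correction. A cluster absent from condition A yields an undefined
    (NaN) percent change; the p-value is still reported.
    """
    condition = np.asarray(condition)
    levels = sorted(set(condition))
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 condition labels, got {levels}")
    a, b = levels
    mask_a = condition == a
    mask_b = condition == b
    n_a, n_b = int(mask_a.sum()), int(mask_b.sum())
    rows = []
    for k in range(clustering.n_clusters):
        in_k = clustering.labels == k
        ka = int((in_k & mask_a).sum())
        kb = int((in_k & mask_b).sum())
        prop_a = ka / n_a
        prop_b = kb / n_b
        pct = 100.0 * (prop_b - prop_a) / prop_a if prop_a > 0 else np.nan
        table = np.array([[ka, n_a - ka], [kb, n_b - kb]])
        if table.sum(axis=0).min() == 0:  # cluster empty in both conditions
            chi2, p = np.nan, np.nan
        else:
            chi2, p, _, _ = sps.chi2_contingency(table, correction=True)
        rows.append(
            {
                "cluster": k,
                f"n_{a}": ka,
                f"n_{b}": kb,
                f"prop_{a}": prop_a,
                f"prop_{b}": prop_b,
                "percent_change": pct,
                "chi2": chi2,
                "p": p,
            }
        )
    return pd.DataFrame(rows)
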