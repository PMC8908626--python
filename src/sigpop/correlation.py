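"""Signature-signature Pearson correlation, overall and per cluster, with
the moderate/strong banding convention.

Bands apply to positive coefficients: r in [0.3, 0.5] is "moderate",
r in (0.5, 0.9] is "strong", non-negative r below 0.3 is "negligible", and
anything else (negative r, or r > 0.9) is "out_of_band". The raw coefficient
is always reported alongside the band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .fea import ScoreVector
from .preprocess import Clustering

__all__ = ["CorrelationResult", "correlate_signatures", "correlation_frame", "band_of"]


@dataclass
class CorrelationResult:
    signature_a: str
    signature_b: str
    cluster: object  # int cluster id or "all"
    n: int
    r: float
    p_value: float
    band: str


def band_of(r: float) -> str:
    if np.isnan(r):
        return "undefined"
    if r < 0 or r > 0.9:
        return "out_of_band"
    if r > 0.5:
        return "strong"
    if r >= 0.3:
        return "moderate"
    return "negligible"


def _pearson(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Pearson r with a two-sided p from the t transform on n-2 df."""
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan, np.nan
    r = float(np.corrcoef(a, b)[0, 1])
    n = len(a)
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return r, float(min(p, 1.0))


def correlate_signatures(
    scores_a: ScoreVector,
    scores_b: ScoreVector,
    clustering: Clustering | None = None,
    min_cells: int = 3,
) -> list[CorrelationResult]:
    """Pearson correlation of two score vectors, overall and per cluster.

    Vectors must cover the same cells in the same order. Clusters with fewer
    than ``min_cells`` cells are skipped; zero variance within a cluster
    yields an undefined (NaN) coefficient for that cluster.
    """
    if not np.array_equal(scores_a.cell_ids, scores_b.cell_ids):
        raise ValueError("score vectors must cover the same cells in the same order")
    a = np.asarray(scores_a.scores, dtype=float)
    b = np.asarray(scores_b.scores, dtype=float)
    results = []
    r, p = _pearson(a, b)
    results.append(
        CorrelationResult(
            scores_a.signature, scores_b.signature, "all", len(a), r, p, band_of(r)
        )
    )
    if clustering is not None:
        if len(clustering.labels) != len(a):
            raise ValueError("clustering does not cover the scored cells")
        for k in range(clustering.n_clusters):
            mask = clustering.labels == k
            if mask.sum() < min_cells:
                continue
            r, p = _pearson(a[mask], b[mask])
            results.append(
                CorrelationResult(
                    scores_a.signature,
                    scores_b.signature,
                    k,
                    int(mask.sum()),
                    r,
                    p,
                    band_of(r),
                )
            )
    return results


def correlation_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sig_a": [r.signature_a for r in results],
            "sig_b": [r.signature_b for r in results],
            "cluster": [r.cluster for r in results],
            "n": [r.n for r in results],
            "r": [r.r for r in results],
            "p": [r.p_value for r in results],
            "band": [r.band for r in results],
        }
    )
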