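"""QC filtering, normalization, scaling, PCA component selection and
clustering — a from-first-principles re-implementation of the standard
single-cell recipe.

Conventions fixed here and relied on downstream:

* sample standard deviation (ddof=1) everywhere;
* log-normalization is ``ln(1 + count * scale_factor / cell_total)``;
* gene-wise scaling drops zero-variance genes and clips at ``+/- clip``;
* principal components are kept when their variance-explained beats a null
  built by independently permuting every gene row (floor of 2 components);
* UMAP is visualization-only — nothing downstream may consume it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .data import CountMatrix, NormalizedMatrix, ScaledMatrix

__all__ = [
    "QCThresholds",
    "QCReport",
    "Embedding",
    "Clustering",
    "qc_filter",
    "log_normalize",
    "scale_genes",
    "regress_out_mito",
    "pca_select",
    "cluster_cells",
    "umap_embed",
    "run_preprocess",
    "PreprocessResult",
]


@dataclass
class QCThresholds:
    """Cell-level QC cutoffs.

    ``max_counts_quantile`` is the doublet stand-in: cells whose totals exceed
    that quantile of the input totals are removed. It is off (``None``) by
    default so that the three-rule filter is idempotent.
    """

    min_barcode_counts: int = 500
    min_genes_per_cell: int = 2000
    max_mito_fraction: float = 0.10
    max_counts_quantile: float | None = None

    def __post_init__(self) -> None:
        if self.min_barcode_counts < 0 or self.min_genes_per_cell < 0:
            raise ValueError("QC thresholds must be non-negative")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction must lie in [0, 1]")
        if self.max_counts_quantile is not None and not (
            0.0 < self.max_counts_quantile <= 1.0
        ):
            raise ValueError("max_counts_quantile must lie in (0, 1]")


@dataclass
class QCReport:
    n_input: int
    n_retained: int
    removed_low_counts: int
    removed_low_genes: int
    removed_high_mito: int
    removed_doublet_proxy: int
    thresholds: QCThresholds

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["thresholds"] = self.thresholds.__dict__.copy()
        return d


@dataclass
class Embedding:
    """Cells x d principal-component scores (plus optional 2-D UMAP)."""

    scores: np.ndarray
    selected_components: list
    cell_ids: np.ndarray
    explained_variance_ratio: np.ndarray | None = None
    component_p_values: np.ndarray | None = None
    umap: np.ndarray | None = None

    @property
    def n_cells(self) -> int:
        return self.scores.shape[0]


@dataclass
class Clustering:
    labels: np.ndarray
    cell_ids: np.ndarray
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        uniq = np.unique(labels)
        if not np.array_equal(uniq, np.arange(len(uniq))):
            raise ValueError("cluster labels must be contiguous from 0")
        self.labels = labels

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0


def qc_filter(
    counts: CountMatrix, thresholds: QCThresholds | None = None
) -> tuple[CountMatrix, QCReport]:
    """Apply the cell-level QC rules; genes are never removed.

    A cell is retained when total counts > ``min_barcode_counts`` AND detected
    genes >= ``min_genes_per_cell`` AND mito fraction <= ``max_mito_fraction``
    (AND, if enabled, totals <= the ``max_counts_quantile`` quantile).
    Raises ``ValueError`` naming the binding filter if no cell survives.
    """
    if thresholds is None:
        thresholds = QCThresholds()
    totals = counts.total_counts()
    detected = counts.detected_genes()
    mito = counts.mito_fraction()

    pass_counts = totals > thresholds.min_barcode_counts
    pass_genes = detected >= thresholds.min_genes_per_cell
    pass_mito = mito <= thresholds.max_mito_fraction
    keep = pass_counts & pass_genes & pass_mito
    removed_doublet = 0
    if thresholds.max_counts_quantile is not None:
        cutoff = np.quantile(totals, thresholds.max_counts_quantile)
        pass_doublet = totals <= cutoff
        removed_doublet = int((keep & ~pass_doublet).sum())
        keep &= pass_doublet

    report = QCReport(
        n_input=counts.n_cells,
        n_retained=int(keep.sum()),
        removed_low_counts=int((~pass_counts).sum()),
        removed_low_genes=int((~pass_genes).sum()),
        removed_high_mito=int((~pass_mito).sum()),
        removed_doublet_proxy=removed_doublet,
        thresholds=thresholds,
    )
    if report.n_retained == 0:
        fails = {
            "min_barcode_counts": int((~pass_counts).sum()),
            "min_genes_per_cell": int((~pass_genes).sum()),
            "max_mito_fraction": int((~pass_mito).sum()),
        }
        binding = max(fails, key=fails.get)
        raise ValueError(
            f"empty after QC: no cell passed all filters "
            f"(most binding filter: {binding}, failed by {fails[binding]} cells)"
        )
    return counts.subset_cells(keep), report


def log_normalize(counts: CountMatrix, scale_factor: float = 10_000.0) -> NormalizedMatrix:
    """LogNormalize: ``ln(1 + count * scale_factor / cell_total)``."""
    totals = counts.total_counts().astype(float)
    if np.any(totals <= 0):
        raise ValueError("log_normalize requires every cell to have total count > 0")
    values = np.log1p(counts.counts * (scale_factor / totals)[np.newaxis, :])
    return NormalizedMatrix(values, counts.gene_ids, counts.cell_ids, scale_factor)


def scale_genes(norm: NormalizedMatrix, clip: float = 10.0) -> ScaledMatrix:
    """Gene-wise standardization (mean 0, sample sd 1), clipping at +/- clip.

    Genes with zero variance across cells are dropped and reported.
    """
    if norm.n_cells < 2:
        raise ValueError("scale_genes requires at least 2 cells")
    means = norm.values.mean(axis=1, keepdims=True)
    sds = norm.values.std(axis=1, ddof=1, keepdims=True)
    keep = sds[:, 0] > 0
    dropped = [g for g, k in zip(norm.gene_ids, keep) if not k]
    vals = (norm.values[keep] - means[keep]) / sds[keep]
    vals = np.clip(vals, -clip, clip)
    return ScaledMatrix(
        vals, np.asarray(norm.gene_ids)[keep], norm.cell_ids, dropped, clip
    )


def regress_out_mito(scaled: ScaledMatrix, mito_fraction: np.ndarray) -> ScaledMatrix:
    """Residualize each gene row on per-cell mito fraction by OLS.

    Optional simplification of the mitochondrial-covariate regression; off by
    default in :func:`run_preprocess`.
    """
    x = np.asarray(mito_fraction, dtype=float)
    if len(x) != scaled.n_cells:
        raise ValueError("mito_fraction length must equal the number of cells")
    xc = x - x.mean()
    denom = (xc**2).sum()
    if denom == 0:
        return scaled
    beta = scaled.values @ xc / denom  # per-gene slope
    vals = scaled.values - np.outer(beta, xc)
    return ScaledMatrix(vals, scaled.gene_ids, scaled.cell_ids, scaled.dropped_genes, scaled.clip)


def pca_select(
    scaled: ScaledMatrix,
    n_components: int = 20,
    n_permutations: int = 30,
    alpha: float = 0.05,
    seed: int = 0,
) -> Embedding:
    """PCA with permutation-based component selection.

    The null permutes each gene row independently ``n_permutations`` times
    and compares each component's variance-explained against the permuted
    values at the same rank; components with empirical p < ``alpha`` are kept,
    with a floor of 2 components.
    """
    if n_permutations < 20:
        raise ValueError("n_permutations must be >= 20 for a usable null")
    n_components = min(n_components, min(scaled.n_genes, scaled.n_cells) - 1)
    if n_components < 1:
        raise ValueError("not enough genes/cells for PCA")
    x = scaled.values.T  # cells x genes
    pca = PCA(n_components=n_components, random_state=seed)
    obs_scores = pca.fit_transform(x)
    obs_evr = pca.explained_variance_ratio_

    rng = np.random.default_rng(seed)
    exceed = np.zeros(n_components)
    null_pca = PCA(n_components=n_components, random_state=seed)
    for _ in range(n_permutations):
        perm = rng.permuted(scaled.values, axis=1).T
        null_pca.fit(perm)
        exceed += null_pca.explained_variance_ratio_ >= obs_evr
    p = (1.0 + exceed) / (1.0 + n_permutations)

    selected = [i for i in range(n_components) if p[i] < alpha]
    if len(selected) < 2:  # floor rule
        selected = [0, 1] if n_components >= 2 else [0]
    return Embedding(
        scores=obs_scores[:, selected],
        selected_components=selected,
        cell_ids=scaled.cell_ids,
        explained_variance_ratio=obs_evr,
        component_p_values=p,
    )


def _leiden_labels(
    scores: np.ndarray, n_neighbors: int, resolution: float, seed: int
) -> np.ndarray:
    import igraph
    import leidenalg

    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(scores)
    _, idx = nn.kneighbors(scores)
    edges = set()
    for i, row in enumerate(idx):
        for j in row[1:]:  # skip self
            edges.add((min(i, int(j)), max(i, int(j))))
    graph = igraph.Graph(n=scores.shape[0], edges=sorted(edges))
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
    )
    return np.asarray(part.membership)


def cluster_cells(
    embedding: Embedding,
    method: str = "leiden",
    n_neighbors: int = 15,
    resolution: float = 1.0,
    n_clusters: int | None = None,
    seed: int = 0,
) -> Clustering:
    """Cluster cells in PC space.

    ``method`` is ``"leiden"`` (KNN graph + Leiden community detection) or
    ``"kmeans"`` (requires ``n_clusters``). Labels are relabeled to be
    contiguous from 0 in decreasing cluster-size order; deterministic given
    the seed.
    """
    n = embedding.n_cells
    if n == 0:
        raise ValueError("empty embedding")
    if method == "leiden":
        if n_neighbors >= n:
            raise ValueError(f"n_neighbors={n_neighbors} >= n_cells={n}")
        raw = _leiden_labels(embedding.scores, n_neighbors, resolution, seed)
        params = {"method": "leiden", "n_neighbors": n_neighbors, "resolution": resolution, "seed": seed}
    elif method == "kmeans":
        if n_clusters is None:
            raise ValueError("kmeans requires n_clusters")
        if n_clusters > n:
            raise ValueError("more clusters than cells")
        km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
        raw = km.fit_predict(embedding.scores)
        params = {"method": "kmeans", "n_clusters": n_clusters, "seed": seed}
    else:
        raise ValueError(f"unknown clustering method {method!r}")

    # relabel by decreasing size, ties broken by original label
    uniq, counts = np.unique(raw, return_counts=True)
    order = uniq[np.lexsort((uniq, -counts))]
    remap = {int(old): new for new, old in enumerate(order)}
    labels = np.array([remap[int(l)] for l in raw])
    return Clustering(labels=labels, cell_ids=embedding.cell_ids, params=params)


def umap_embed(embedding: Embedding, seed: int = 0, **kwargs) -> Embedding:
    """Attach 2-D UMAP coordinates for visualization only."""
    if embedding.n_cells < 10:
        raise ValueError("umap_embed requires at least 10 cells")
    import umap  # deferred: heavy numba import

    reducer = umap.UMAP(n_components=2, random_state=seed, **kwargs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coords = reducer.fit_transform(embedding.scores)
    return Embedding(
        scores=embedding.scores,
        selected_components=embedding.selected_components,
        cell_ids=embedding.cell_ids,
        explained_variance_ratio=embedding.explained_variance_ratio,
        component_p_values=embedding.component_p_values,
        umap=np.asarray(coords),
    )


@dataclass
class PreprocessResult:
    counts: CountMatrix
    qc_report: QCReport
    normalized: NormalizedMatrix
    scaled: ScaledMatrix
    embedding: Embedding
    clustering: Clustering


def run_preprocess(
    counts: CountMatrix,
    thresholds: QCThresholds | None = None,
    scale_factor: float = 10_000.0,
    clip: float = 10.0,
    n_components: int = 20,
    select_components: bool = False,
    n_permutations: int = 30,
    regress_mito: bool = False,
    cluster_method: str = "leiden",
    n_neighbors: int = 15,
    resolution: float = 1.0,
    n_clusters: int | None = None,
    seed: int = 0,
    compute_umap: bool = False,
) -> PreprocessResult:
    """QC -> log-normalize -> scale -> PCA -> cluster, in one call.

    ``select_components=False`` keeps all ``n_components`` PCs (skipping the
    permutation null, which dominates runtime on large matrices).
    """
    filtered, report = qc_filter(counts, thresholds)
    norm = log_normalize(filtered, scale_factor)
    scaled = scale_genes(norm, clip)
    if regress_mito:
        scaled = regress_out_mito(scaled, filtered.mito_fraction())
    if select_components:
        emb = pca_select(scaled, n_components, n_permutations, seed=seed)
    else:
        k = min(n_components, min(scaled.n_genes, scaled.n_cells) - 1)
        pca = PCA(n_components=k, random_state=seed)
        scores = pca.fit_transform(scaled.values.T)
        emb = Embedding(
            scores=scores,
            selected_components=list(range(k)),
            cell_ids=scaled.cell_ids,
            explained_variance_ratio=pca.explained_variance_ratio_,
        )
    clustering = cluster_cells(
        emb,
        method=cluster_method,
        n_neighbors=n_neighbors,
        resolution=resolution,
        n_clusters=n_clusters,
        seed=seed,
    )
    if compute_umap:
        emb = umap_embed(emb, seed=seed)
    return PreprocessResult(filtered, report, norm, scaled, emb, clustering)
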