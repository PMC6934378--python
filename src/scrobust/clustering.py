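"""KNN-graph community detection with permutation-calibrated resolution.

Clustering follows the Phenograph recipe: exact k-nearest neighbors on the
selected principal components, edges weighted by the Jaccard overlap of the
two endpoints' (self-inclusive) neighbor sets, and Louvain community
detection maximizing weighted Newman–Girvan modularity.

The KNN parameter k controls the resolution. To pick it, the observed
modularity O_k is compared with the mean modularity S_k of the same analysis
run on expression matrices whose values were permuted *within each cell*
(preserving each cell's coverage profile while destroying gene structure).
The chosen resolution is the highest-resolution k — the one yielding the
most clusters — among those with O_k / S_k at or above a ratio threshold
(default 2); if none qualifies the scan reports no structure.

After clustering, B-cell contaminants (CD79+ cells) are purged two ways:
whole clusters whose marker detection rate is high, and individual outlier
cells scoring extremely on principal components driven by marker genes; the
caller then repeats the entire processing so contaminant-driven variable
genes and components do not mask small populations of interest.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from typing import Sequence

import igraph
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from .io_qc import NormalizedMatrix
from .reduction import PCAResult, run_pca, select_significant_pcs, select_variable_genes

logger = logging.getLogger("scrobust")


@dataclass
class ClusteringResult:
    """Per-cell labels plus the parameters and graph that produced them."""

    labels: np.ndarray  # contiguous ints from 0
    k: int
    modularity: float
    seed: int
    n_nodes: int
    n_edges: int
    barcodes: list[str] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    def to_series(self) -> pd.Series:
        return pd.Series(self.labels, index=pd.Index(self.barcodes, name="barcode"),
                         name="cluster")


@dataclass
class ResolutionScan:
    """Observed vs shuffled-null modularity over a grid of k values."""

    table: pd.DataFrame  # k, observed, null_mean, ratio, n_clusters
    null_samples: dict[int, np.ndarray]
    ratio_threshold: float
    n_shuffles: int
    chosen_k: int | None
    chosen: ClusteringResult | None

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


# ---------------------------------------------------------------------------
# Graph construction and community detection
# ---------------------------------------------------------------------------

def build_knn_graph(scores: np.ndarray, k: int) -> igraph.Graph:
    """Jaccard-weighted exact KNN graph on component scores.

    Each node's neighbor set is itself plus its k nearest neighbors
    (Euclidean); an undirected edge i–j (for j among i's neighbors) is
    weighted by the Jaccard overlap of the two sets, and zero-weight edges
    are dropped. Two nodes that are mutual neighbors and share all other
    neighbors therefore get weight 1.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    n = scores.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(scores)
    _, nbr = nn.kneighbors(scores)  # first column is the point itself

    rows = np.repeat(np.arange(n), k + 1)
    cols = nbr.ravel()
    sets = sp.csr_matrix(
        (np.ones(rows.size), (rows, cols)), shape=(n, n), dtype=np.int32
    )
    sets.data[:] = 1  # in case self appeared twice via exact ties

    # candidate edges: i — each of its k neighbors, deduplicated as i<j pairs
    di = np.repeat(np.arange(n), k)
    dj = nbr[:, 1:].ravel()
    a = np.minimum(di, dj)
    b = np.maximum(di, dj)
    key = np.unique(a.astype(np.int64) * n + b)
    ra, ca = key // n, key % n

    counts = (sets @ sets.T).tocsr()
    inter = np.asarray(counts[ra, ca]).ravel().astype(float)
    sizes = np.asarray(sets.sum(axis=1)).ravel()
    union = sizes[ra] + sizes[ca] - inter
    weights = inter / union

    keep = weights > 0
    edges = list(zip(ra[keep].tolist(), ca[keep].tolist()))
    g = igraph.Graph(n=n, edges=edges, directed=False)
    g.es["weight"] = list(weights[keep])
    return g


def graph_modularity(graph: igraph.Graph, labels: Sequence[int]) -> float:
    """Weighted Newman–Girvan modularity of a partition (0 for edgeless graphs)."""
    if graph.ecount() == 0:
        return 0.0
    return float(graph.modularity(list(labels), weights=graph.es["weight"]))


def louvain_cluster(graph: igraph.Graph, seed: int = 0) -> ClusteringResult:
    """Seeded Louvain (multilevel) community detection on a weighted graph.

    The reported modularity is the weighted modularity of the returned
    partition. An edgeless graph yields singleton communities with
    modularity 0.
    """
    n = graph.vcount()
    if n == 0:
        raise ValueError("empty graph")
    if graph.ecount() == 0:
        labels = np.arange(n)
        return ClusteringResult(labels, k=0, modularity=0.0, seed=seed,
                                n_nodes=n, n_edges=0)
    igraph.set_random_number_generator(random.Random(seed))
    part = graph.community_multilevel(weights=graph.es["weight"])
    labels = _contiguous(np.asarray(part.membership))
    mod = graph_modularity(graph, labels)
    return ClusteringResult(labels, k=0, modularity=mod, seed=seed,
                            n_nodes=n, n_edges=graph.ecount())


def leiden_cluster(graph: igraph.Graph, seed: int = 0) -> ClusteringResult:
    """Leiden alternative to :func:`louvain_cluster` (modularity objective)."""
    import leidenalg

    n = graph.vcount()
    if graph.ecount() == 0:
        return ClusteringResult(np.arange(n), k=0, modularity=0.0, seed=seed,
                                n_nodes=n, n_edges=0)
    part = leidenalg.find_partition(
        graph, leidenalg.ModularityVertexPartition,
        weights=graph.es["weight"], seed=seed,
    )
    labels = _contiguous(np.asarray(part.membership))
    return ClusteringResult(labels, k=0, modularity=graph_modularity(graph, labels),
                            seed=seed, n_nodes=n, n_edges=graph.ecount())


def _contiguous(labels: np.ndarray) -> np.ndarray:
    _, out = np.unique(labels, return_inverse=True)
    return out


# ---------------------------------------------------------------------------
# Within-cell shuffling and resolution selection
# ---------------------------------------------------------------------------

def shuffle_within_cells(matrix: NormalizedMatrix, seed: int = 0) -> NormalizedMatrix:
    """Permute every cell's values independently across genes.

    Each cell's multiset of values (hence its coverage profile) is exactly
    preserved; gene identity within the cell is destroyed.
    """
    rng = np.random.default_rng(seed)
    n_genes = matrix.n_genes
    if sp.issparse(matrix.X):
        X = matrix.X.tocsr()
        indptr = X.indptr.copy()
        data = X.data.copy()
        indices = np.empty_like(X.indices)
        for i in range(matrix.n_cells):
            start, end = indptr[i], indptr[i + 1]
            nnz = end - start
            if nnz:
                pos = rng.choice(n_genes, size=nnz, replace=False)
                order = np.argsort(pos)
                indices[start:end] = pos[order]
                data[start:end] = X.data[start:end][order]
        out = sp.csr_matrix((data, indices, indptr), shape=X.shape)
    else:
        X = np.asarray(matrix.X, float)
        out = np.empty_like(X)
        for i in range(X.shape[0]):
            out[i] = X[i, rng.permutation(n_genes)]
    return NormalizedMatrix(out, matrix.obs.copy(), matrix.var.copy(), matrix.source)


@dataclass
class ReductionParams:
    """Parameters of the HVG → PCA → PC-selection sub-pipeline."""

    n_bins: int = 20
    z_threshold: float = 1.0
    n_components: int = 20
    pc_selection: str = "fixed"  # or "permutation"
    pc_permutations: int = 25
    alpha: float = 0.05
    scale: bool = False
    min_hvg: int = 30  # fallback size when the binned selector finds fewer


def reduce_matrix(
    matrix: NormalizedMatrix, params: ReductionParams, seed: int = 0
) -> tuple[PCAResult, list[str]]:
    """HVG selection, PCA and significant-PC selection in one step."""
    hvg = select_variable_genes(matrix, params.n_bins, params.z_threshold)
    genes = hvg.selected
    if len(genes) < params.min_hvg:
        fallback = hvg.table.sort_values("z", ascending=False).index[: params.min_hvg]
        genes = [g for g in fallback if hvg.table.loc[g, "dispersion"] > 0]
        logger.debug("reduce_matrix: HVG fallback to top %d by z", len(genes))
    n_comp = min(params.n_components, max(2, len(genes) - 1), matrix.n_cells - 1)
    pca = run_pca(matrix, genes, n_comp, scale=params.scale)
    if params.pc_selection == "permutation":
        selected = select_significant_pcs(
            matrix, genes, n_comp, n_permutations=params.pc_permutations,
            alpha=params.alpha, seed=seed, scale=params.scale,
        )
        if not selected:
            # no component beats the null: there is no evidence for any
            # truncation, so keep the full computed basis (the scan's
            # modularity ratio judges whether structure exists)
            selected = list(range(n_comp))
    elif params.pc_selection == "fixed":
        selected = list(range(n_comp))
    else:
        raise ValueError(f"unknown pc_selection {params.pc_selection!r}")
    pca.selected = selected
    return pca, genes


def cluster_matrix(
    matrix: NormalizedMatrix,
    k: int,
    params: ReductionParams | None = None,
    seed: int = 0,
    method: str = "louvain",
) -> tuple[ClusteringResult, PCAResult]:
    """Full sub-pipeline: HVG → PCA → selected PCs → KNN graph → Louvain."""
    params = params or ReductionParams()
    pca, _ = reduce_matrix(matrix, params, seed=seed)
    graph = build_knn_graph(pca.selected_scores, k)
    cluster_fn = leiden_cluster if method == "leiden" else louvain_cluster
    result = cluster_fn(graph, seed=seed)
    result.k = k
    result.barcodes = list(matrix.obs.index)
    return result, pca


def default_k_grid(n_cells: int, k_min: int = 10, n_points: int = 4) -> list[int]:
    """Geometric grid of k from ``k_min`` to √(cells)."""
    k_max = max(k_min + 1, int(np.sqrt(n_cells)))
    grid = np.unique(
        np.round(np.geomspace(k_min, k_max, n_points)).astype(int)
    )
    return [int(k) for k in grid if k < n_cells]


def select_resolution(
    matrix: NormalizedMatrix,
    k_grid: Sequence[int] | None = None,
    n_shuffles: int = 100,
    ratio_threshold: float = 2.0,
    seed: int = 0,
    params: ReductionParams | None = None,
    method: str = "louvain",
) -> ResolutionScan:
    """Choose the clustering resolution by a shuffled-matrix modularity null.

    For every k in the grid, the observed modularity O_k of the full
    sub-pipeline is compared with S_k, the mean modularity of the same
    sub-pipeline (HVG and PCA recomputed per shuffle) on ``n_shuffles``
    within-cell-shuffled matrices. Among k with O_k/S_k ≥
    ``ratio_threshold``, the one yielding the most clusters wins (ties:
    larger modularity, then smaller k); ``chosen_k`` is None if no k
    qualifies.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be at least 1")
    k_grid = list(k_grid) if k_grid is not None else default_k_grid(matrix.n_cells)
    if not k_grid:
        raise ValueError("empty k grid")
    bad = [k for k in k_grid if k >= matrix.n_cells]
    if bad:
        raise ValueError(f"k values {bad} not below cell count {matrix.n_cells}")
    params = params or ReductionParams()
    rng = np.random.default_rng(seed)

    observed: dict[int, ClusteringResult] = {}
    pca, _ = reduce_matrix(matrix, params, seed=seed)
    for k in k_grid:
        graph = build_knn_graph(pca.selected_scores, k)
        fn = leiden_cluster if method == "leiden" else louvain_cluster
        res = fn(graph, seed=seed)
        res.k = k
        res.barcodes = list(matrix.obs.index)
        observed[k] = res

    null: dict[int, list[float]] = {k: [] for k in k_grid}
    for s in range(n_shuffles):
        shuf_seed = int(rng.integers(2**31))
        shuffled = shuffle_within_cells(matrix, seed=shuf_seed)
        pca_s, _ = reduce_matrix(shuffled, params, seed=shuf_seed)
        for k in k_grid:
            graph = build_knn_graph(pca_s.selected_scores, k)
            fn = leiden_cluster if method == "leiden" else louvain_cluster
            null[k].append(fn(graph, seed=shuf_seed).modularity)

    rows = []
    for k in k_grid:
        o = observed[k].modularity
        s_mean = float(np.mean(null[k]))
        ratio = o / s_mean if s_mean > 0 else np.inf if o > 0 else 0.0
        rows.append(
            {"k": k, "observed": o, "null_mean": s_mean, "ratio": ratio,
             "n_clusters": observed[k].n_clusters}
        )
    table = pd.DataFrame(rows)

    qualifying = table[table["ratio"] >= ratio_threshold]
    chosen_k: int | None = None
    if not qualifying.empty:
        best = qualifying.sort_values(
            ["n_clusters", "observed", "k"], ascending=[False, False, True]
        ).iloc[0]
        chosen_k = int(best["k"])
    return ResolutionScan(
        table=table,
        null_samples={k: np.asarray(v) for k, v in null.items()},
        ratio_threshold=ratio_threshold,
        n_shuffles=n_shuffles,
        chosen_k=chosen_k,
        chosen=observed[chosen_k] if chosen_k is not None else None,
    )


# ---------------------------------------------------------------------------
# Contaminant purge
# ---------------------------------------------------------------------------

def purge_contaminant_cells(
    matrix,
    clustering: ClusteringResult,
    pca: PCAResult,
    marker_symbols: Sequence[str] = ("Cd79a", "Cd79b"),
    marker_fraction: float = 0.5,
    loading_quantile: float = 0.99,
) -> tuple[np.ndarray, dict]:
    """Flag B-cell contaminants for removal; the caller re-runs the pipeline.

    Two rules: (1) clusters whose marker detection rate (fraction of cells
    with any marker read) is at least ``marker_fraction`` are removed
    wholesale; (2) components whose top-decile absolute loadings include a
    marker gene are flagged, and cells above the ``loading_quantile``
    quantile of |score| on a flagged component are removed individually.
    Returns a boolean keep-mask and a report dict.
    """
    markers = [s for s in marker_symbols if s in matrix.gene_symbols]
    report: dict = {"markers": markers, "removed_clusters": [],
                    "flagged_components": [], "n_cluster_rule": 0, "n_pc_rule": 0}
    keep = np.ones(matrix.n_cells, dtype=bool)
    if not markers:
        logger.warning("purge_contaminant_cells: markers %s absent; identity mask",
                       list(marker_symbols))
        return keep, report

    cols = [matrix.var.index.get_loc(s) for s in markers]
    sub = matrix.X[:, cols]
    detected = (
        np.asarray((sub > 0).sum(axis=1)).ravel() if sp.issparse(sub)
        else (np.asarray(sub) > 0).sum(axis=1)
    ) > 0

    labels = np.asarray(clustering.labels)
    for c in np.unique(labels):
        members = labels == c
        if detected[members].mean() >= marker_fraction:
            keep[members] = False
            report["removed_clusters"].append(int(c))
    report["n_cluster_rule"] = int((~keep).sum())

    marker_rows = [pca.genes.index(s) for s in markers if s in pca.genes]
    pc_removed = np.zeros(matrix.n_cells, dtype=bool)
    if marker_rows:
        comps = pca.selected or list(range(pca.loadings.shape[1]))
        for c in comps:
            load = np.abs(pca.loadings[:, c])
            cutoff = np.quantile(load, 0.9)
            top = set(np.flatnonzero(load >= cutoff))
            if any(r in top for r in marker_rows):
                report["flagged_components"].append(int(c))
                sc = np.abs(pca.scores[:, c])
                pc_removed |= sc > np.quantile(sc, loading_quantile)
    report["n_pc_rule"] = int(pc_removed.sum())
    keep &= ~pc_removed
    report["n_removed"] = int((~keep).sum())
    return keep, report


def write_resolution_scan(scan: ResolutionScan, path) -> None:
    scan.table.to_csv(path, sep="\t", index=False)


def write_labels(result: ClusteringResult, path) -> None:
    result.to_series().to_frame().to_csv(path, sep="\t")
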