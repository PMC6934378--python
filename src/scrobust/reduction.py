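"""Variable-gene selection, PCA with permutation component selection, t-SNE.

Highly variable genes are found per dataset by binning genes into
equal-frequency bins of mean expression and selecting genes whose dispersion
(variance/mean of normalized values) lies more than ``z_threshold`` standard
deviations above their bin's average — the binning absorbs the
mean–dispersion trend (heteroscedasticity) of log-normalized counts.

Significant principal components are chosen with a gene-permutation test in
the spirit of jackstraw: each gene's values are permuted independently
across cells (destroying gene–gene covariance while keeping every gene's
marginal distribution), PCA is re-run, and the observed explained variance
of rank c is compared to the rank-c null quantile; selection stops at the
first non-significant rank so the result is a contiguous top-k prefix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .io_qc import NormalizedMatrix

logger = logging.getLogger("scrobust")


@dataclass
class HVGResult:
    """Per-gene HVG statistics and the selected gene list."""

    table: pd.DataFrame  # index symbol; mean, dispersion, bin, z, selected
    n_bins: int
    z_threshold: float

    @property
    def selected(self) -> list[str]:
        return list(self.table.index[self.table["selected"]])


@dataclass
class PCAResult:
    """Cell scores, gene loadings and explained variance of one PCA."""

    scores: np.ndarray  # cells × components
    loadings: np.ndarray  # genes × components
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    genes: list[str]
    barcodes: list[str]
    selected: list[int] = field(default_factory=list)
    permutation_pvalues: np.ndarray | None = None

    @property
    def selected_scores(self) -> np.ndarray:
        idx = self.selected if self.selected else list(range(self.scores.shape[1]))
        return self.scores[:, idx]


def _gene_moments(matrix: NormalizedMatrix) -> tuple[np.ndarray, np.ndarray]:
    X = matrix.X
    if sp.issparse(X):
        mean = np.asarray(X.mean(axis=0)).ravel()
        sq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
        var = np.maximum(sq - mean**2, 0.0)
    else:
        X = np.asarray(X, float)
        mean = X.mean(axis=0)
        var = X.var(axis=0)
    return mean, var


def select_variable_genes(
    matrix: NormalizedMatrix, n_bins: int = 20, z_threshold: float = 1.0
) -> HVGResult:
    """Binned-dispersion highly-variable-gene selection.

    Genes are placed into ``n_bins`` equal-frequency bins by mean normalized
    expression; within each bin the dispersion (variance/mean) is
    standardized and genes with z > ``z_threshold`` are selected. Constant
    genes (zero variance) are never selected.
    """
    mean, var = _gene_moments(matrix)
    with np.errstate(invalid="ignore", divide="ignore"):
        dispersion = np.where(mean > 0, var / np.maximum(mean, 1e-300), 0.0)

    table = pd.DataFrame(
        {"mean": mean, "dispersion": dispersion}, index=matrix.var.index.copy()
    )
    informative = (mean > 0) & (var > 0)
    if not informative.any():
        logger.warning("select_variable_genes: all genes constant; empty selection")
        table["bin"] = -1
        table["z"] = np.nan
        table["selected"] = False
        return HVGResult(table, n_bins, z_threshold)

    # equal-frequency bins: the r-th smallest mean (stable order) goes to
    # bin floor(r * n_eff / m)
    bins = pd.Series(-1, index=table.index, dtype=int)
    info_idx = np.flatnonzero(informative)
    m = info_idx.size
    n_eff_bins = min(n_bins, m)
    order = np.lexsort((info_idx, mean[info_idx]))
    ranks = np.empty(m, dtype=int)
    ranks[order] = np.arange(m)
    bins.iloc[info_idx] = (ranks * n_eff_bins) // m
    table["bin"] = bins

    z = pd.Series(np.nan, index=table.index)
    for b, group in table.loc[informative].groupby("bin"):
        d = group["dispersion"]
        sd = d.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            z.loc[group.index] = 0.0
        else:
            z.loc[group.index] = (d - d.mean()) / sd
    table["z"] = z
    table["selected"] = informative & (table["z"] > z_threshold)
    return HVGResult(table, n_bins, z_threshold)


def _dense_subset(matrix: NormalizedMatrix, genes: Sequence[str]) -> np.ndarray:
    idx = [matrix.var.index.get_loc(g) for g in genes]
    X = matrix.X[:, idx] if not sp.issparse(matrix.X) else matrix.X[:, idx].toarray()
    return np.asarray(X, dtype=float)


def _pca_fixed_sign(X: np.ndarray, n_components: int) -> PCA:
    n_components = min(n_components, min(X.shape))
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(X)
    # sign convention: the largest-magnitude loading of each component is positive
    for c in range(pca.components_.shape[0]):
        j = np.argmax(np.abs(pca.components_[c]))
        if pca.components_[c, j] < 0:
            pca.components_[c] *= -1
    return pca


def run_pca(
    matrix: NormalizedMatrix,
    genes: Sequence[str],
    n_components: int,
    scale: bool = False,
) -> PCAResult:
    """PCA on the (centered, optionally unit-scaled) chosen genes.

    Genes are centered but not variance-scaled by default, preserving the
    dispersion signal the HVG step selected for. A deterministic sign
    convention (largest-magnitude loading positive) is applied.
    """
    if matrix.n_cells < 2:
        raise ValueError("PCA requires at least 2 cells")
    genes = list(genes)
    if n_components > min(matrix.n_cells, len(genes)):
        raise ValueError(
            f"n_components={n_components} exceeds min(cells={matrix.n_cells}, "
            f"genes={len(genes)})"
        )
    X = _dense_subset(matrix, genes)
    if scale:
        sd = X.std(axis=0, ddof=0)
        X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    pca = _pca_fixed_sign(X, n_components)
    scores = (X - X.mean(axis=0)) @ pca.components_.T
    return PCAResult(
        scores=scores,
        loadings=pca.components_.T.copy(),
        explained_variance=pca.explained_variance_.copy(),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        genes=genes,
        barcodes=list(matrix.obs.index),
    )


def select_significant_pcs(
    matrix: NormalizedMatrix,
    genes: Sequence[str],
    n_components: int,
    n_permutations: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    scale: bool = False,
) -> list[int]:
    """Gene-permutation test for significant principal components.

    The null distribution of per-rank explained variance is built by
    independently permuting each gene across cells and re-running PCA;
    component c is selected if its observed explained variance exceeds the
    (1 − alpha) null quantile for rank c, and selection is a contiguous
    prefix (stops at the first failing rank).
    """
    if n_components == 0:
        return []
    if n_permutations < 1:
        raise ValueError("n_permutations must be at least 1")
    observed = run_pca(matrix, genes, n_components, scale=scale)
    X = _dense_subset(matrix, list(genes))
    rng = np.random.default_rng(seed)
    n_cells = X.shape[0]
    k = observed.explained_variance.shape[0]
    null_ev = np.empty((n_permutations, k))
    Xp = np.empty_like(X)
    for p in range(n_permutations):
        for j in range(X.shape[1]):
            Xp[:, j] = X[rng.permutation(n_cells), j]
        if scale:
            sd = Xp.std(axis=0, ddof=0)
            Xs = (Xp - Xp.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
        else:
            Xs = Xp
        pca = PCA(n_components=k, svd_solver="full").fit(Xs)
        null_ev[p] = pca.explained_variance_
    thresholds = np.quantile(null_ev, 1.0 - alpha, axis=0)
    selected: list[int] = []
    for c in range(k):
        if observed.explained_variance[c] > thresholds[c]:
            selected.append(c)
        else:
            break
    return selected


def run_tsne(
    pcs: PCAResult,
    perplexity: float = 30.0,
    iterations: int = 10000,
    seed: int = 0,
) -> np.ndarray:
    """Barnes-Hut t-SNE on the selected components (2-D, seeded)."""
    scores = pcs.selected_scores
    if scores.shape[1] == 0:
        raise ValueError("no selected components to embed")
    n = scores.shape[0]
    if n <= 3 * perplexity:
        suggested = max(2.0, (n - 1) / 3.0)
        raise ValueError(
            f"{n} cells is too few for perplexity={perplexity}; "
            f"try perplexity≤{suggested:.0f}"
        )
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        max_iter=iterations,
        method="barnes_hut",
        init="pca",
        random_state=seed,
    )
    return tsne.fit_transform(scores)


def write_hvg_table(result: HVGResult, path) -> None:
    result.table.to_csv(path, sep="\t")


def write_pca_scores(result: PCAResult, path) -> None:
    df = pd.DataFrame(
        result.scores,
        index=pd.Index(result.barcodes, name="barcode"),
        columns=[f"PC{i+1}" for i in range(result.scores.shape[1])],
    )
    df.to_csv(path, sep="\t")


def write_embedding(coords: np.ndarray, barcodes: Sequence[str], path) -> None:
    pd.DataFrame(
        coords, index=pd.Index(barcodes, name="barcode"), columns=["tsne1", "tsne2"]
    ).to_csv(path, sep="\t")
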