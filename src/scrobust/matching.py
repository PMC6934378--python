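"""Batch-robust cluster matching, robust-cluster calling and meta-clustering.

A cluster's fingerprint is its fold-change (FC) vector: per gene, the ratio
of the cluster's mean normalized expression to the pooled mean of all other
clusters of the *same* dataset. Because each gene is expressed relative to
its own dataset's background, multiplicative per-dataset batch effects
cancel, so Pearson correlation between FC vectors compares clusters by
their deviation pattern rather than by tissue/batch context. The Euclidean
distance between raw mean-expression vectors — which groups clusters by
dataset when batch effects dominate — is kept as the contrast baseline.

A cluster is called *robust* when its best cross-replicate FC correlation
exceeds its dataset's mean cross-replicate correlation by ~1.28 standard
deviations (the upper-tail normal quantile at nominal p = 0.1). Robust
clusters from all datasets are then merged by average-linkage hierarchical
clustering of 1 − r into meta-clusters that may span tissues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.sparse as sp
import scipy.spatial.distance as ssd

from .clustering import ClusteringResult
from .io_qc import NormalizedMatrix

logger = logging.getLogger("scrobust")

FC_EPS = 1e-9
FC_CAP = 1e4
ROBUST_Z = 1.2816  # upper-tail N(0,1) quantile at p = 0.1


@dataclass
class ClusterProfile:
    """Per-cluster expression fingerprints over one dataset's gene universe."""

    cluster: int
    dataset: str
    mean_expr: pd.Series  # gene-indexed mean normalized expression
    fc: pd.Series  # gene-indexed fold-change vector (ε-floored, capped)
    detection: pd.Series
    n_cells: int

    @property
    def key(self) -> str:
        return f"{self.dataset}:c{self.cluster}"


@dataclass
class MatchMatrix:
    """Cross-dataset Pearson correlations of cluster FC vectors."""

    corr: pd.DataFrame  # rows: dataset X clusters, cols: dataset Y clusters
    dataset_x: str
    dataset_y: str
    log_fc: bool

    def stats_for(self, axis: int) -> tuple[float, float]:
        values = self.corr.to_numpy(float).ravel()
        return float(values.mean()), float(values.std(ddof=1)) if values.size > 1 else 0.0

    def best_match(self, axis: int = 0) -> pd.Series:
        return self.corr.max(axis=1) if axis == 0 else self.corr.max(axis=0)


@dataclass
class MetaClustering:
    """Hierarchical meta-clusters over robust cluster profiles."""

    assignments: pd.Series  # profile key -> meta-cluster id (1-based)
    linkage: np.ndarray
    keys: list[str]
    cut: float | int
    merged: dict = field(default_factory=dict)

    @property
    def n_meta(self) -> int:
        return int(self.assignments.nunique())

    def newick(self) -> str:
        tree = sch.to_tree(self.linkage)

        def walk(node) -> str:
            if node.is_leaf():
                return self.keys[node.id]
            return f"({walk(node.left)},{walk(node.right)}):{node.dist:.4f}"

        return walk(tree) + ";"


def fold_change_vectors(
    matrix: NormalizedMatrix,
    labels: ClusteringResult | np.ndarray,
    gene_universe: Sequence[str] | None = None,
    dataset: str | None = None,
) -> list[ClusterProfile]:
    """FC, mean-expression and detection vectors for every cluster.

    ``FC_gc = (mean_c(norm_g) + ε) / (mean_not-c(norm_g) + ε)``, ε = 1e-9,
    capped at 1e4; the background pools all other clusters of the same
    dataset, so the vectors are invariant to how the rest is partitioned.
    """
    lab = np.asarray(labels.labels if isinstance(labels, ClusteringResult) else labels)
    clusters = np.unique(lab)
    if clusters.size < 2:
        raise ValueError("fold-change vectors need at least 2 clusters")
    if dataset is None:
        dataset = (
            str(matrix.obs["dataset"].iloc[0]) if "dataset" in matrix.obs.columns
            and matrix.n_cells else "dataset"
        )
    if gene_universe is not None:
        cols = np.asarray([matrix.var.index.get_loc(g) for g in gene_universe], int)
        matrix = matrix.subset_genes(cols)

    X = matrix.X
    dense = not sp.issparse(X)
    profiles = []
    for c in clusters:
        fg = np.flatnonzero(lab == c)
        bg = np.flatnonzero(lab != c)
        if dense:
            m_fg = np.asarray(X, float)[fg].mean(axis=0)
            m_bg = np.asarray(X, float)[bg].mean(axis=0)
            det = (np.asarray(X)[fg] > 0).mean(axis=0)
        else:
            m_fg = np.asarray(X[fg].mean(axis=0)).ravel()
            m_bg = np.asarray(X[bg].mean(axis=0)).ravel()
            det = np.asarray((X[fg] > 0).sum(axis=0)).ravel() / fg.size
        fc = np.minimum((m_fg + FC_EPS) / (m_bg + FC_EPS), FC_CAP)
        idx = matrix.var.index
        profiles.append(
            ClusterProfile(
                cluster=int(c),
                dataset=dataset,
                mean_expr=pd.Series(m_fg, index=idx),
                fc=pd.Series(fc, index=idx),
                detection=pd.Series(det, index=idx),
                n_cells=int(fg.size),
            )
        )
    return profiles


#: Minimum within-dataset detection rate for a gene to enter the
#: FC-correlation universe. Genes essentially undetected in a dataset have
#: near-zero group means, so their ε-floored fold changes are numerical
#: noise that would swamp the Pearson correlation.
MIN_DETECTION = 0.05


def _detected_genes(profiles: Sequence[ClusterProfile], min_detection: float) -> set:
    det = pd.concat([p.detection for p in profiles], axis=1).max(axis=1)
    return set(det.index[det >= min_detection])


def _shared_universe(
    profiles_x, profiles_y, min_detection: float = MIN_DETECTION
) -> pd.Index:
    gx = profiles_x[0].fc.index
    gy = set(profiles_y[0].fc.index)
    shared = [g for g in gx if g in gy]
    if min_detection > 0:
        keep = _detected_genes(profiles_x, min_detection) & _detected_genes(
            profiles_y, min_detection
        )
        shared = [g for g in shared if g in keep]
    return pd.Index(shared)


def correlate_clusters(
    profiles_x: Sequence[ClusterProfile],
    profiles_y: Sequence[ClusterProfile],
    log_fc: bool = True,
    min_detection: float = MIN_DETECTION,
) -> MatchMatrix:
    """Pearson correlation of FC vectors for every cross-dataset cluster pair.

    Correlation is computed on log(FC) by default (ratios are multiplicative;
    the log keeps a few extreme genes from dominating Pearson); raw-FC mode
    is available for fidelity checks. The gene universe is the intersection
    of the two datasets' genes, restricted to genes detected in at least
    ``min_detection`` of some cluster's cells on both sides.
    """
    shared = _shared_universe(profiles_x, profiles_y, min_detection)
    if len(shared) < 10:
        raise ValueError(
            f"shared gene universe has only {len(shared)} genes; correlation unstable"
        )

    def vec(p: ClusterProfile) -> np.ndarray:
        v = p.fc.loc[shared].to_numpy(float)
        return np.log(v) if log_fc else v

    vx = np.array([vec(p) for p in profiles_x])
    vy = np.array([vec(p) for p in profiles_y])
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(np.vstack([vx, vy]))[: len(vx), len(vx):]
    corr = np.nan_to_num(corr)  # constant FC vectors: correlation undefined -> 0
    df = pd.DataFrame(
        corr,
        index=[p.key for p in profiles_x],
        columns=[p.key for p in profiles_y],
    )
    return MatchMatrix(
        corr=df,
        dataset_x=profiles_x[0].dataset,
        dataset_y=profiles_y[0].dataset,
        log_fc=log_fc,
    )


def call_robust_clusters(matches: MatchMatrix, z: float = ROBUST_Z) -> pd.Series:
    """Flag clusters whose best replicate match clears the dataset threshold.

    For each dataset the threshold is mean + z·SD over *all* of its
    cross-replicate correlations; a cluster is robust iff its best match
    strictly exceeds the threshold. With SD = 0 no cluster is robust.
    """
    values = matches.corr.to_numpy(float).ravel()
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    if sd == 0.0:
        logger.warning("call_robust_clusters: zero SD of correlations; none robust")
    threshold = mean + z * sd
    flags = {}
    for key in matches.corr.index:
        flags[key] = bool(sd > 0 and matches.corr.loc[key].max() > threshold)
    for key in matches.corr.columns:
        flags[key] = bool(sd > 0 and matches.corr[key].max() > threshold)
    return pd.Series(flags, name="robust")


def _pairwise_fc_corr(
    profiles: Sequence[ClusterProfile], log_fc: bool,
    min_detection: float = MIN_DETECTION,
) -> np.ndarray:
    shared = profiles[0].fc.index
    for p in profiles[1:]:
        inset = set(p.fc.index)
        shared = pd.Index([g for g in shared if g in inset])
    if min_detection > 0:
        by_dataset: dict[str, list[ClusterProfile]] = {}
        for p in profiles:
            by_dataset.setdefault(p.dataset, []).append(p)
        for group in by_dataset.values():
            keep = _detected_genes(group, min_detection)
            shared = pd.Index([g for g in shared if g in keep])
    if len(shared) < 10:
        raise ValueError("shared gene universe too small for meta-clustering")
    V = np.array([
        np.log(p.fc.loc[shared].to_numpy(float)) if log_fc
        else p.fc.loc[shared].to_numpy(float)
        for p in profiles
    ])
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(V)
    corr = np.nan_to_num(corr)
    np.fill_diagonal(corr, 1.0)
    return corr


def meta_cluster(
    profiles: Sequence[ClusterProfile],
    linkage: str = "average",
    cut: int | float = 2,
    cut_by: str = "count",
    log_fc: bool = True,
    min_detection: float = MIN_DETECTION,
    merge: Mapping[int, int] | None = None,
) -> MetaClustering:
    """Agglomerate robust clusters on 1 − Pearson(FC) into meta-clusters.

    ``cut_by='count'`` cuts the tree into ``cut`` meta-clusters;
    ``cut_by='height'`` cuts at distance ``cut``. An explicit ``merge``
    directive (meta id → meta id) supports curated merges and is recorded on
    the result.
    """
    if len(profiles) < 2:
        raise ValueError("meta-clustering needs at least 2 robust clusters")
    if linkage not in ("average", "complete"):
        raise ValueError("linkage must be 'average' or 'complete'")
    corr = _pairwise_fc_corr(profiles, log_fc, min_detection)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    Z = sch.linkage(ssd.squareform(dist, checks=False), method=linkage)
    if cut_by == "count":
        if int(cut) > len(profiles):
            raise ValueError(
                f"cut={cut} exceeds the number of robust clusters ({len(profiles)})"
            )
        assign = sch.fcluster(Z, t=int(cut), criterion="maxclust")
    elif cut_by == "height":
        assign = sch.fcluster(Z, t=float(cut), criterion="distance")
    else:
        raise ValueError("cut_by must be 'count' or 'height'")
    keys = [p.key for p in profiles]
    series = pd.Series(assign, index=keys, name="meta_cluster")
    merged: dict = {}
    if merge:
        for src, dst in merge.items():
            merged[int(src)] = int(dst)
            series[series == int(src)] = int(dst)
            logger.info("meta_cluster: merged meta-cluster %s into %s", src, dst)
    return MetaClustering(series, Z, keys, cut, merged)


def euclidean_baseline(
    profiles_x: Sequence[ClusterProfile],
    profiles_y: Sequence[ClusterProfile] | None = None,
    linkage: str = "average",
    cut: int = 2,
) -> tuple[pd.DataFrame, pd.Series]:
    """Euclidean distances between mean-expression vectors, plus a grouping.

    The contrast baseline for :func:`meta_cluster`: distances computed on
    raw mean-expression vectors, hierarchically grouped with the same cut
    convention.
    """
    profiles = list(profiles_x) + (list(profiles_y) if profiles_y else [])
    shared = profiles[0].mean_expr.index
    for p in profiles[1:]:
        inset = set(p.mean_expr.index)
        shared = pd.Index([g for g in shared if g in inset])
    if len(shared) == 0:
        raise ValueError("no shared genes for the Euclidean baseline")
    V = np.array([p.mean_expr.loc[shared].to_numpy(float) for p in profiles])
    keys = [p.key for p in profiles]
    dist = ssd.squareform(ssd.pdist(V, metric="euclidean"))
    df = pd.DataFrame(dist, index=keys, columns=keys)
    Z = sch.linkage(ssd.pdist(V, metric="euclidean"), method=linkage)
    grouping = pd.Series(
        sch.fcluster(Z, t=int(cut), criterion="maxclust"), index=keys, name="group"
    )
    return df, grouping


def write_match_matrix(matches: MatchMatrix, path) -> None:
    matches.corr.rename_axis("cluster").to_csv(path, sep="\t")


def write_meta_clusters(meta: MetaClustering, path) -> None:
    meta.assignments.rename_axis("cluster").to_frame().to_csv(path, sep="\t")
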