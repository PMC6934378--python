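"""Two-group differential expression with empirical-Bayes moderated t-tests.

The moderated t follows the limma design for a two-group contrast: per-gene
pooled variances s_g² (df d = n1 + n2 − 2) are shrunk toward a prior s0²
with prior degrees of freedom d0, both estimated by matching the first two
moments of the observed variance distribution to its scaled-F marginal
(s² ~ s0²·F(d, d0)). The moderated statistic uses the posterior variance
s̃² = (d0·s0² + d·s²)/(d0 + d) and is referred to a t distribution with
d + d0 degrees of freedom. As d0 → 0 this reduces to the ordinary pooled
t-test (which equals Welch's t when group sizes and variances agree); a
Welch-t mode is provided as a cross-check. P-values are BH-adjusted.

Fold change is the linear-space ratio of group means of normalized values,
floored with ε = 1e-9. Replicate-concordant cluster-defining genes must
pass FC > 1.25 and Q < 0.1 (strict) independently in both replicates.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

from .io_qc import CountMatrix, NormalizedMatrix

logger = logging.getLogger("scrobust")

FC_EPS = 1e-9


def _group_stats(X, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-gene mean, unbiased variance and detection rate over a cell set."""
    n = idx.size
    if sp.issparse(X):
        sub = X[idx]
        mean = np.asarray(sub.mean(axis=0)).ravel()
        sq = np.asarray(sub.multiply(sub).mean(axis=0)).ravel()
        var = np.maximum(sq - mean**2, 0.0) * (n / max(n - 1, 1))
        det = np.asarray((sub > 0).sum(axis=0)).ravel() / n
    else:
        sub = np.asarray(X, float)[idx]
        mean = sub.mean(axis=0)
        var = sub.var(axis=0, ddof=1) if n > 1 else np.zeros_like(mean)
        det = (sub > 0).mean(axis=0)
    return mean, var, det


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square variance prior (d0, s0²).

    Under the prior, observed variances follow s0²·F(df, d0); matching the
    mean and squared coefficient of variation of the positive s² values
    gives closed-form d0 and s0². Returns ``d0 = inf`` (complete shrinkage)
    when the observed variances are underdispersed relative to any finite
    prior.
    """
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 3:
        return np.inf, float(np.mean(s2)) if s2.size else 1.0
    m = float(np.mean(s2))
    v = float(np.var(s2, ddof=1))
    c = v / m**2  # squared CV; for F(df, d0): 2(df+d0-2) / (df(d0-4))
    denom = c * df - 2.0
    if denom <= 0:
        return np.inf, m
    d0 = (4.0 * c * df + 2.0 * df - 4.0) / denom
    if d0 <= 4.0:
        d0 = 4.0 + 1e-6
    s0_sq = m * (d0 - 2.0) / d0
    return float(d0), float(s0_sq)


def de_test(
    matrix: NormalizedMatrix,
    foreground: Sequence[int] | np.ndarray,
    background: Sequence[int] | np.ndarray,
    method: str = "moderated-t",
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Per-gene two-group test of foreground vs background cells.

    Returns a gene-indexed table with linear-space fold change of means
    (ε-floored), the t statistic, raw p, BH-adjusted ``q``, and detection
    rates in both groups. Genes with zero variance in both groups get p = 1.
    ``prior_df`` overrides the fitted prior degrees of freedom (0 recovers
    the unmoderated pooled t).
    """
    fg = np.asarray(foreground, int)
    bg = np.asarray(background, int)
    if fg.size < 3 or bg.size < 3:
        raise ValueError("both cell sets need at least 3 cells")
    if np.intersect1d(fg, bg).size:
        raise ValueError("foreground and background cell sets overlap")

    m1, v1, d1 = _group_stats(matrix.X, fg)
    m2, v2, d2 = _group_stats(matrix.X, bg)
    n1, n2 = fg.size, bg.size
    diff = m1 - m2
    degenerate = (v1 == 0) & (v2 == 0)

    if method == "welch-t":
        se2 = v1 / n1 + v2 / n2
        with np.errstate(invalid="ignore", divide="ignore"):
            t = diff / np.sqrt(se2)
            df = se2**2 / (
                (v1 / n1) ** 2 / max(n1 - 1, 1) + (v2 / n2) ** 2 / max(n2 - 1, 1)
            )
        p = 2.0 * st.t.sf(np.abs(t), df)
    elif method == "moderated-t":
        df_resid = n1 + n2 - 2
        s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df_resid
        if prior_df is None:
            d0, s0_sq = fit_variance_prior(s2, df_resid)
        else:
            d0 = prior_df
            _, s0_sq = fit_variance_prior(s2, df_resid)
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0_sq)
            df_total = np.inf
        elif d0 == 0:
            s2_post = s2
            df_total = df_resid
        else:
            s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
            df_total = df_resid + d0
        with np.errstate(invalid="ignore", divide="ignore"):
            t = diff / np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
        if np.isinf(df_total):
            p = 2.0 * st.norm.sf(np.abs(t))
        else:
            p = 2.0 * st.t.sf(np.abs(t), df_total)
    else:
        raise ValueError(f"unknown method {method!r}")

    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate | ~np.isfinite(p), 1.0, p)
    q = bh_adjust(p)
    fc = (m1 + FC_EPS) / (m2 + FC_EPS)
    return pd.DataFrame(
        {
            "fc": fc,
            "t": t,
            "p": p,
            "q": q,
            "det_fg": d1,
            "det_bg": d2,
            "det_diff": d1 - d2,
            "mean_fg": m1,
            "mean_bg": m2,
        },
        index=matrix.var.index.copy(),
    )


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values."""
    return multipletests(np.clip(p, 0.0, 1.0), method="fdr_bh")[1]


def detection_rates(
    matrix: CountMatrix, cell_sets: Mapping[str, Sequence[int]]
) -> pd.DataFrame:
    """Per-gene fraction of cells with ≥1 read, per named cell set (on raw counts)."""
    out = {}
    for name, idx in cell_sets.items():
        idx = np.asarray(idx, int)
        if idx.size == 0:
            raise ValueError(f"cell set {name!r} is empty")
        sub = matrix.X[idx]
        out[name] = np.asarray((sub > 0).sum(axis=0)).ravel() / idx.size
    return pd.DataFrame(out, index=matrix.var.index.copy())


def cluster_defining_genes(
    tables_rep1: Mapping, tables_rep2: Mapping,
    matching: Mapping | None = None,
    fc_min: float = 1.25,
    q_max: float = 0.1,
) -> dict:
    """Replicate-concordant cluster-defining genes.

    A gene defines a cluster only if it passes FC > ``fc_min`` and
    Q < ``q_max`` (both strict) in that cluster's DE table in replicate 1
    *and* in the matched cluster's table in replicate 2. ``matching`` maps
    replicate-1 cluster ids to replicate-2 ids (identity by default);
    unmatched clusters yield an empty list.
    """
    out: dict = {}
    for c1, t1 in tables_rep1.items():
        c2 = matching.get(c1) if matching is not None else c1
        if c2 is None or c2 not in tables_rep2:
            logger.warning("cluster_defining_genes: cluster %r unmatched", c1)
            out[c1] = []
            continue
        t2 = tables_rep2[c2]
        pass1 = (t1["fc"] > fc_min) & (t1["q"] < q_max)
        shared = t1.index[pass1].intersection(t2.index)
        pass2 = (t2.loc[shared, "fc"] > fc_min) & (t2.loc[shared, "q"] < q_max)
        out[c1] = list(shared[pass2.to_numpy()])
    return out


def subpopulation_signature(
    matrix_rep1: NormalizedMatrix,
    labels_rep1: np.ndarray,
    matrix_rep2: NormalizedMatrix,
    labels_rep2: np.ndarray,
    target: Sequence[int],
    universe: Sequence[int] | None = None,
    fc_min: float = 1.25,
    q_max: float = 0.1,
    det_margin: float = 0.1,
    method: str = "moderated-t",
) -> list[str]:
    """Genes defining a subpopulation concordantly in both replicates.

    ``target`` lists the cluster ids of the subpopulation (per replicate
    labeling); ``universe`` restricts the background clusters (default: all
    non-target clusters). A gene qualifies if in *both* replicates it passes
    the FC/Q thresholds and its detection-rate difference exceeds
    ``det_margin``.
    """
    target = set(target)
    sigs = []
    for mat, labels in ((matrix_rep1, labels_rep1), (matrix_rep2, labels_rep2)):
        labels = np.asarray(labels)
        fg = np.flatnonzero(np.isin(labels, list(target)))
        if fg.size == 0:
            raise ValueError("target clusters absent in one replicate")
        if universe is None:
            bg = np.flatnonzero(~np.isin(labels, list(target)))
        else:
            bg = np.flatnonzero(np.isin(labels, list(set(universe) - target)))
        table = de_test(mat, fg, bg, method=method)
        hits = table[
            (table["fc"] > fc_min) & (table["q"] < q_max)
            & (table["det_diff"] > det_margin)
        ]
        sigs.append(set(hits.index))
    ordered = [g for g in matrix_rep1.gene_symbols if g in (sigs[0] & sigs[1])]
    return ordered


def cross_dataset_characterization(
    matrix_x: NormalizedMatrix,
    labels_x: np.ndarray,
    cluster_a: int,
    matrix_y: NormalizedMatrix,
    labels_y: np.ndarray,
    cluster_b: int,
    fc_min: float = 1.25,
    q_max: float = 0.1,
    method: str = "moderated-t",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, list[str]]:
    """Three-way DE characterization of cluster A (dataset X) vs B (dataset Y).

    Returns DE tables for (1) A vs rest-of-X, (2) B vs rest-of-Y, (3) A vs B
    (over the shared gene universe), plus the A-specific joint calls: genes
    overexpressed in A both relative to the other clusters of X and relative
    to B. Interpreting the calls jointly over two replicates is the caller's
    responsibility (run once per replicate and intersect).
    """
    labels_x = np.asarray(labels_x)
    labels_y = np.asarray(labels_y)
    a_idx = np.flatnonzero(labels_x == cluster_a)
    b_idx = np.flatnonzero(labels_y == cluster_b)
    t1 = de_test(matrix_x, a_idx, np.flatnonzero(labels_x != cluster_a), method=method)
    t2 = de_test(matrix_y, b_idx, np.flatnonzero(labels_y != cluster_b), method=method)

    # align the two datasets on the shared gene universe, in X's gene order
    y_set = set(matrix_y.gene_symbols)
    shared = [g for g in matrix_x.gene_symbols if g in y_set]
    mx = matrix_x.subset_genes(
        np.asarray([matrix_x.var.index.get_loc(g) for g in shared], int))
    my = matrix_y.subset_genes(
        np.asarray([matrix_y.var.index.get_loc(g) for g in shared], int))

    joint_X = sp.vstack if sp.issparse(mx.X) and sp.issparse(my.X) else np.vstack
    pooled = NormalizedMatrix(
        joint_X([mx.X[a_idx], my.X[b_idx]]),
        pd.concat([mx.obs.iloc[a_idx], my.obs.iloc[b_idx]]),
        mx.var.copy(),
    )
    t3 = de_test(pooled, np.arange(a_idx.size),
                 np.arange(a_idx.size, a_idx.size + b_idx.size), method=method)

    def passing(t: pd.DataFrame) -> set:
        return set(t.index[(t["fc"] > fc_min) & (t["q"] < q_max)])

    calls = [g for g in matrix_x.gene_symbols if g in (passing(t1) & passing(t3))]
    return t1, t2, t3, calls


def signature_overlap_test(
    set_a: Sequence[str], set_b: Sequence[str], universe_size: int
) -> tuple[int, float]:
    """Upper-tail hypergeometric test for the overlap of two gene sets."""
    a, b = set(set_a), set(set_b)
    if universe_size < max(len(a), len(b)):
        raise ValueError("universe smaller than one of the sets")
    k = len(a & b)
    p = float(st.hypergeom.sf(k - 1, universe_size, len(a), len(b)))
    return k, min(p, 1.0)


def cross_cohort_detection_test(
    matrix: CountMatrix,
    lesion_labels: Sequence[str],
    response_labels: Mapping[str, str],
    signature: Sequence[str],
) -> pd.DataFrame:
    """Lesion-level detection-rate comparison of a signature across responses.

    Detection rates are computed per lesion (the unit of analysis) for each
    signature gene, then compared across the two response groups with a
    two-sided Wilcoxon rank-sum test, BH-adjusted across signature genes.
    Each response group must contribute at least 2 lesions.
    """
    lesions = np.asarray(lesion_labels)
    groups: dict[str, list[str]] = {}
    for lesion in pd.unique(lesions):
        groups.setdefault(response_labels[lesion], []).append(lesion)
    if len(groups) != 2:
        raise ValueError(f"expected 2 response groups, got {list(groups)}")
    for g, ls in groups.items():
        if len(ls) < 2:
            raise ValueError(f"response group {g!r} has fewer than 2 lesions")

    genes = [g for g in signature if g in matrix.gene_symbols]
    if not genes:
        raise KeyError("no signature genes present in matrix")
    sets = {lesion: np.flatnonzero(lesions == lesion) for lesion in pd.unique(lesions)}
    rates = detection_rates(matrix.subset_genes(
        np.asarray([matrix.var.index.get_loc(g) for g in genes], int)), sets)

    (name_a, lesions_a), (name_b, lesions_b) = groups.items()
    pvals = []
    for g in genes:
        ra = rates.loc[g, lesions_a].to_numpy(float)
        rb = rates.loc[g, lesions_b].to_numpy(float)
        if np.all(ra == ra[0]) and np.all(rb == rb[0]) and ra[0] == rb[0]:
            pvals.append(1.0)
        else:
            pvals.append(float(st.mannwhitneyu(ra, rb, alternative="two-sided").pvalue))
    out = rates.copy()
    out["p"] = pvals
    out["q"] = bh_adjust(np.asarray(pvals))
    out[f"mean_{name_a}"] = rates[lesions_a].mean(axis=1)
    out[f"mean_{name_b}"] = rates[lesions_b].mean(axis=1)
    return out


def write_de_table(table: pd.DataFrame, path) -> None:
    table.rename_axis("gene").to_csv(path, sep="\t")
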