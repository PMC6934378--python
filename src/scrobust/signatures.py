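"""Gene-signature scoring, confound-signature derivation and regression.

A signature's activation in a cell is its mean normalized expression over
the signature genes minus the mean over a technically matched background:
for each signature gene the 10 most similar non-signature genes in
(mean, variance) space. Scoring against matched background cancels
cell-level coverage effects, so a null signature scores ~0 in every cell.

A derived "activation confound" signature (e.g. the transcriptomic imprint
of tetramer-based sorting on the TCR pathway) can be regressed out of the
expression matrix gene-by-gene with a per-gene linear model, leaving every
gene exactly uncorrelated with the confound score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from .io_qc import NormalizedMatrix

logger = logging.getLogger("scrobust")


@dataclass
class SignatureScore:
    scores: pd.Series  # per-cell, indexed by barcode
    signature_genes: list[str]
    background: dict[str, list[str]]  # per signature gene, its matched genes

    @property
    def values(self) -> np.ndarray:
        return self.scores.to_numpy(float)


def score_signature(
    matrix: NormalizedMatrix,
    gene_set: Sequence[str],
    n_background: int = 10,
    deduplicate_background: bool = False,
) -> SignatureScore:
    """Score a gene signature against background-matched control genes.

    For each signature gene, its ``n_background`` nearest non-signature
    genes in z-standardized (mean, variance) space (Euclidean distance) form
    its background. The per-cell score is the mean expression of the
    signature genes minus the mean over the pooled background multiset (a
    gene backing two signature genes counts twice unless
    ``deduplicate_background``).
    """
    requested = list(dict.fromkeys(gene_set))
    present = [g for g in requested if g in matrix.gene_symbols]
    missing = [g for g in requested if g not in matrix.gene_symbols]
    if not present:
        raise KeyError(f"no signature genes found in matrix; missing: {missing}")
    if missing:
        logger.warning(
            "score_signature: %d/%d signature genes matched",
            len(present), len(requested),
        )
    pool = [g for g in matrix.gene_symbols if g not in set(present)]
    if not pool:
        raise ValueError("background pool is empty: signature covers the gene universe")
    if len(pool) < n_background:
        logger.warning(
            "score_signature: background pool (%d) smaller than n_background (%d)",
            len(pool), n_background,
        )
        n_background = len(pool)

    X = matrix.X
    if sp.issparse(X):
        mean = np.asarray(X.mean(axis=0)).ravel()
        sq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
        var = np.maximum(sq - mean**2, 0.0)
    else:
        X = np.asarray(X, float)
        mean = X.mean(axis=0)
        var = X.var(axis=0)

    def standardize(v: np.ndarray) -> np.ndarray:
        sd = v.std()
        return (v - v.mean()) / (sd if sd > 0 else 1.0)

    feats = np.column_stack([standardize(mean), standardize(var)])
    sym_to_col = {s: j for j, s in enumerate(matrix.gene_symbols)}
    pool_cols = np.array([sym_to_col[g] for g in pool])
    nn = NearestNeighbors(n_neighbors=n_background).fit(feats[pool_cols])

    background: dict[str, list[str]] = {}
    bg_cols: list[int] = []
    sig_cols = [sym_to_col[g] for g in present]
    _, nbr = nn.kneighbors(feats[sig_cols])
    for g, row in zip(present, nbr):
        genes = [pool[i] for i in row]
        background[g] = genes
        bg_cols.extend(pool_cols[row])
    if deduplicate_background:
        bg_cols = sorted(set(bg_cols))

    def col_mean(cols: Sequence[int]) -> np.ndarray:
        cols = np.asarray(cols)
        if sp.issparse(matrix.X):
            sub = matrix.X[:, cols]
            return np.asarray(sub.mean(axis=1)).ravel()
        return np.asarray(matrix.X, float)[:, cols].mean(axis=1)

    scores = col_mean(sig_cols) - col_mean(bg_cols)
    return SignatureScore(
        scores=pd.Series(scores, index=matrix.obs.index, name="score"),
        signature_genes=present,
        background=background,
    )


def derive_confound_signature(
    matrix: NormalizedMatrix,
    sample_labels: Sequence[str] | pd.Series,
    clustering,
    dominance: float = 0.9,
    fc_min: float = 1.25,
    q_max: float = 0.1,
) -> list[str]:
    """Derive a confound signature from label-dominated clusters.

    Given a pooled clustering of two samples (e.g. tetramer-sorted vs
    unsorted), clusters in which the first label's fraction is at least
    ``dominance`` are flagged, and genes overexpressed in the flagged
    clusters versus all other cells (fold change > ``fc_min``, BH
    Q < ``q_max``) form the signature. Returns an empty list (with a
    warning) when no cluster is dominated.
    """
    from .de import de_test

    labels = np.asarray(
        sample_labels.to_numpy() if isinstance(sample_labels, pd.Series) else sample_labels
    )
    levels = pd.unique(labels)
    if len(levels) != 2:
        raise ValueError(f"sample_labels must have exactly 2 levels, got {len(levels)}")
    target = levels[0]
    members = np.asarray(clustering.labels)
    flagged = [
        c for c in np.unique(members)
        if (labels[members == c] == target).mean() >= dominance
    ]
    if not flagged:
        logger.warning("derive_confound_signature: no cluster dominated at %.2f", dominance)
        return []
    fg = np.flatnonzero(np.isin(members, flagged))
    bg = np.flatnonzero(~np.isin(members, flagged))
    table = de_test(matrix, fg, bg)
    hits = table[(table["fc"] > fc_min) & (table["q"] < q_max)]
    return list(hits.index)


def regress_out_signature(
    matrix: NormalizedMatrix, score: SignatureScore | np.ndarray | pd.Series
) -> NormalizedMatrix:
    """Remove a per-cell confound score from every gene by linear regression.

    Each gene is fit as ``x_j = a + b·s_j`` and replaced by
    ``x_j − b·(s_j − mean(s))`` — the residual plus the gene's mean — so the
    per-gene Pearson correlation with the score becomes 0 (to numerical
    precision) and gene means are preserved exactly, keeping the log-space
    location interpretable. A constant score makes the regression degenerate;
    the input is returned unchanged with a warning.
    """
    s = np.asarray(
        score.values if isinstance(score, SignatureScore)
        else (score.to_numpy(float) if isinstance(score, pd.Series) else score),
        dtype=float,
    )
    if s.shape[0] != matrix.n_cells:
        raise ValueError("score length does not match cell count")
    sc = s - s.mean()
    denom = float(sc @ sc)
    if denom == 0.0:
        logger.warning("regress_out_signature: constant score; returning input unchanged")
        return matrix.copy()
    X = matrix.to_dense()
    b = (sc @ X) / denom  # per-gene slope
    # subtract the centered-score component: residual + per-gene mean, so
    # gene means are preserved exactly and corr(out, score) = 0
    out = X - np.outer(sc, b)
    return NormalizedMatrix(out, matrix.obs.copy(), matrix.var.copy(), matrix.source)


def scale_minmax(values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Min-max scale to [0, 1]; a constant vector maps to all zeros."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot scale an empty vector")
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def write_scores(score: SignatureScore, path) -> None:
    score.scores.rename_axis("barcode").to_frame().to_csv(path, sep="\t")
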