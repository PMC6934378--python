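"""Reading 10x-style matrices, quality-control filtering, and normalization.

The containers here are deliberately thin: a sparse cells × genes matrix with
a cell table (``obs``) and a gene table (``var``), mirroring the layout of
AnnData without imposing a dependency on the rest of the pipeline.

Quality control removes, in a single pass evaluated against the *unfiltered*
input matrix:

* cells with fewer than 500 detected genes,
* presumed doublets — cells whose detected-gene count **or** total UMI count
  lies strictly above the 98th sample quantile (matching the ~2% doublet rate
  of droplet platforms),
* presumed dying/senescent cells with a mitochondrial read fraction strictly
  above 10% (computed over a designated set of 13 ``mt-`` genes).

Normalization is library-size scaling to 10,000 counts followed by a natural
log transform: ``norm_ji = ln(1 + 1e4 * raw_ji / LS_j)``.
"""

from __future__ import annotations

import gzip
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger("scrobust")

MITO_PREFIXES = ("mt-", "MT-", "Mt-")

#: The 13 protein-coding mitochondrial genes of the mouse mitochondrial
#: genome, used as the default mitochondrial gene set.
MOUSE_MITO_GENES = (
    "mt-Nd1", "mt-Nd2", "mt-Co1", "mt-Co2", "mt-Atp8", "mt-Atp6", "mt-Co3",
    "mt-Nd3", "mt-Nd4l", "mt-Nd4", "mt-Nd5", "mt-Nd6", "mt-Cytb",
)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Sparse integer UMI matrix (cells × genes) with cell and gene tables.

    Parameters
    ----------
    X
        Sparse non-negative integer matrix, one row per cell.
    obs
        Cell table indexed by barcode. The pipeline uses the optional
        columns ``dataset``, ``tissue`` and ``replicate`` when present.
    var
        Gene table indexed by (deduplicated) symbol, with a boolean
        ``mito`` column flagging mitochondrial genes.
    """

    X: sp.csr_matrix
    obs: pd.DataFrame
    var: pd.DataFrame

    def __post_init__(self) -> None:
        self.X = sp.csr_matrix(self.X)
        if self.X.shape[0] != len(self.obs):
            raise ValueError(
                f"matrix has {self.X.shape[0]} rows but obs has {len(self.obs)} cells"
            )
        if self.X.shape[1] != len(self.var):
            raise ValueError(
                f"matrix has {self.X.shape[1]} columns but var has {len(self.var)} genes"
            )
        if "mito" not in self.var.columns:
            self.var["mito"] = flag_mito_genes(self.var.index)

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X.shape[1]

    @property
    def library_size(self) -> np.ndarray:
        """Total UMIs per cell (LS_j)."""
        return np.asarray(self.X.sum(axis=1)).ravel()

    @property
    def n_detected(self) -> np.ndarray:
        """Number of genes with at least one read, per cell."""
        return np.asarray((self.X > 0).sum(axis=1)).ravel()

    @property
    def gene_symbols(self) -> pd.Index:
        return self.var.index

    def mito_fraction(self) -> np.ndarray:
        """Fraction of each cell's reads mapped to mitochondrial genes."""
        ls = self.library_size.astype(float)
        mito_cols = np.flatnonzero(self.var["mito"].to_numpy())
        if mito_cols.size == 0:
            return np.zeros(self.n_cells)
        mito_sum = np.asarray(self.X[:, mito_cols].sum(axis=1)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(ls > 0, mito_sum / np.maximum(ls, 1e-300), 0.0)
        return frac

    def subset_cells(self, mask_or_idx) -> "CountMatrix":
        idx = _as_row_index(mask_or_idx, self.n_cells)
        return CountMatrix(self.X[idx], self.obs.iloc[idx].copy(), self.var.copy())

    def subset_genes(self, mask_or_idx) -> "CountMatrix":
        idx = _as_row_index(mask_or_idx, self.n_genes)
        return CountMatrix(self.X[:, idx], self.obs.copy(), self.var.iloc[idx].copy())

    def copy(self) -> "CountMatrix":
        return CountMatrix(self.X.copy(), self.obs.copy(), self.var.copy())


@dataclass
class NormalizedMatrix:
    """Real-valued cells × genes matrix of ln(1 + 1e4·raw/LS) values.

    ``X`` is kept sparse where the transform preserves sparsity; operations
    such as confound regression may return a dense ``X``.
    """

    X: sp.spmatrix | np.ndarray
    obs: pd.DataFrame
    var: pd.DataFrame
    source: CountMatrix | None = field(default=None, repr=False)

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X.shape[1]

    @property
    def gene_symbols(self) -> pd.Index:
        return self.var.index

    def to_dense(self) -> np.ndarray:
        if sp.issparse(self.X):
            return np.asarray(self.X.todense(), dtype=float)
        return np.asarray(self.X, dtype=float)

    def subset_cells(self, mask_or_idx) -> "NormalizedMatrix":
        idx = _as_row_index(mask_or_idx, self.n_cells)
        X = self.X[idx] if sp.issparse(self.X) else self.X[idx, :]
        return NormalizedMatrix(X, self.obs.iloc[idx].copy(), self.var.copy())

    def subset_genes(self, mask_or_idx) -> "NormalizedMatrix":
        idx = _as_row_index(mask_or_idx, self.n_genes)
        return NormalizedMatrix(self.X[:, idx], self.obs.copy(), self.var.iloc[idx].copy())

    def gene_values(self, symbol: str) -> np.ndarray:
        j = self.var.index.get_loc(symbol)
        col = self.X[:, j]
        return np.asarray(col.todense()).ravel() if sp.issparse(col) else np.asarray(col).ravel()

    def copy(self) -> "NormalizedMatrix":
        return NormalizedMatrix(self.X.copy(), self.obs.copy(), self.var.copy(), self.source)


@dataclass
class QCReport:
    """Book-keeping for one ``filter_cells`` pass."""

    n_input: int
    n_retained: int
    removed_min_genes: int
    removed_doublet: int
    removed_mito: int
    removed_union: int
    min_genes: int
    doublet_quantile: float
    mito_max: float
    genes_cutoff: float
    umis_cutoff: float
    warnings: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rule": ["min_genes", "doublet_quantile", "mito_fraction", "union"],
                "removed": [
                    self.removed_min_genes,
                    self.removed_doublet,
                    self.removed_mito,
                    self.removed_union,
                ],
                "threshold": [
                    self.min_genes,
                    self.doublet_quantile,
                    self.mito_max,
                    np.nan,
                ],
            }
        )


def _as_row_index(mask_or_idx, n: int) -> np.ndarray:
    arr = np.asarray(mask_or_idx)
    if arr.dtype == bool:
        if arr.size != n:
            raise ValueError(f"boolean mask of length {arr.size} for axis of size {n}")
        return np.flatnonzero(arr)
    return arr.astype(int)


def flag_mito_genes(
    symbols: Iterable[str], explicit: Sequence[str] | None = None
) -> np.ndarray:
    """Boolean mitochondrial flags by symbol prefix or an explicit list."""
    symbols = list(symbols)
    if explicit is not None:
        explicit_set = set(explicit)
        return np.array([s in explicit_set for s in symbols])
    return np.array([s.startswith(MITO_PREFIXES) for s in symbols])


# ---------------------------------------------------------------------------
# 10x MTX reading
# ---------------------------------------------------------------------------

def _find_file(directory: Path, stems: Sequence[str]) -> Path:
    for stem in stems:
        for name in (stem, stem + ".gz"):
            p = directory / name
            if p.exists():
                return p
    raise FileNotFoundError(
        f"none of {stems} (or .gz variants) found in {directory}"
    )


def _read_tsv_lines(path: Path) -> list[list[str]]:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [line.rstrip("\n").split("\t") for line in fh if line.strip()]


def deduplicate_symbols(symbols: Sequence[str]) -> list[str]:
    """Deterministic deduplication: repeats get suffixes ``.1``, ``.2``, ...."""
    seen: dict[str, int] = {}
    out = []
    for s in symbols:
        if s in seen:
            seen[s] += 1
            out.append(f"{s}.{seen[s]}")
        else:
            seen[s] = 0
            out.append(s)
    return out


def read_10x_mtx(
    directory: str | os.PathLike,
    mito_genes: Sequence[str] | None = None,
) -> CountMatrix:
    """Read a 10x-style MTX triplet directory into a :class:`CountMatrix`.

    Accepts plain or gzipped ``matrix.mtx`` with ``barcodes.tsv`` and
    ``features.tsv``/``genes.tsv``. The on-disk matrix may be stored either
    genes × cells (10x convention) or cells × genes; the result is always
    cells × genes. Duplicate gene symbols are disambiguated with ``.1``,
    ``.2``, ... suffixes in file order.
    """
    directory = Path(directory)
    mtx_path = _find_file(directory, ["matrix.mtx"])
    bc_path = _find_file(directory, ["barcodes.tsv"])
    ft_path = _find_file(directory, ["features.tsv", "genes.tsv"])

    X = sp.csr_matrix(scipy.io.mmread(str(mtx_path)))
    barcodes = [row[0] for row in _read_tsv_lines(bc_path)]
    feat_rows = _read_tsv_lines(ft_path)
    symbols = [row[1] if len(row) > 1 else row[0] for row in feat_rows]

    n_cells, n_genes = len(barcodes), len(symbols)
    if X.shape == (n_genes, n_cells) and n_genes != n_cells:
        X = sp.csr_matrix(X.T)
    elif X.shape == (n_cells, n_genes):
        pass
    elif X.shape == (n_genes, n_cells):  # square case: keep 10x orientation
        X = sp.csr_matrix(X.T)
    else:
        raise ValueError(
            f"dimension mismatch: {mtx_path.name} is {X.shape} but "
            f"{bc_path.name} lists {n_cells} barcodes and "
            f"{ft_path.name} lists {n_genes} features"
        )

    symbols = deduplicate_symbols(symbols)
    obs = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))
    var = pd.DataFrame(index=pd.Index(symbols, name="symbol"))
    var["mito"] = flag_mito_genes(symbols, explicit=mito_genes)
    return CountMatrix(X, obs, var)


# ---------------------------------------------------------------------------
# QC filtering and normalization
# ---------------------------------------------------------------------------

def filter_cells(
    matrix: CountMatrix,
    min_genes: int = 500,
    doublet_quantile: float = 0.98,
    mito_max: float = 0.10,
) -> tuple[CountMatrix, QCReport]:
    """Apply the three QC rules in one pass against the unfiltered input.

    Rules (each evaluated on the full input matrix, so per-rule counts are
    unambiguous and a cell may trip several):

    1. detected genes < ``min_genes``;
    2. detected genes **or** total UMIs strictly above the
       ``doublet_quantile`` sample quantile (linear-interpolation quantile;
       strictness means an all-tied input removes nothing);
    3. mitochondrial read fraction strictly above ``mito_max`` (skipped with
       a recorded warning when no gene is flagged mitochondrial).
    """
    if matrix.n_cells == 0:
        raise ValueError("cannot QC-filter a matrix with zero cells")

    warnings: list[str] = []
    detected = matrix.n_detected
    ls = matrix.library_size

    low = detected < min_genes

    genes_cutoff = float(np.quantile(detected, doublet_quantile))
    umis_cutoff = float(np.quantile(ls, doublet_quantile))
    doublet = (detected > genes_cutoff) | (ls > umis_cutoff)

    if matrix.var["mito"].any():
        mito = matrix.mito_fraction() > mito_max
    else:
        warnings.append("no mitochondrial genes flagged; mito rule skipped")
        logger.warning("filter_cells: %s", warnings[-1])
        mito = np.zeros(matrix.n_cells, dtype=bool)

    remove = low | doublet | mito
    keep = ~remove
    report = QCReport(
        n_input=matrix.n_cells,
        n_retained=int(keep.sum()),
        removed_min_genes=int(low.sum()),
        removed_doublet=int(doublet.sum()),
        removed_mito=int(mito.sum()),
        removed_union=int(remove.sum()),
        min_genes=min_genes,
        doublet_quantile=doublet_quantile,
        mito_max=mito_max,
        genes_cutoff=genes_cutoff,
        umis_cutoff=umis_cutoff,
        warnings=warnings,
    )
    return matrix.subset_cells(keep), report


def normalize(matrix: CountMatrix, scale: float = 1e4) -> NormalizedMatrix:
    """Library-size normalize and natural-log transform.

    ``norm_ji = ln(1 + scale * raw_ji / LS_j)``; the sparsity pattern of the
    input is preserved exactly (zeros map to zero).
    """
    ls = matrix.library_size.astype(float)
    if np.any(ls == 0):
        n0 = int((ls == 0).sum())
        raise ValueError(
            f"{n0} cells have zero total UMIs; run filter_cells before normalize"
        )
    X = matrix.X.tocsr().astype(float)
    row_scale = scale / ls
    X = sp.diags(row_scale) @ X
    X.data = np.log1p(X.data)
    return NormalizedMatrix(sp.csr_matrix(X), matrix.obs.copy(), matrix.var.copy(), matrix)


# ---------------------------------------------------------------------------
# Human-data helpers
# ---------------------------------------------------------------------------

def select_cd4_t_cells(
    matrix: CountMatrix,
    cd4_symbol: str = "CD4",
    cd3_symbols: Sequence[str] = ("CD3D", "CD3E", "CD3G"),
) -> CountMatrix:
    """Keep cells with ≥1 read of CD4 AND ≥1 read of any CD3 chain gene."""
    if cd4_symbol not in matrix.gene_symbols:
        raise KeyError(f"CD4 symbol {cd4_symbol!r} not found in gene table")
    present_cd3 = [s for s in cd3_symbols if s in matrix.gene_symbols]
    if not present_cd3:
        logger.warning("select_cd4_t_cells: none of %s present", list(cd3_symbols))
    cd4_idx = matrix.var.index.get_loc(cd4_symbol)
    cd4_pos = np.asarray(matrix.X[:, cd4_idx].todense()).ravel() >= 1
    if present_cd3:
        cd3_cols = [matrix.var.index.get_loc(s) for s in present_cd3]
        cd3_pos = np.asarray(matrix.X[:, cd3_cols].max(axis=1).todense()).ravel() >= 1
    else:
        cd3_pos = np.zeros(matrix.n_cells, dtype=bool)
    return matrix.subset_cells(cd4_pos & cd3_pos)


def translate_symbols(
    genes: Sequence[str],
    mapping: pd.DataFrame | str | os.PathLike,
) -> tuple[list[str], list[str]]:
    """Translate gene symbols through a two-column mapping table.

    ``mapping`` is a DataFrame (or TSV path) whose first column is the source
    symbol and second the target. Duplicate source symbols are resolved by
    first occurrence (collisions logged). Returns the order-preserving list
    of translated symbols and the list of unmapped inputs; nothing is
    silently dropped.
    """
    if not isinstance(mapping, pd.DataFrame):
        mapping = pd.read_csv(mapping, sep="\t", header=None, dtype=str, comment="#")
    if mapping.shape[1] < 2:
        raise ValueError("mapping table needs at least two columns")
    src = mapping.iloc[:, 0].astype(str)
    dst = mapping.iloc[:, 1].astype(str)

    table: dict[str, str] = {}
    for s, d in zip(src, dst):
        if s in table:
            if table[s] != d:
                logger.warning(
                    "translate_symbols: duplicate source %r maps to %r and %r; "
                    "keeping first (%r)", s, table[s], d, table[s],
                )
            continue
        table[s] = d
    if not table:
        logger.warning("translate_symbols: empty mapping; all symbols unmapped")

    translated, unmapped = [], []
    for g in genes:
        if g in table:
            translated.append(table[g])
        else:
            unmapped.append(g)
    return translated, unmapped


# ---------------------------------------------------------------------------
# TSV writers (External Interfaces)
# ---------------------------------------------------------------------------

def write_qc_report(report: QCReport, path: str | os.PathLike) -> None:
    report.to_frame().to_csv(path, sep="\t", index=False)


def read_gene_list(path: str | os.PathLike) -> list[str]:
    """One symbol per line; '#' starts a comment."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                out.append(line)
    return out


def write_gene_list(genes: Sequence[str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(g + "\n")
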