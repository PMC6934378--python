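"""Synthetic multi-tissue, multi-replicate UMI cohorts with known ground truth.

The generator emulates the statistical structure the downstream pipeline
assumes or must defeat: several tissue contexts, each profiled in two
biological replicates; a small number of planted transcriptional programs
(subpopulations) with log-scale gene effects; per-dataset per-gene
multiplicative batch factors; lognormal library sizes; cell doublets formed
by summing two same-dataset singlets; 13 designated mitochondrial genes
(``mt-`` prefixed) with an optional high-mitochondrial contamination mode
that reallocates a cell's UMIs into those genes while preserving its library
size; B-cell-like CD79+ contaminant cells; and an activation-like confound
that up-shifts a signature gene set in a random subset of cells,
independently of program membership.

Counts are Poisson conditional on the per-cell rate (UMI counts are close to
Poisson given the rate); an optional gene-level overdispersion parameter
turns them negative-binomial. Baseline expression is gamma-distributed so a
realistic mean–dispersion trend exists for the binned variable-gene selector
to exploit.
"""

from __future__ import annotations

import os
import shutil
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .io_qc import CountMatrix, MOUSE_MITO_GENES, flag_mito_genes, read_10x_mtx

B_CELL_MARKERS = ("Cd79a", "Cd79b")

#: Share of the total baseline rate carried by mitochondrial genes in a
#: normal cell (~4%, comfortably below the 10% QC cutoff).
MITO_BASELINE_SHARE = 0.04


@dataclass
class CohortConfig:
    """Parameters of one synthetic cohort.

    Defaults describe a desk-scale version of a multi-tissue CD4 T-cell
    study: a few thousand cells per dataset, ~2,000-UMI libraries, four
    planted programs with e-fold effects around 3, a 2% doublet rate and 13
    mitochondrial genes.
    """

    n_datasets: int = 2  # tissue contexts
    replicates_per_dataset: int = 2
    cells_per_dataset: int = 1000
    n_genes: int = 1000
    n_programs: int = 4
    program_effect: float = float(np.log(3.0))  # natural-log units
    program_gene_fraction: float = 0.03
    batch_sd: float = 0.3
    libsize_log_mean: float = float(np.log(4000.0))
    libsize_log_sd: float = 0.3
    doublet_rate: float = 0.02
    n_mito_genes: int = 13
    mito_high_fraction: float = 0.25  # UMI share moved into mt- genes
    mito_high_rate: float = 0.02  # fraction of cells affected
    contaminant_rate: float = 0.0
    confound_rate: float = 0.0
    confound_effect: float = 0.0
    overdispersion: float = 0.0  # gene-level NB overdispersion; 0 = Poisson
    seed: int = 0

    def validate(self) -> None:
        fractions = {
            "program_gene_fraction": self.program_gene_fraction,
            "doublet_rate": self.doublet_rate,
            "mito_high_fraction": self.mito_high_fraction,
            "mito_high_rate": self.mito_high_rate,
            "contaminant_rate": self.contaminant_rate,
            "confound_rate": self.confound_rate,
        }
        for name, value in fractions.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} outside [0, 1]")
        for name in ("n_datasets", "replicates_per_dataset", "n_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.cells_per_dataset < 0:
            raise ValueError("cells_per_dataset must be non-negative")
        if self.n_programs < 1:
            raise ValueError("n_programs must be at least 1")
        if self.n_mito_genes > self.n_genes:
            raise ValueError("n_mito_genes exceeds n_genes")
        if 0 < self.cells_per_dataset < self.n_programs:
            raise ValueError(
                f"cells_per_dataset={self.cells_per_dataset} cannot seat "
                f"{self.n_programs} programs"
            )


@dataclass
class SyntheticTruth:
    """Ground truth for one generated dataset (tissue × replicate).

    ``cells`` records per-cell program label and doublet / contaminant /
    high-mito / confounded flags (doublets record both parent barcodes);
    ``genes`` records the shared baseline rate, this dataset's per-gene batch
    factor and each gene's program membership.
    """

    dataset: str
    tissue: str
    replicate: int
    cells: pd.DataFrame
    genes: pd.DataFrame
    program_effect: float

    def copy(self) -> "SyntheticTruth":
        return SyntheticTruth(
            self.dataset, self.tissue, self.replicate,
            self.cells.copy(), self.genes.copy(), self.program_effect,
        )


def _gene_symbols(config: CohortConfig) -> list[str]:
    symbols: list[str] = []
    if config.n_mito_genes <= len(MOUSE_MITO_GENES):
        symbols += list(MOUSE_MITO_GENES[: config.n_mito_genes])
    else:
        symbols += list(MOUSE_MITO_GENES)
        symbols += [f"mt-Extra{i}" for i in range(config.n_mito_genes - len(MOUSE_MITO_GENES))]
    for marker in B_CELL_MARKERS:
        if len(symbols) < config.n_genes:
            symbols.append(marker)
    i = 0
    while len(symbols) < config.n_genes:
        symbols.append(f"Gene{i:05d}")
        i += 1
    return symbols[: config.n_genes]


def _baseline_and_programs(config: CohortConfig, rng: np.random.Generator):
    """Shared (cross-dataset) baseline rates and program gene assignments."""
    baseline = rng.gamma(shape=0.7, scale=1.0, size=config.n_genes) + 1e-4
    symbols = _gene_symbols(config)
    mito = flag_mito_genes(symbols)
    # pin the mitochondrial share of the baseline to a realistic level
    if mito.any() and MITO_BASELINE_SHARE > 0:
        non_mito_sum = baseline[~mito].sum()
        target = MITO_BASELINE_SHARE / (1 - MITO_BASELINE_SHARE) * non_mito_sum
        baseline[mito] *= target / baseline[mito].sum()

    # B-cell markers are essentially silent in T cells (detection well below
    # 1%), so the contaminant purge rules have a meaningful baseline
    marker_idx = {s: j for j, s in enumerate(symbols) if s in B_CELL_MARKERS}
    for j in marker_idx.values():
        baseline[j] = 1e-3
    eligible = np.flatnonzero(~mito & ~np.isin(symbols, B_CELL_MARKERS))
    n_per_program = max(1, round(config.program_gene_fraction * config.n_genes))
    if n_per_program * config.n_programs > eligible.size:
        raise ValueError("not enough genes to assign disjoint program gene sets")
    chosen = rng.choice(eligible, size=n_per_program * config.n_programs, replace=False)
    program_genes = {
        p: np.sort(chosen[p * n_per_program : (p + 1) * n_per_program])
        for p in range(config.n_programs)
    }
    return symbols, baseline, mito, program_genes, marker_idx


def _dataset_counts(
    config: CohortConfig,
    rng: np.random.Generator,
    baseline: np.ndarray,
    mito: np.ndarray,
    program_genes: dict[int, np.ndarray],
) -> tuple[sp.csr_matrix, pd.DataFrame, np.ndarray]:
    """Counts, per-cell truth and batch factors for one tissue × replicate."""
    G = config.n_genes
    n_cells = config.cells_per_dataset
    batch = rng.lognormal(mean=0.0, sigma=config.batch_sd, size=G)

    if n_cells == 0:
        cells = pd.DataFrame(
            columns=["program", "doublet", "parent1", "parent2",
                     "contaminant", "high_mito", "confounded"]
        )
        return sp.csr_matrix((0, G), dtype=np.int64), cells, batch

    n_doublets = round(config.doublet_rate * n_cells)
    n_singlets = n_cells - n_doublets
    if n_doublets > 0 and n_singlets < 2:
        raise ValueError("too few singlets to form doublets")

    # per-program rate vectors (shared baseline × dataset batch × effect)
    rates = np.tile(baseline * batch, (config.n_programs, 1))
    eff = np.exp(config.program_effect)
    for p, genes in program_genes.items():
        rates[p, genes] *= eff
    rates /= rates.sum(axis=1, keepdims=True)

    labels = np.arange(n_singlets) % config.n_programs
    rng.shuffle(labels)
    ls = rng.lognormal(config.libsize_log_mean, config.libsize_log_sd, size=n_singlets)

    mean = ls[:, None] * rates[labels]
    if config.overdispersion > 0:
        od = config.overdispersion
        mean = mean * rng.gamma(shape=1.0 / od, scale=od, size=mean.shape)
    counts = rng.poisson(mean).astype(np.int64)

    # high-mitochondrial cells: reallocate UMIs into mt- genes, LS preserved
    high_mito = np.zeros(n_singlets, dtype=bool)
    n_high = round(config.mito_high_rate * n_singlets)
    if n_high > 0 and mito.any():
        victims = rng.choice(n_singlets, size=n_high, replace=False)
        high_mito[victims] = True
        mito_idx = np.flatnonzero(mito)
        mito_probs = baseline[mito] / baseline[mito].sum()
        for j in victims:
            total = counts[j].sum()
            target = int(round(config.mito_high_fraction * total))
            deficit = target - counts[j, mito_idx].sum()
            if deficit <= 0:
                continue
            nonmito_idx = np.flatnonzero(~mito)
            pool = counts[j, nonmito_idx]
            deficit = min(deficit, int(pool.sum()))
            removed = rng.multivariate_hypergeometric(pool, deficit)
            counts[j, nonmito_idx] -= removed
            counts[j, mito_idx] += rng.multinomial(deficit, mito_probs)

    barcodes = [f"CELL{i:05d}" for i in range(n_cells)]
    program_col = [f"P{p}" for p in labels] + [""] * n_doublets
    doublet_col = [False] * n_singlets + [True] * n_doublets
    parent1 = [""] * n_cells
    parent2 = [""] * n_cells

    if n_doublets > 0:
        doublet_rows = np.zeros((n_doublets, G), dtype=np.int64)
        for d in range(n_doublets):
            a, b = rng.choice(n_singlets, size=2, replace=False)
            doublet_rows[d] = counts[a] + counts[b]
            parent1[n_singlets + d] = barcodes[a]
            parent2[n_singlets + d] = barcodes[b]
            program_col[n_singlets + d] = f"P{labels[a]}+P{labels[b]}"
        counts = np.vstack([counts, doublet_rows])
        high_mito = np.concatenate([high_mito, np.zeros(n_doublets, dtype=bool)])

    cells = pd.DataFrame(
        {
            "program": program_col,
            "doublet": doublet_col,
            "parent1": parent1,
            "parent2": parent2,
            "contaminant": False,
            "high_mito": high_mito,
            "confounded": False,
        },
        index=pd.Index(barcodes, name="barcode"),
    )
    return sp.csr_matrix(counts), cells, batch


def generate_cohort(config: CohortConfig) -> list[tuple[CountMatrix, SyntheticTruth]]:
    """Generate one (CountMatrix, SyntheticTruth) pair per tissue × replicate.

    Baselines and program gene sets are shared across all datasets (so that
    with ``batch_sd=0`` replicates have identical per-gene expected means);
    batch factors, library sizes and counts are drawn per dataset. Fixing
    ``config.seed`` reproduces the cohort bit-identically.
    """
    config.validate()
    root_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    symbols, baseline, mito, program_genes, _ = _baseline_and_programs(config, root_rng)

    gene_program = np.array([""] * config.n_genes, dtype=object)
    for p, genes in program_genes.items():
        gene_program[genes] = f"P{p}"

    out: list[tuple[CountMatrix, SyntheticTruth]] = []
    ds_index = 0
    for t in range(config.n_datasets):
        for r in range(1, config.replicates_per_dataset + 1):
            ds_index += 1
            rng = np.random.default_rng(np.random.SeedSequence([config.seed, ds_index]))
            X, cells, batch = _dataset_counts(config, rng, baseline, mito, program_genes)
            tissue = f"tissue{t}"
            dataset = f"{tissue}_rep{r}"
            barcodes = [f"{dataset}-{bc}" for bc in cells.index]
            obs = pd.DataFrame(
                {"dataset": dataset, "tissue": tissue, "replicate": r},
                index=pd.Index(barcodes, name="barcode"),
            )
            var = pd.DataFrame(index=pd.Index(symbols, name="symbol"))
            var["mito"] = mito
            genes = pd.DataFrame(
                {"baseline": baseline, "batch_factor": batch, "program": gene_program},
                index=pd.Index(symbols, name="symbol"),
            )
            truth_cells = cells.copy()
            truth_cells.index = pd.Index(barcodes, name="barcode")
            truth_cells["parent1"] = [
                f"{dataset}-{p}" if p else "" for p in truth_cells["parent1"]
            ]
            truth_cells["parent2"] = [
                f"{dataset}-{p}" if p else "" for p in truth_cells["parent2"]
            ]
            matrix = CountMatrix(X, obs, var)
            truth = SyntheticTruth(dataset, tissue, r, truth_cells, genes,
                                   config.program_effect)
            if config.contaminant_rate > 0:
                matrix, truth = spike_contaminants(
                    matrix, truth, config.contaminant_rate,
                    seed=int(rng.integers(2**31)),
                )
            if config.confound_rate > 0 and config.confound_effect != 0:
                sig = [s for s in symbols if truth.genes.loc[s, "program"] == "P0"]
                matrix, truth = spike_confound(
                    matrix, truth, sig, config.confound_rate,
                    config.confound_effect, seed=int(rng.integers(2**31)),
                )
            out.append((matrix, truth))
    return out


def spike_contaminants(
    matrix: CountMatrix,
    truth: SyntheticTruth,
    rate: float,
    marker_symbols: Sequence[str] = B_CELL_MARKERS,
    effect: float | None = None,
    seed: int = 0,
) -> tuple[CountMatrix, SyntheticTruth]:
    """Replace a ``rate`` fraction of cells with CD79+ contaminant profiles.

    Contaminants keep their library size in expectation but lose the planted
    T-cell program effect and gain a strong marker-gene shift (``effect``
    defaults to twice the cohort's program effect, and marker detection is
    forced to 1 so downstream purge rules have an unambiguous target).
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"rate={rate} outside [0, 1]")
    missing = [s for s in marker_symbols if s not in matrix.gene_symbols]
    if missing:
        raise KeyError(f"marker symbols absent from gene table: {missing}")
    if rate == 0 or matrix.n_cells == 0:
        return matrix, truth

    rng = np.random.default_rng(seed)
    if effect is None:
        effect = 2.0 * max(truth.program_effect, np.log(2.0))
    n_spike = round(rate * matrix.n_cells)
    eligible = np.flatnonzero(~truth.cells["doublet"].to_numpy())
    if n_spike > eligible.size:
        raise ValueError("not enough singlet cells to replace with contaminants")
    victims = rng.choice(eligible, size=n_spike, replace=False)

    baseline = truth.genes["baseline"].to_numpy(float)
    batch = truth.genes["batch_factor"].to_numpy(float)
    p = baseline * batch
    marker_cols = np.array([matrix.var.index.get_loc(s) for s in marker_symbols])
    p = p.copy()
    p[marker_cols] = np.maximum(p[marker_cols], np.median(p)) * np.exp(effect)
    p /= p.sum()

    X = matrix.X.tolil()
    ls = matrix.library_size
    for j in victims:
        counts = rng.poisson(max(ls[j], 1) * p)
        counts[marker_cols] = np.maximum(counts[marker_cols], 1)
        X.rows[j] = list(np.flatnonzero(counts))
        X.data[j] = list(counts[counts > 0])
    new = CountMatrix(sp.csr_matrix(X), matrix.obs.copy(), matrix.var.copy())

    truth = truth.copy()
    truth.cells.iloc[victims, truth.cells.columns.get_loc("contaminant")] = True
    truth.cells.iloc[victims, truth.cells.columns.get_loc("program")] = "contaminant"
    return new, truth


def spike_confound(
    matrix: CountMatrix,
    truth: SyntheticTruth,
    signature_genes: Sequence[str],
    rate: float,
    effect: float,
    seed: int = 0,
) -> tuple[CountMatrix, SyntheticTruth]:
    """Up-shift a signature gene set in a random subset of cells.

    The selected cells receive extra counts ``Poisson((e^effect − 1)·raw)``
    on the signature genes, which multiplies the Poisson mean by
    ``e^effect`` and leaves the matrix exactly unchanged at ``effect=0``.
    Selection is uniform over cells, independent of program labels.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"rate={rate} outside [0, 1]")
    genes = [g for g in signature_genes if g in matrix.gene_symbols]
    if not signature_genes:
        raise ValueError("empty confound signature")
    if not genes:
        raise KeyError("none of the signature genes present in gene table")

    rng = np.random.default_rng(seed)
    n_spike = round(rate * matrix.n_cells)
    truth = truth.copy()
    if n_spike == 0 or effect == 0:
        return matrix, truth
    victims = rng.choice(matrix.n_cells, size=n_spike, replace=False)
    cols = np.array([matrix.var.index.get_loc(g) for g in genes])

    X = matrix.X.tocsc(copy=True).astype(np.int64)
    factor = np.exp(effect) - 1.0
    victim_mask = np.zeros(matrix.n_cells, dtype=bool)
    victim_mask[victims] = True
    for c in cols:
        start, end = X.indptr[c], X.indptr[c + 1]
        rows = X.indices[start:end]
        sel = victim_mask[rows]
        if sel.any():
            extra = rng.poisson(factor * X.data[start:end][sel])
            X.data[start:end][sel] += extra
    new = CountMatrix(sp.csr_matrix(X), matrix.obs.copy(), matrix.var.copy())
    truth.cells.iloc[victims, truth.cells.columns.get_loc("confounded")] = True
    return new, truth


# ---------------------------------------------------------------------------
# Fixture I/O (10x v2 layout + truth tables)
# ---------------------------------------------------------------------------

def write_fixture(
    matrices: Sequence[CountMatrix],
    truths: Sequence[SyntheticTruth],
    directory: str | os.PathLike,
    overwrite: bool = False,
) -> None:
    """Write each dataset as an MTX triplet plus truth TSVs.

    Layout: ``<dir>/<dataset>/{matrix.mtx, barcodes.tsv, features.tsv,
    cells.tsv, truth_cells.tsv, truth_genes.tsv}``. Matrices are stored
    genes × cells (10x convention); the reader round-trips losslessly.
    """
    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()):
        if not overwrite:
            raise FileExistsError(
                f"{directory} exists and is not empty; pass overwrite=True"
            )
        shutil.rmtree(directory)
    directory.mkdir(parents=True, exist_ok=True)

    for matrix, truth in zip(matrices, truths, strict=True):
        sub = directory / truth.dataset
        sub.mkdir()
        scipy.io.mmwrite(
            str(sub / "matrix.mtx"), sp.coo_matrix(matrix.X.T), field="integer"
        )
        with open(sub / "barcodes.tsv", "w") as fh:
            for bc in matrix.obs.index:
                fh.write(bc + "\n")
        with open(sub / "features.tsv", "w") as fh:
            for s in matrix.var.index:
                fh.write(f"{s}\t{s}\tGene Expression\n")
        matrix.obs.to_csv(sub / "cells.tsv", sep="\t")
        truth.cells.to_csv(sub / "truth_cells.tsv", sep="\t")
        truth.genes.to_csv(sub / "truth_genes.tsv", sep="\t")
        with open(sub / "meta.tsv", "w") as fh:
            fh.write("dataset\ttissue\treplicate\tprogram_effect\n")
            fh.write(f"{truth.dataset}\t{truth.tissue}\t{truth.replicate}\t"
                     f"{truth.program_effect}\n")


def read_fixture(directory: str | os.PathLike) -> list[tuple[CountMatrix, SyntheticTruth]]:
    """Read a fixture written by :func:`write_fixture`."""
    directory = Path(directory)
    out = []
    for sub in sorted(p for p in directory.iterdir() if p.is_dir()):
        matrix = read_10x_mtx(sub)
        cells_path = sub / "cells.tsv"
        if cells_path.exists():
            obs = pd.read_csv(cells_path, sep="\t", index_col=0)
            obs.index = obs.index.astype(str)
            matrix = CountMatrix(matrix.X, obs, matrix.var)
        truth_cells = pd.read_csv(sub / "truth_cells.tsv", sep="\t", index_col=0,
                                  keep_default_na=False)
        truth_genes = pd.read_csv(sub / "truth_genes.tsv", sep="\t", index_col=0,
                                  keep_default_na=False)
        meta = pd.read_csv(sub / "meta.tsv", sep="\t")
        truth = SyntheticTruth(
            dataset=str(meta.loc[0, "dataset"]),
            tissue=str(meta.loc[0, "tissue"]),
            replicate=int(meta.loc[0, "replicate"]),
            cells=truth_cells,
            genes=truth_genes,
            program_effect=float(meta.loc[0, "program_effect"]),
        )
        out.append((matrix, truth))
    return out
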