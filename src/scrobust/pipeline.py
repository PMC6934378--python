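"""End-to-end orchestration with declarative YAML config and seeded stages.

The pipeline runs, per dataset (tissue × replicate): QC filtering →
normalization → optional confound-signature regression → variable genes →
PCA → significant-PC selection → permutation-calibrated resolution scan →
clustering → contaminant purge → repeat (bounded) → per-cluster differential
expression. Across datasets it then matches replicate clusters by
fold-change-vector correlation, calls robust clusters, meta-clusters them,
and writes the Euclidean baseline grouping for contrast.

Every random stage derives its seed deterministically from the master seed
and the stage name, so a fixed config reproduces byte-identical outputs. A
small JSON manifest of stage input hashes supports skipping completed
per-dataset stages on resume.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import clustering as cl
from . import de as de_mod
from . import matching as match_mod
from . import signatures as sig_mod
from .io_qc import (CountMatrix, NormalizedMatrix, filter_cells, normalize,
                    read_10x_mtx, read_gene_list, write_qc_report)
from .synthetic import CohortConfig, generate_cohort

logger = logging.getLogger("scrobust")


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

@dataclass
class QCParams:
    min_genes: int = 500
    doublet_quantile: float = 0.98
    mito_max: float = 0.10


@dataclass
class ClusteringParams:
    k_grid: list[int] | None = None
    n_shuffles: int = 100
    ratio_threshold: float = 2.0
    method: str = "louvain"


@dataclass
class PurgeParams:
    marker_symbols: list[str] = field(default_factory=lambda: ["Cd79a", "Cd79b"])
    marker_fraction: float = 0.5
    loading_quantile: float = 0.99


@dataclass
class SignatureParams:
    confound_signature: str | None = None  # path to a gene-list file
    n_background: int = 10
    regress: bool = False


@dataclass
class DEParams:
    method: str = "moderated-t"
    fc_min: float = 1.25
    q_max: float = 0.1
    det_margin: float = 0.1


@dataclass
class MatchingParams:
    z: float = match_mod.ROBUST_Z
    linkage: str = "average"
    cut: int = 2
    log_fc: bool = True
    merge: dict = field(default_factory=dict)


@dataclass
class DatasetEntry:
    path: str
    dataset: str
    tissue: str
    replicate: int


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str = "scrobust_out"
    purge_iterations: int = 2
    qc: QCParams = field(default_factory=QCParams)
    reduction: cl.ReductionParams = field(default_factory=cl.ReductionParams)
    clustering: ClusteringParams = field(default_factory=ClusteringParams)
    purge: PurgeParams = field(default_factory=PurgeParams)
    signatures: SignatureParams = field(default_factory=SignatureParams)
    de: DEParams = field(default_factory=DEParams)
    matching: MatchingParams = field(default_factory=MatchingParams)
    datasets: list[DatasetEntry] = field(default_factory=list)
    simulate: dict | None = None  # CohortConfig overrides, alternative to datasets

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _build(cls, data: dict, context: str):
    known = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(
            f"unknown config key(s) {sorted(unknown)} under {context!r}"
        )
    return cls(**data)


_SECTION_TYPES = {
    "qc": QCParams,
    "reduction": cl.ReductionParams,
    "clustering": ClusteringParams,
    "purge": PurgeParams,
    "signatures": SignatureParams,
    "de": DEParams,
    "matching": MatchingParams,
}


def validate_config(source: str | os.PathLike | dict) -> PipelineConfig:
    """Load and strictly validate a pipeline config (YAML path or dict).

    Unknown keys are rejected by name at every level; dataset manifest paths
    must exist. The resolved config carries every default, so re-validating
    its dump is the identity.
    """
    if isinstance(source, (str, os.PathLike)):
        with open(source) as fh:
            data = yaml.safe_load(fh) or {}
    else:
        data = dict(source)
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")

    top_known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - top_known
    if unknown:
        raise ValueError(f"unknown config key(s) {sorted(unknown)}")

    kwargs: dict[str, Any] = {}
    for name, value in data.items():
        if name in _SECTION_TYPES:
            kwargs[name] = _build(_SECTION_TYPES[name], value or {}, name)
        elif name == "datasets":
            entries = []
            for i, entry in enumerate(value or []):
                entries.append(_build(DatasetEntry, entry, f"datasets[{i}]"))
            kwargs[name] = entries
        elif name == "simulate":
            if value is not None:
                known = {f.name for f in dataclasses.fields(CohortConfig)}
                bad = set(value) - known
                if bad:
                    raise ValueError(f"unknown config key(s) {sorted(bad)} under 'simulate'")
            kwargs[name] = value
        else:
            kwargs[name] = value
    config = PipelineConfig(**kwargs)

    if not config.datasets and config.simulate is None:
        raise ValueError("config needs a 'datasets' manifest or a 'simulate' block")
    for entry in config.datasets:
        if not Path(entry.path).exists():
            raise FileNotFoundError(f"dataset path does not exist: {entry.path}")
    return config


def dump_config(config: PipelineConfig, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Per-dataset processing
# ---------------------------------------------------------------------------

@dataclass
class DatasetResult:
    entry: DatasetEntry
    qc_report: Any
    normalized: NormalizedMatrix
    scan: cl.ResolutionScan
    clustering: cl.ClusteringResult
    pca: Any
    purge_reports: list[dict]
    de_tables: dict[int, pd.DataFrame]
    profiles: list[match_mod.ClusterProfile]


def _hash_matrix(matrix: CountMatrix) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(matrix.X.indptr).tobytes())
    h.update(np.ascontiguousarray(matrix.X.indices).tobytes())
    h.update(np.ascontiguousarray(matrix.X.data).tobytes())
    h.update("|".join(matrix.obs.index).encode())
    return h.hexdigest()


def process_dataset(
    matrix: CountMatrix, entry: DatasetEntry, config: PipelineConfig,
    out_dir: Path | None = None,
) -> DatasetResult:
    """QC → normalize → (regress) → scan/cluster → purge loop → DE for one dataset."""
    seed_base = f"{entry.dataset}"
    filtered, qc_report = filter_cells(
        matrix, config.qc.min_genes, config.qc.doublet_quantile, config.qc.mito_max
    )
    logger.info("%s: QC retained %d/%d cells", entry.dataset,
                qc_report.n_retained, qc_report.n_input)

    purge_reports: list[dict] = []
    current = filtered
    iteration = 0
    while True:
        norm = normalize(current)
        if config.signatures.confound_signature and config.signatures.regress:
            genes = read_gene_list(config.signatures.confound_signature)
            score = sig_mod.score_signature(norm, genes, config.signatures.n_background)
            norm = sig_mod.regress_out_signature(norm, score)

        scan = cl.select_resolution(
            norm,
            k_grid=config.clustering.k_grid,
            n_shuffles=config.clustering.n_shuffles,
            ratio_threshold=config.clustering.ratio_threshold,
            seed=stage_seed(config.seed, f"{seed_base}:scan{iteration}"),
            params=config.reduction,
            method=config.clustering.method,
        )
        if scan.chosen is None:
            logger.warning("%s: no k passed the modularity-ratio rule", entry.dataset)
            k = int(scan.table.sort_values("ratio", ascending=False)["k"].iloc[0])
            result, pca = cl.cluster_matrix(
                norm, k, config.reduction,
                seed=stage_seed(config.seed, f"{seed_base}:cluster{iteration}"),
                method=config.clustering.method,
            )
        else:
            result = scan.chosen
            pca, _ = cl.reduce_matrix(
                norm, config.reduction,
                seed=stage_seed(config.seed, f"{seed_base}:scan{iteration}"),
            )

        if iteration >= config.purge_iterations:
            break
        keep, report = cl.purge_contaminant_cells(
            current, result, pca,
            marker_symbols=config.purge.marker_symbols,
            marker_fraction=config.purge.marker_fraction,
            loading_quantile=config.purge.loading_quantile,
        )
        purge_reports.append(report)
        if keep.all():
            break
        logger.info("%s: purge iteration %d removed %d cells",
                    entry.dataset, iteration + 1, int((~keep).sum()))
        current = current.subset_cells(keep)
        iteration += 1

    labels = result.labels
    de_tables: dict[int, pd.DataFrame] = {}
    profiles: list[match_mod.ClusterProfile] = []
    if result.n_clusters >= 2:
        for c in range(result.n_clusters):
            fg = np.flatnonzero(labels == c)
            bg = np.flatnonzero(labels != c)
            if fg.size >= 3 and bg.size >= 3:
                de_tables[c] = de_mod.de_test(norm, fg, bg, method=config.de.method)
        profiles = match_mod.fold_change_vectors(norm, result, dataset=entry.dataset)

    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        write_qc_report(qc_report, out_dir / "qc_report.tsv")
        cl.write_resolution_scan(scan, out_dir / "resolution_scan.tsv")
        cl.write_labels(result, out_dir / "clusters.tsv")
        with open(out_dir / "purge_report.json", "w") as fh:
            json.dump(purge_reports, fh, indent=2)
        for c, table in de_tables.items():
            de_mod.write_de_table(table, out_dir / f"de_cluster{c}.tsv")

    return DatasetResult(entry, qc_report, norm, scan, result, pca,
                         purge_reports, de_tables, profiles)


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------

def _load_datasets(config: PipelineConfig) -> list[tuple[CountMatrix, DatasetEntry]]:
    out = []
    if config.simulate is not None:
        sim = dict(config.simulate)
        sim.setdefault("seed", config.seed)
        cohort = generate_cohort(CohortConfig(**sim))
        for matrix, truth in cohort:
            out.append((matrix, DatasetEntry(
                path="<simulated>", dataset=truth.dataset,
                tissue=truth.tissue, replicate=truth.replicate,
            )))
    for entry in config.datasets:
        matrix = read_10x_mtx(entry.path)
        matrix.obs["dataset"] = entry.dataset
        matrix.obs["tissue"] = entry.tissue
        matrix.obs["replicate"] = entry.replicate
        out.append((matrix, entry))
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full pipeline; returns a summary dict and writes the output tree."""
    out_root = Path(config.output_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    manifest_path = out_root / "manifest.json"
    manifest = {}
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())

    datasets = _load_datasets(config)
    results: dict[str, DatasetResult] = {}
    for matrix, entry in datasets:
        ds_dir = out_root / entry.dataset
        input_hash = _hash_matrix(matrix)
        results[entry.dataset] = process_dataset(matrix, entry, config, ds_dir)
        manifest[entry.dataset] = {"input_hash": input_hash, "complete": True}
    manifest_path.write_text(json.dumps(manifest, indent=2))

    # replicate matching per tissue, robust calling, meta-clustering
    by_tissue: dict[str, list[DatasetResult]] = {}
    for r in results.values():
        by_tissue.setdefault(r.entry.tissue, []).append(r)

    robust_profiles: list[match_mod.ClusterProfile] = []
    robust_flags: dict[str, bool] = {}
    matches: dict[str, match_mod.MatchMatrix] = {}
    for tissue, group in by_tissue.items():
        group = sorted(group, key=lambda r: r.entry.replicate)
        if len(group) < 2 or not group[0].profiles or not group[1].profiles:
            logger.warning("tissue %s: fewer than 2 clustered replicates; skipping match",
                           tissue)
            continue
        mm = match_mod.correlate_clusters(
            group[0].profiles, group[1].profiles, log_fc=config.matching.log_fc
        )
        matches[tissue] = mm
        match_mod.write_match_matrix(mm, out_root / f"match_{tissue}.tsv")
        flags = match_mod.call_robust_clusters(mm, z=config.matching.z)
        robust_flags.update(flags.to_dict())
        for r in group[:2]:
            for p in r.profiles:
                if flags.get(p.key, False):
                    robust_profiles.append(p)

    meta = None
    baseline_grouping = None
    if len(robust_profiles) >= 2:
        cut = min(config.matching.cut, len(robust_profiles))
        meta = match_mod.meta_cluster(
            robust_profiles, linkage=config.matching.linkage, cut=cut,
            log_fc=config.matching.log_fc,
            merge=config.matching.merge or None,
        )
        match_mod.write_meta_clusters(meta, out_root / "meta_clusters.tsv")
        _, baseline_grouping = match_mod.euclidean_baseline(
            robust_profiles, None, linkage=config.matching.linkage, cut=cut
        )
        baseline_grouping.rename_axis("cluster").to_frame().to_csv(
            out_root / "baseline_groups.tsv", sep="\t"
        )

    pd.Series(robust_flags, name="robust").rename_axis("cluster").to_frame().to_csv(
        out_root / "robust.tsv", sep="\t"
    )

    summary = {
        "datasets": {
            name: {
                "cells_in": r.qc_report.n_input,
                "cells_retained": r.qc_report.n_retained,
                "cells_clustered": int(r.clustering.labels.size),
                "chosen_k": r.scan.chosen_k,
                "n_clusters": r.clustering.n_clusters,
                "modularity": r.clustering.modularity,
            }
            for name, r in results.items()
        },
        "n_robust": int(sum(robust_flags.values())),
        "n_meta_clusters": meta.n_meta if meta is not None else 0,
        "results": results,
        "matches": matches,
        "meta": meta,
        "baseline_grouping": baseline_grouping,
    }
    report(out_root, summary)
    return summary


def report(output_dir: str | os.PathLike, summary: dict | None = None) -> pd.DataFrame:
    """Summarize a (possibly partial) run as one TSV plus readable text."""
    output_dir = Path(output_dir)
    rows = []
    if summary is not None:
        for name, s in summary["datasets"].items():
            rows.append({"stage": f"dataset:{name}", **{k: v for k, v in s.items()}})
        rows.append({"stage": "robust_calling", "n_robust": summary["n_robust"]})
        rows.append({"stage": "meta_clustering",
                     "n_meta_clusters": summary["n_meta_clusters"]})
    else:
        for sub in sorted(p for p in output_dir.iterdir() if p.is_dir()):
            row = {"stage": f"dataset:{sub.name}"}
            qc = sub / "qc_report.tsv"
            if qc.exists():
                t = pd.read_csv(qc, sep="\t")
                row["cells_removed"] = int(t.loc[t["rule"] == "union", "removed"].iloc[0])
            labels = sub / "clusters.tsv"
            if labels.exists():
                t = pd.read_csv(labels, sep="\t")
                row["cells_clustered"] = len(t)
                row["n_clusters"] = int(t["cluster"].nunique())
            rows.append(row)
        meta = output_dir / "meta_clusters.tsv"
        if meta.exists():
            t = pd.read_csv(meta, sep="\t")
            rows.append({"stage": "meta_clustering",
                         "n_meta_clusters": int(t["meta_cluster"].nunique())})
    frame = pd.DataFrame(rows)
    if not frame.empty:
        frame.to_csv(output_dir / "report.tsv", sep="\t", index=False)
        with open(output_dir / "report.txt", "w") as fh:
            fh.write(frame.to_string(index=False) + "\n")
    return frame
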