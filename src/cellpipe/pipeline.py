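"""Step-wise workflow orchestration.

A pipeline run is described by a plain YAML config: input matrix/metadata
paths, a global seed, an output directory, and an ordered list of stages
with per-stage parameters.  Stages follow a fixed dependency order

    merge -> batch_correct -> outlier_removal -> normalize ->
    gene_filter -> log_transform -> cluster -> de -> gsea

and any of the optional stages (batch correction, outlier removal,
normalization, gene filtering) can be skipped or omitted without breaking
the workflow: a skipped stage passes its input straight through.  Every
stage writes its output matrix and/or reports into the run directory, and
a manifest records the seed, per-stage parameters, and SHA-256 checksums
of every artifact, so identical configs produce identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .batch import BatchAssignment, eb_batch_adjust, median_align
from .core import (
    CellpipeError, Dataset, SampleMetadata, align,
    log_transform, merge_datasets, read_expression_matrix, read_metadata,
    remove_samples, write_expression_matrix, write_metadata,
)
from .de_gsea import de_pairwise, gsea, read_gmt, write_de_csv, write_gsea_csv
from .normalize import mean_align, quantile_normalize, size_factor_normalize
from .quality import (
    apply_gene_filter, cell_norms, detect_outliers, dispersion_table,
    filter_genes, fit_dispersion_trend,
)
from .reduce_cluster import (
    CLUSTER_METHODS, ClusterAssignment, auto_cluster, cluster_hclust,
    cluster_kmeans, cluster_nmf,
)

logger = logging.getLogger(__name__)

STAGE_ORDER = (
    "merge", "batch_correct", "outlier_removal", "normalize",
    "gene_filter", "log_transform", "cluster", "de", "gsea",
)


@dataclass
class PipelineConfig:
    seed: int
    output_dir: str
    matrices: list[str]
    metadata: list[str]
    stages: list[dict]
    delimiter: str = ","

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        inp = raw.get("input", {}) or {}
        return cls(
            seed=int(raw.get("seed", 0)),
            output_dir=str(raw.get("output_dir", "cellpipe_run")),
            matrices=list(inp.get("matrices", []) or []),
            metadata=list(inp.get("metadata", []) or []),
            stages=list(raw.get("stages", []) or []),
            delimiter=str(inp.get("delimiter", ",")),
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def validate_config(config: PipelineConfig) -> list[str]:
    """Return the list of problems; empty means run_pipeline would start."""
    issues: list[str] = []
    if not config.matrices:
        issues.append("input.matrices: at least one expression matrix path is required")
    if config.metadata and len(config.metadata) != len(config.matrices):
        issues.append("input.metadata: must match input.matrices in length (or be empty)")
    names = [s.get("name") for s in config.stages]
    last = -1
    for i, s in enumerate(config.stages):
        name = s.get("name")
        if name not in STAGE_ORDER:
            issues.append(f"stages[{i}]: unknown stage {name!r}")
            continue
        idx = STAGE_ORDER.index(name)
        if idx <= last:
            issues.append(
                f"stages[{i}]: {name!r} violates the dependency order "
                f"{' -> '.join(STAGE_ORDER)}"
            )
        last = max(last, idx)
        if name == "cluster":
            method = s.get("method", "kmeans")
            if method not in CLUSTER_METHODS:
                issues.append(f"stages[{i}]: unknown cluster method {method!r}")
            k = s.get("k")
            if k is not None and not 2 <= int(k) <= 10:
                issues.append(
                    f"stages[{i}]: k={k} outside the supported range [2, 10]"
                )
        if name == "gsea" and not s.get("gmt"):
            issues.append(f"stages[{i}]: gsea requires a 'gmt' path")
    if "de" in names and "cluster" not in names:
        issues.append("stage 'de' requires a 'cluster' stage before it")
    if "gsea" in names and "de" not in names:
        issues.append("stage 'gsea' requires a 'de' stage before it")
    return issues


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_inputs(config: PipelineConfig) -> Dataset:
    datasets = []
    for i, mpath in enumerate(config.matrices):
        matrix = read_expression_matrix(mpath, config.delimiter)
        if config.metadata:
            meta = read_metadata(config.metadata[i], config.delimiter)
            datasets.append(align(matrix, meta))
        else:
            datasets.append(Dataset(matrix, SampleMetadata(list(matrix.sample_ids))))
    return merge_datasets(datasets) if len(datasets) > 1 else datasets[0]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in order; returns the manifest."""
    issues = validate_config(config)
    if issues:
        raise CellpipeError("invalid pipeline config: " + "; ".join(issues))

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset = _load_inputs(config)
    assignment: ClusterAssignment | None = None
    de_results = None
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": []}

    def emit_matrix(stage_i: int, name: str) -> dict:
        path = out / f"{stage_i:02d}_{name}.matrix.csv"
        write_expression_matrix(dataset.matrix, path)
        return {path.name: _sha256(path)}

    def emit_json(stage_i: int, name: str, payload: dict, suffix="report") -> dict:
        path = out / f"{stage_i:02d}_{name}.{suffix}.json"
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
        return {path.name: _sha256(path)}

    for i, stage in enumerate(config.stages, start=1):
        name = stage["name"]
        outputs: dict = {}
        if stage.get("skip"):
            logger.info("stage %s skipped; passing input through", name)
            manifest["stages"].append(
                {"name": name, "skipped": True, "params": {}, "outputs": {}}
            )
            continue

        if name == "merge":
            outputs |= emit_matrix(i, name)
            path = out / f"{i:02d}_merge.metadata.csv"
            write_metadata(dataset.metadata, path)
            outputs[path.name] = _sha256(path)

        elif name == "batch_correct":
            column = stage.get("batch_column", "batch")
            batches = BatchAssignment.from_metadata(dataset.metadata, column)
            if stage.get("method", "median") == "median":
                matrix, report = median_align(dataset.matrix, batches)
                outputs |= emit_json(i, name, report.to_dict())
            else:
                matrix = eb_batch_adjust(dataset.matrix, batches)
            dataset = Dataset(matrix, dataset.metadata)
            outputs |= emit_matrix(i, name)

        elif name == "outlier_removal":
            norms = cell_norms(dataset.matrix)
            report = detect_outliers(
                norms, dataset.matrix.sample_ids,
                z_threshold=float(stage.get("z_threshold", 2.0)),
                n_outliers=stage.get("n_outliers"),
                value_space=dataset.matrix.value_space,
            )
            if report.flagged:
                dataset = remove_samples(dataset, report.flagged)
            outputs |= emit_json(i, name, report.to_dict())
            outputs |= emit_matrix(i, name)

        elif name == "normalize":
            method = stage.get("method", "size-factor")
            if method == "voom":
                raise CellpipeError(
                    "voom produces precision weights for an external "
                    "linear-model engine and is not provided; choose "
                    "quantile, mean-align, or size-factor"
                )
            fn = {"quantile": quantile_normalize, "mean-align": mean_align,
                  "size-factor": size_factor_normalize}.get(method)
            if fn is None:
                raise CellpipeError(f"unknown normalization method {method!r}")
            dataset = Dataset(fn(dataset.matrix), dataset.metadata)
            outputs |= emit_matrix(i, name)

        elif name == "gene_filter":
            table = dispersion_table(dataset.matrix)
            trend = fit_dispersion_trend(table)
            table = filter_genes(
                table, trend,
                mean_threshold=float(stage.get("min_mean", 0.0)),
                dispersion_ratio=float(stage.get("disp_ratio", 1.0)),
            )
            dataset = apply_gene_filter(dataset, table)
            outputs |= emit_json(i, name, {
                "a0": trend.a0, "a1": trend.a1, **table.summary,
                "plot": {"x_log_mean": np.log(
                    table.mean_expr[table.defined]).tolist(),
                    "y_dispersion": table.dispersion[table.defined].tolist()},
            })
            outputs |= emit_matrix(i, name)

        elif name == "log_transform":
            dataset = Dataset(
                log_transform(dataset.matrix,
                              float(stage.get("pseudocount", 1.0))),
                dataset.metadata,
            )
            outputs |= emit_matrix(i, name)

        elif name == "cluster":
            method = stage.get("method", "kmeans")
            k = stage.get("k")
            if k is None:
                k_range = range(int(stage.get("k_min", 2)),
                                int(stage.get("k_max", 10)) + 1)
                assignment, profile = auto_cluster(
                    dataset.matrix, method, seed=config.seed, k_range=k_range,
                )
                outputs |= emit_json(i, name, profile.to_dict(), "evprofile")
            else:
                k = int(k)
                if method == "kmeans":
                    assignment = cluster_kmeans(dataset.matrix, k, seed=config.seed)
                elif method == "hclust":
                    assignment = cluster_hclust(dataset.matrix, k)
                elif method == "nmf":
                    assignment = cluster_nmf(dataset.matrix, k, seed=config.seed)
                else:
                    assignment, _ = auto_cluster(
                        dataset.matrix, method, seed=config.seed,
                        k_range=range(k, k + 1),
                    )
            path = out / f"{i:02d}_cluster.labels.csv"
            pd.DataFrame({"sample": assignment.sample_ids,
                          "cluster": assignment.labels}).to_csv(path, index=False)
            outputs[path.name] = _sha256(path)

        elif name == "de":
            if assignment is None:
                raise CellpipeError("de stage reached without cluster labels")
            de_results = de_pairwise(dataset.matrix, assignment,
                                     n_workers=int(stage.get("workers", 1)))
            for (a, b), ranked in de_results.items():
                path = out / f"{i:02d}_de.{a}_vs_{b}.csv"
                write_de_csv(ranked, path)
                outputs[path.name] = _sha256(path)

        elif name == "gsea":
            if de_results is None:
                raise CellpipeError("gsea stage reached without DE results")
            collection = read_gmt(stage["gmt"])
            for (a, b), ranked in de_results.items():
                results = gsea(
                    ranked, collection,
                    n_perm=int(stage.get("n_perm", 1000)),
                    seed=config.seed,
                    min_size=int(stage.get("min_size", 5)),
                    max_size=int(stage.get("max_size", 500)),
                )
                path = out / f"{i:02d}_gsea.{a}_vs_{b}.csv"
                write_gsea_csv(results, path)
                outputs[path.name] = _sha256(path)

        manifest["stages"].append({
            "name": name, "skipped": False,
            "params": {k: v for k, v in stage.items() if k != "name"},
            "outputs": outputs,
        })

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    return manifest
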