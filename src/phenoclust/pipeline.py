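"""End-to-end orchestration: read -> filter -> dissimilarity -> cluster
-> quality/summary, with optional expression mapping and annotation
composition, writing all reports plus a manifest to an output directory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .annotation import BOOLEAN_ATTRIBUTES, composition, read_annotations
from .cluster import agglomerative, pam
from .dissimilarity import PRESETS, WeightVector, gower_matrix
from .expression import ExpressionMatrix, kmeans_profiles, map_profiles, standardize_rows
from .phenotypes import filter_complete, read_phenotype_table
from .quality import cluster_summary, guideline_check, run_quality, weight_scan

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message is prefixed with the stage name."""


@dataclass
class RunConfig:
    """Configuration for a full pipeline run."""

    phenotypes: str
    out_dir: str
    weights: str | tuple[float, ...] = "W6"
    k: int = 40
    k_values: tuple[int, ...] | None = None  # triggers a scan when set
    method: str = "pam"
    expression: str | None = None
    expression_k: int = 7
    annotations: str | None = None
    attributes: tuple[str, ...] = ()
    min_size: int = 3
    max_k: int = 40
    rsd_limit: float = 15.0
    consensus_min: float = 95.0
    varied_threshold: float = 50.0
    dominance: float = 0.40
    min_genes: int = 3
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        """Load a run configuration from a YAML key-value file.

        Keys mirror the dataclass fields; list values are coerced to
        tuples. Referenced input files must exist.
        """
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in __import__("dataclasses").fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"[config] unknown keys: {sorted(unknown)}")
        for key in ("k_values", "attributes", "weights"):
            if isinstance(raw.get(key), list):
                raw[key] = tuple(raw[key])
        config = cls(**raw)
        for key in ("phenotypes", "expression", "annotations"):
            value = getattr(config, key)
            if value and not Path(value).exists():
                raise PipelineError(f"[config] {key} file not found: {value}")
        return config

    def weight_vector(self) -> WeightVector:
        if isinstance(self.weights, str):
            try:
                return PRESETS[self.weights]
            except KeyError:
                raise PipelineError(
                    f"[config] unknown weight preset {self.weights!r}; "
                    f"choose from {sorted(PRESETS)}"
                ) from None
        return WeightVector(tuple(float(w) for w in self.weights))


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as e:
            raise PipelineError(f"[{name}] {e}") from e

    return wrap


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write reports under ``out_dir``.

    Returns the manifest (also written as ``manifest.json``). Any stage
    failure raises :class:`PipelineError` naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []

    def write(name: str, writer) -> None:
        path = out / name
        writer(path)
        outputs.append(name)

    table = _stage("phenotype_data")(read_phenotype_table, config.phenotypes)
    table = _stage("phenotype_data")(filter_complete, table)
    if len(table) == 0:
        raise PipelineError("[phenotype_data] no complete records to cluster")
    write("phenotypes_complete.csv", table.to_csv)

    weights = config.weight_vector()
    if config.k_values:
        scan = _stage("cluster_quality")(
            weight_scan,
            table,
            [weights],
            list(config.k_values),
            config.method,
            min_size=config.min_size,
            max_k=config.max_k,
            rsd_limit=config.rsd_limit,
            consensus_min=config.consensus_min,
        )
        write("weight_scan.csv", lambda p: scan.to_csv(p, index=False))

    D = _stage("dissimilarity")(gower_matrix, table, weights)
    if config.method == "pam":
        assignment = _stage("partition_clustering")(pam, D, config.k)
    else:
        assignment = _stage("partition_clustering")(agglomerative, D, config.method, config.k)
    write(
        "assignment.csv",
        lambda p: assignment.write(p, out / "assignment.json"),
    )
    outputs.append("assignment.json")

    report = _stage("cluster_quality")(run_quality, assignment, table)
    verdict = guideline_check(
        report,
        min_size=config.min_size,
        max_k=config.max_k,
        rsd_limit=config.rsd_limit,
        consensus_min=config.consensus_min,
    )
    write("quality_per_cluster.csv", lambda p: report.per_cluster.to_csv(p, index=False))
    summary = _stage("cluster_quality")(
        cluster_summary, assignment, table, config.varied_threshold
    )
    write("cluster_summary.csv", lambda p: summary.to_csv(p, index=False))

    expression_summary = None
    if config.expression:
        expr = _stage("expression_profiles")(ExpressionMatrix.from_csv, config.expression)
        expr = _stage("expression_profiles")(standardize_rows, expr)
        profiles = _stage("expression_profiles")(
            kmeans_profiles, expr, config.expression_k, config.seed
        )
        mapping = _stage("expression_profiles")(
            map_profiles, assignment, profiles, config.min_genes, config.dominance
        )
        write("profile_crosstab.csv", mapping.crosstab.to_csv)
        write(
            "profile_map.csv", lambda p: mapping.per_cluster.to_csv(p, index=False)
        )
        expression_summary = {
            "k": config.expression_k,
            "avg_profiles_per_cluster": mapping.avg_profiles_per_cluster,
            "excluded_clusters": list(mapping.excluded_clusters),
            "modal_dominant_profile": mapping.modal_dominant_profile,
            "modal_dominant_share": mapping.modal_dominant_share,
        }

    if config.annotations:
        annotations = _stage("cluster_annotation")(read_annotations, config.annotations)
        attrs = config.attributes or tuple(
            a for a in BOOLEAN_ATTRIBUTES if a in annotations.columns
        )
        for attr in attrs:
            per_cluster, overall = _stage("cluster_annotation")(
                composition, assignment, annotations, attr
            )
            per_cluster["dataset_percent"] = overall
            write(
                f"composition_{attr}.csv",
                lambda p, df=per_cluster: df.to_csv(p, index=False),
            )

    from . import __version__

    manifest = {
        "phenoclust_version": __version__,
        "config": {k: v for k, v in asdict(config).items()},
        "n_genes": len(table),
        "method": config.method,
        "k": config.k,
        "total_cost": assignment.total_cost,
        "composite_consensus": report.composite_consensus,
        "composite_rsd": report.composite_rsd,
        "guidelines": {
            "min_size_ok": verdict.min_size_ok,
            "max_clusters_ok": verdict.max_clusters_ok,
            "rsd_ok": verdict.rsd_ok,
            "consensus_ok": verdict.consensus_ok,
            "passed": verdict.passed,
        },
        "expression": expression_summary,
        "outputs": outputs,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
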