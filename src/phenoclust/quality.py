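"""Cluster-quality statistics, guideline checks and model-selection scans.

Cluster quality for a mixed-trait partition is judged with two bespoke
statistics: the relative standard deviation (per cluster, per continuous
trait: 100 * SD / mean) and the percent consensus (per cluster, per
categorical trait: the share of the modal category). Run-level values
average clusters with equal weight, and two composites summarize a run:
the mean of the two continuous per-trait averages and the mean of the
eight categorical per-trait averages. A run passes the selection
guidelines when no cluster has fewer than 3 genes, there are at most 40
clusters, composite relative SD is below 15% and composite consensus is
at least 95%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .cluster import ClusterAssignment, pam, agglomerative
from .dissimilarity import WeightVector, gower_matrix
from .phenotypes import (
    ALL_TRAITS,
    CATEGORICAL_TRAITS,
    CONTINUOUS_TRAITS,
    PhenotypeTable,
    bin_series,
)

_MEAN_GUARD = 1e-9


def relative_sd(values: Sequence[float]) -> float:
    """Relative standard deviation as a percent: 100 * sample SD / mean.

    Uses the n-1 denominator; a singleton has no spread and returns 0.
    Raises if the mean is not positive (the statistic is undefined).
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("relative_sd of an empty sample is undefined")
    mean = float(x.mean())
    if mean <= _MEAN_GUARD:
        raise ValueError(f"relative_sd undefined for mean {mean} <= {_MEAN_GUARD}")
    if x.size == 1:
        return 0.0
    return float(100.0 * x.std(ddof=1) / mean)


class Consensus(NamedTuple):
    percent: float
    majority: str
    tie: bool


def percent_consensus(
    labels: Sequence[str], vocabulary: Sequence[str] | None = None
) -> Consensus:
    """Share of the modal category in a cluster, as a percent.

    Ties for the modal category are broken by vocabulary order (sorted
    order if no vocabulary is given) and flagged.
    """
    labels = list(labels)
    if not labels:
        raise ValueError("percent_consensus of an empty cluster is undefined")
    counts = pd.Series(labels).value_counts()
    top = counts.max()
    winners = sorted(counts[counts == top].index)
    if vocabulary is not None:
        order = {lab: i for i, lab in enumerate(vocabulary)}
        winners.sort(key=lambda lab: order.get(lab, len(order)))
    return Consensus(float(100.0 * top / len(labels)), winners[0], len(winners) > 1)


@dataclass
class QualityReport:
    """Per-cluster and run-level quality statistics for a clustering run."""

    per_cluster: pd.DataFrame  # cluster, size, rsd_<cont>, consensus_<cat>, majority_<cat>
    per_trait_average: pd.Series  # trait -> run-level average over clusters
    composite_rsd: float  # mean of the 2 continuous per-trait averages
    composite_consensus: float  # mean of the 8 categorical per-trait averages
    method: str = ""
    weights: str = ""
    k: int = 0

    @property
    def min_cluster_size(self) -> int:
        return int(self.per_cluster["size"].min())


def run_quality(assignment: ClusterAssignment, table: PhenotypeTable) -> QualityReport:
    """Quality statistics for one clustering run over the phenotype table.

    Every gene in the assignment must be present in the table. Run-level
    per-trait averages weight clusters equally, regardless of size.
    """
    data = table.data.set_index("gene_id")
    missing = [g for g in assignment.ids if g not in data.index]
    if missing:
        raise ValueError(f"genes in assignment absent from table: {missing[:5]}")
    sub = data.loc[list(assignment.ids)]
    labels = assignment.labels

    rows = []
    for c in range(1, assignment.k + 1):
        grp = sub[labels == c]
        row: dict[str, object] = {"cluster": c, "size": len(grp)}
        for trait in CONTINUOUS_TRAITS:
            row[f"rsd_{trait}"] = relative_sd(grp[trait].astype(float))
        for trait in CATEGORICAL_TRAITS:
            cons = percent_consensus(grp[trait], table.trait_schema(trait).vocabulary)
            row[f"consensus_{trait}"] = cons.percent
            row[f"majority_{trait}"] = cons.majority
        rows.append(row)
    per_cluster = pd.DataFrame(rows)

    per_trait = {}
    for trait in CONTINUOUS_TRAITS:
        per_trait[trait] = float(per_cluster[f"rsd_{trait}"].mean())
    for trait in CATEGORICAL_TRAITS:
        per_trait[trait] = float(per_cluster[f"consensus_{trait}"].mean())
    per_trait_average = pd.Series(per_trait)

    return QualityReport(
        per_cluster=per_cluster,
        per_trait_average=per_trait_average,
        composite_rsd=float(np.mean([per_trait[t] for t in CONTINUOUS_TRAITS])),
        composite_consensus=float(np.mean([per_trait[t] for t in CATEGORICAL_TRAITS])),
        method=assignment.method,
        k=assignment.k,
    )


@dataclass(frozen=True)
class GuidelineVerdict:
    """Outcome of the four run-selection guidelines."""

    min_size_ok: bool
    max_clusters_ok: bool
    rsd_ok: bool
    consensus_ok: bool
    thresholds: dict = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return self.min_size_ok and self.max_clusters_ok and self.rsd_ok and self.consensus_ok


def guideline_check(
    report: QualityReport,
    min_size: int = 3,
    max_k: int = 40,
    rsd_limit: float = 15.0,
    consensus_min: float = 95.0,
) -> GuidelineVerdict:
    """Check a run against the cluster-selection guidelines.

    Defaults: at least 3 genes per cluster, at most 40 clusters,
    composite relative SD strictly below 15% and composite consensus no
    less than 95%.
    """
    return GuidelineVerdict(
        min_size_ok=report.min_cluster_size >= min_size,
        max_clusters_ok=len(report.per_cluster) <= max_k,
        rsd_ok=report.composite_rsd < rsd_limit,
        consensus_ok=report.composite_consensus >= consensus_min,
        thresholds={
            "min_size": min_size,
            "max_k": max_k,
            "rsd_limit": rsd_limit,
            "consensus_min": consensus_min,
        },
    )


def weight_scan(
    table: PhenotypeTable,
    presets: Sequence[WeightVector],
    k_values: Sequence[int],
    method: str = "pam",
    **guideline_kwargs,
) -> pd.DataFrame:
    """Scan weight presets x cluster counts and tabulate run quality.

    Returns one row per (preset, k) with run-level per-trait averages,
    the two composites and the guideline verdict. The best row by
    lexicographic criterion (max composite consensus, then min composite
    RSD) is flagged in the ``best`` column.
    """
    if not presets or not k_values:
        raise ValueError("presets and k_values must be non-empty")
    rows = []
    for preset in presets:
        D = gower_matrix(table, preset)
        for k in k_values:
            if method == "pam":
                assignment = pam(D, k)
            else:
                assignment = agglomerative(D, method, k)
            report = run_quality(assignment, table)
            verdict = guideline_check(report, **guideline_kwargs)
            row = {
                "weights": preset.name,
                "k": k,
                **{f"avg_consensus_{t}": report.per_trait_average[t] for t in CATEGORICAL_TRAITS},
                **{f"avg_rsd_{t}": report.per_trait_average[t] for t in CONTINUOUS_TRAITS},
                "composite_consensus": report.composite_consensus,
                "composite_rsd": report.composite_rsd,
                "min_cluster_size": report.min_cluster_size,
                "passes_guidelines": verdict.passed,
            }
            rows.append(row)
    scan = pd.DataFrame(rows)
    best_idx = scan.sort_values(
        ["composite_consensus", "composite_rsd"], ascending=[False, True], kind="stable"
    ).index[0]
    scan["best"] = False
    scan.loc[best_idx, "best"] = True
    return scan


def cluster_summary(
    assignment: ClusterAssignment,
    table: PhenotypeTable,
    varied_threshold: float = 50.0,
) -> pd.DataFrame:
    """Majority-phenotype summary per cluster, one column per trait.

    Continuous traits are first binned against the wild-type reference
    ranges; each cell then reads like ``"75% Normal Average"``, or
    ``"Varied"`` when no single phenotype exceeds ``varied_threshold``
    percent of the cluster.
    """
    data = table.data.set_index("gene_id")
    missing = [g for g in assignment.ids if g not in data.index]
    if missing:
        raise ValueError(f"genes in assignment absent from table: {missing[:5]}")
    sub = data.loc[list(assignment.ids)]
    labels = assignment.labels

    rows = []
    for c in range(1, assignment.k + 1):
        grp = sub[labels == c]
        row: dict[str, object] = {"cluster": c, "size": len(grp)}
        for trait in ALL_TRAITS:
            if trait in CONTINUOUS_TRAITS:
                values = bin_series(grp[trait].astype(float), trait)
                vocab = None
            else:
                values = grp[trait]
                vocab = table.trait_schema(trait).vocabulary
            cons = percent_consensus(values, vocab)
            if cons.percent <= varied_threshold:
                row[trait] = "Varied"
            else:
                row[trait] = f"{cons.percent:.0f}% {cons.majority}"
        rows.append(row)
    return pd.DataFrame(rows)
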