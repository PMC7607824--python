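"""Expression-profile K-means and mapping onto phenotypic clusters.

Time-course expression matrices (genes x time points) are row-
standardized to mean 0 and standard deviation 2, partitioned into
profiles by K-means, and the profiles are cross-tabulated against a
phenotypic clustering. A phenotypic cluster has a *dominant* profile
when a single expression profile covers at least 40% of its genes with
expression data; clusters with fewer than three covered genes are
excluded from the mapping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import davies_bouldin_score

from .cluster import ClusterAssignment, kmeans

_SD_TOL = 1e-9


@dataclass
class ExpressionMatrix:
    """Genes x time points expression values."""

    ids: tuple[str, ...]
    timepoints: tuple[str, ...]
    values: np.ndarray
    standardized: bool = False

    def __post_init__(self) -> None:
        self.ids = tuple(self.ids)
        self.timepoints = tuple(self.timepoints)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.timepoints)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.ids)} genes x {len(self.timepoints)} time points"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.ids), columns=list(self.timepoints)
        ).rename_axis("gene_id")

    def to_csv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf)

    @classmethod
    def from_csv(cls, path_or_buf, sep: str = ",") -> "ExpressionMatrix":
        df = pd.read_csv(path_or_buf, sep=sep, index_col=0)
        return cls(
            ids=tuple(str(i) for i in df.index),
            timepoints=tuple(str(c) for c in df.columns),
            values=df.to_numpy(dtype=float),
        )


def standardize_rows(expr: ExpressionMatrix, target_sd: float = 2.0) -> ExpressionMatrix:
    """Linearly transform each row to mean 0 and sample SD ``target_sd``.

    Constant rows cannot be standardized; they are dropped with a
    warning (zero-filled rows would distort downstream centroids).
    """
    if len(expr.timepoints) < 2:
        raise ValueError("standardization needs at least 2 time points")
    X = expr.values
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    constant = sd[:, 0] <= 1e-12
    if constant.any():
        dropped = [expr.ids[i] for i in np.flatnonzero(constant)]
        warnings.warn(f"dropping {len(dropped)} constant rows: {dropped[:5]}", stacklevel=2)
    keep = ~constant
    Z = (X[keep] - mean[keep]) / sd[keep] * target_sd
    return ExpressionMatrix(
        ids=tuple(g for g, k in zip(expr.ids, keep) if k),
        timepoints=expr.timepoints,
        values=Z,
        standardized=True,
    )


def kmeans_profiles(
    expr: ExpressionMatrix, k: int, seed: int, restarts: int = 25
) -> ClusterAssignment:
    """Partition standardized expression rows into k profiles by K-means.

    Defaults to 25 random restarts (the usual nstart=25 practice) since
    profile counts of 6-8 need several initializations to reach the best
    optimum. The per-profile mean curves (centroids) are exposed in
    ``extras['centroids']`` for reporting.
    """
    if not expr.standardized:
        raise ValueError("kmeans_profiles expects a standardized matrix")
    assignment = kmeans(expr.values, k, seed=seed, restarts=restarts, ids=expr.ids)
    assignment.method = "kmeans_profiles"
    assignment.extras["timepoints"] = list(expr.timepoints)
    return assignment


def _within_ss(X: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for c in np.unique(labels):
        sub = X[labels == c]
        total += float(((sub - sub.mean(axis=0)) ** 2).sum())
    return total


def k_diagnostics(
    expr: ExpressionMatrix,
    k_range,
    B: int = 50,
    seed: int = 0,
    restarts: int = 25,
) -> tuple[pd.DataFrame, dict[str, int | None]]:
    """Profile-number diagnostics: within-SS, gap statistic, Davies-Bouldin.

    For each k: the within-cluster sum of squares of the best K-means
    run; the gap statistic against B uniform reference sets sampled
    within the observed per-time-point ranges (gap(k) = mean log W_ref -
    log W_obs, with SE inflated by sqrt(1 + 1/B)); and the
    Davies-Bouldin index. Recommended k: for the gap, the smallest k
    with gap(k) >= gap(k+1) - SE(k+1); for Davies-Bouldin, the argmin.
    The within-SS elbow is left to the user.
    """
    X = expr.values
    n = X.shape[0]
    k_range = sorted(int(k) for k in k_range)
    if k_range[0] < 2 or k_range[-1] > n - 1:
        raise ValueError(f"k_range must lie within [2, {n - 1}]")
    rng = np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)
    refs = [rng.uniform(lo, hi, size=X.shape) for _ in range(B)]

    rows = []
    for k in k_range:
        assignment = kmeans(X, k, seed=seed, restarts=restarts)
        wss = assignment.total_cost
        db = float(davies_bouldin_score(X, assignment.labels))
        log_ref = np.array(
            [np.log(kmeans(R, k, seed=seed, restarts=max(1, restarts // 3)).total_cost)
             for R in refs]
        )
        gap = float(log_ref.mean() - np.log(wss))
        se = float(log_ref.std(ddof=1) * np.sqrt(1.0 + 1.0 / B)) if B > 1 else 0.0
        rows.append({"k": k, "within_ss": wss, "gap": gap, "gap_se": se, "davies_bouldin": db})
    diag = pd.DataFrame(rows)

    gap_k: int | None = None
    for i in range(len(diag) - 1):
        if diag.gap[i] >= diag.gap[i + 1] - diag.gap_se[i + 1]:
            gap_k = int(diag.k[i])
            break
    recommended = {
        "gap": gap_k,
        "davies_bouldin": int(diag.k[diag.davies_bouldin.idxmin()]),
    }
    return diag, recommended


@dataclass
class ProfileMapReport:
    """Cross-tabulation of expression profiles against phenotypic clusters."""

    per_cluster: pd.DataFrame  # cluster, n_covered, n_profiles, dominant_profile, dominant_share
    crosstab: pd.DataFrame  # phenotypic cluster x profile counts
    excluded_clusters: tuple[int, ...]  # clusters with < min_genes covered genes
    avg_profiles_per_cluster: float
    modal_dominant_profile: int | None
    modal_dominant_share: float  # share of dominant-profile clusters carrying the modal profile
    unmatched_genes: int = 0


def map_profiles(
    pheno: ClusterAssignment,
    profiles: ClusterAssignment,
    min_genes: int = 3,
    dominance: float = 0.40,
) -> ProfileMapReport:
    """Map expression profiles onto phenotypic clusters with the dominance rule.

    The gene universe is the intersection of the two assignments.
    Clusters with fewer than ``min_genes`` covered genes are excluded
    (and listed). A dominant profile is reported when a single profile
    covers at least ``dominance`` (fraction) of the cluster's covered
    genes; ties for the top count go to the smallest profile id.
    """
    profile_of = dict(zip(profiles.ids, profiles.labels))
    common = [g for g in pheno.ids if g in profile_of]
    if not common:
        raise ValueError("no genes shared between phenotype and expression assignments")
    unmatched = len(pheno.ids) - len(common)

    pheno_of = dict(zip(pheno.ids, pheno.labels))
    df = pd.DataFrame(
        {
            "cluster": [pheno_of[g] for g in common],
            "profile": [int(profile_of[g]) for g in common],
        }
    )
    crosstab = pd.crosstab(df["cluster"], df["profile"])

    rows = []
    excluded = []
    for c in range(1, pheno.k + 1):
        counts = crosstab.loc[c] if c in crosstab.index else pd.Series(dtype=int)
        n_cov = int(counts.sum())
        if n_cov < min_genes:
            excluded.append(c)
            continue
        top = counts.max()
        dominant = int(min(counts[counts == top].index))
        share = float(top / n_cov)
        rows.append(
            {
                "cluster": c,
                "n_covered": n_cov,
                "n_profiles": int((counts > 0).sum()),
                "dominant_profile": dominant if share >= dominance else None,
                "dominant_share": share if share >= dominance else np.nan,
            }
        )
    per_cluster = pd.DataFrame(rows)
    if len(per_cluster):
        avg_profiles = float(per_cluster["n_profiles"].mean())
    else:
        avg_profiles = float("nan")

    dominated = per_cluster.dropna(subset=["dominant_profile"]) if len(per_cluster) else per_cluster
    if len(dominated):
        counts = dominated["dominant_profile"].astype(int).value_counts()
        modal = int(min(counts[counts == counts.max()].index))
        modal_share = float(counts.max() / len(dominated))
    else:
        modal, modal_share = None, float("nan")

    return ProfileMapReport(
        per_cluster=per_cluster,
        crosstab=crosstab,
        excluded_clusters=tuple(excluded),
        avg_profiles_per_cluster=avg_profiles,
        modal_dominant_profile=modal,
        modal_dominant_share=modal_share,
        unmatched_genes=unmatched,
    )
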