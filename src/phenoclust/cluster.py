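"""Partitional and hierarchical clustering on dissimilarities.

PAM (Partitioning Around Medoids) is implemented here directly so that
BUILD/SWAP behaviour, tie-breaking and the cost trace are fully
deterministic and inspectable. Hierarchical clustering (Ward, complete
linkage) is delegated to scipy and K-means to scikit-learn, with a
uniform :class:`ClusterAssignment` result type.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .dissimilarity import DissimilarityMatrix


@dataclass
class ClusterAssignment:
    """A partition of gene IDs into clusters 1..k with provenance.

    ``medoids`` is populated for PAM (and, as per-cluster representative
    points, for the hierarchical methods); ``total_cost`` is the sum of
    dissimilarities of points to their medoid (PAM/HAC) or the
    within-cluster sum of squares (K-means).
    """

    ids: tuple[str, ...]
    labels: np.ndarray  # int array, values 1..k
    k: int
    method: str
    total_cost: float
    medoids: tuple[str, ...] | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ids = tuple(self.ids)
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.ids):
            raise ValueError("labels and ids length mismatch")
        present = set(self.labels.tolist())
        if present != set(range(1, self.k + 1)):
            raise ValueError(f"labels must cover 1..{self.k}, got {sorted(present)}")
        if self.medoids is not None:
            self.medoids = tuple(self.medoids)
            if len(self.medoids) != self.k:
                raise ValueError("need exactly k medoids")

    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {c: [] for c in range(1, self.k + 1)}
        for gid, lab in zip(self.ids, self.labels):
            out[int(lab)].append(gid)
        return out

    def to_series(self) -> pd.Series:
        return pd.Series(self.labels, index=list(self.ids), name="cluster")

    def write(self, csv_path, sidecar_path=None) -> None:
        """Two-column CSV (gene_id, cluster) plus a JSON sidecar."""
        pd.DataFrame({"gene_id": list(self.ids), "cluster": self.labels}).to_csv(
            csv_path, index=False
        )
        if sidecar_path is not None:
            meta = {
                "method": self.method,
                "k": self.k,
                "total_cost": self.total_cost,
                "medoids": list(self.medoids) if self.medoids else None,
                **{k: v for k, v in self.extras.items() if _jsonable(v)},
            }
            Path(sidecar_path).write_text(json.dumps(meta, indent=2))


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def total_cost(D: DissimilarityMatrix, medoids: Sequence[str]) -> float:
    """Sum over points of the dissimilarity to the nearest medoid."""
    index = {g: i for i, g in enumerate(D.ids)}
    try:
        idx = [index[m] for m in medoids]
    except KeyError as e:
        raise ValueError(f"unknown medoid id {e.args[0]!r}") from None
    return float(D.values[:, idx].min(axis=1).sum())


def _pam_build(d: np.ndarray, k: int) -> list[int]:
    """Greedy BUILD phase: seed medoids by maximal cost reduction."""
    n = d.shape[0]
    medoids = [int(np.argmin(d.sum(axis=0)))]
    dn = d[medoids[0]].copy()
    while len(medoids) < k:
        gain = np.maximum(dn[:, None] - d, 0.0).sum(axis=0)
        gain[medoids] = -np.inf
        medoids.append(int(np.argmax(gain)))
        np.minimum(dn, d[:, medoids[-1]], out=dn)
    return sorted(medoids)


def pam(D: DissimilarityMatrix, k: int) -> ClusterAssignment:
    """Partitioning Around Medoids with deterministic BUILD + SWAP.

    BUILD picks the point minimizing total dissimilarity first, then
    repeatedly adds the point with the largest total cost reduction.
    SWAP evaluates every (medoid, non-medoid) exchange, applies the
    single best-improving swap (ties broken by smallest index in table
    order) and repeats until no swap improves the objective. The cost
    trace across swap iterations is recorded in ``extras['cost_trace']``.
    """
    n = len(D)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    d = D.values
    medoids = _pam_build(d, k)

    cost_trace = []
    n_swaps = 0
    while True:
        med = np.asarray(medoids)
        dm = d[:, med]  # n x k
        order = np.argsort(dm, axis=1, kind="stable")
        nearest = order[:, 0]
        dn = dm[np.arange(n), nearest]
        if k > 1:
            ds = dm[np.arange(n), order[:, 1]]
        else:
            ds = np.full(n, np.inf)
        cost_trace.append(float(dn.sum()))

        if k == n:
            break
        # FastPAM-style exact swap deltas:
        #   delta(m, h) = colsum(B)[h] + (G @ (A - B))[m, h]
        # where, per point i and candidate h,
        #   A[i,h] = min(d(i,h), second-nearest) - nearest   (i loses m)
        #   B[i,h] = min(d(i,h) - nearest, 0)                (i keeps m)
        A = np.minimum(d, ds[:, None]) - dn[:, None]
        B = np.minimum(d - dn[:, None], 0.0)
        G = np.zeros((k, n))
        G[nearest, np.arange(n)] = 1.0
        delta = B.sum(axis=0)[None, :] + G @ (A - B)
        delta[:, med] = np.inf
        flat = int(np.argmin(delta))  # row-major: smallest medoid index, then h
        best = delta.flat[flat]
        if best < -1e-12:
            mi, h = divmod(flat, n)
            medoids[mi] = h
            medoids.sort()
            n_swaps += 1
        else:
            break

    med = np.asarray(medoids)
    dm = d[:, med]
    nearest = np.argmin(dm, axis=1)  # ties -> smallest medoid index
    labels = nearest + 1
    cost = float(dm[np.arange(n), nearest].sum())
    return ClusterAssignment(
        ids=D.ids,
        labels=labels,
        k=k,
        method="pam",
        total_cost=cost,
        medoids=tuple(D.ids[m] for m in medoids),
        extras={"cost_trace": cost_trace, "n_swaps": n_swaps},
    )


def _cluster_medoids(d: np.ndarray, labels: np.ndarray) -> tuple[list[int], float]:
    """Per-cluster medoid (min within-cluster dissimilarity sum) and cost."""
    medoids = []
    cost = 0.0
    for c in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == c)
        sub = d[np.ix_(idx, idx)]
        m = idx[int(np.argmin(sub.sum(axis=0)))]
        medoids.append(int(m))
        cost += float(d[idx, m].sum())
    return medoids, cost


def agglomerative(D: DissimilarityMatrix, method: str, k: int) -> ClusterAssignment:
    """Hierarchical agglomerative clustering cut at k clusters.

    ``method`` is ``"ward"`` (Lance-Williams updates on squared
    dissimilarities, the ward.D2 convention) or ``"complete"``. Labels
    are renumbered 1..k in order of first appearance for determinism.
    """
    if method not in ("ward", "complete"):
        raise ValueError(f"unknown linkage method {method!r}")
    n = len(D)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    Z = linkage(squareform(D.values, checks=False), method=method)
    raw = fcluster(Z, t=k, criterion="maxclust")
    # renumber in order of first appearance
    remap: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, c in enumerate(raw):
        if c not in remap:
            remap[c] = len(remap) + 1
        labels[i] = remap[c]
    med_idx, cost = _cluster_medoids(D.values, labels)
    return ClusterAssignment(
        ids=D.ids,
        labels=labels,
        k=int(labels.max()),
        method=method,
        total_cost=cost,
        medoids=tuple(D.ids[m] for m in med_idx),
    )


def kmeans(
    X: pd.DataFrame | np.ndarray,
    k: int,
    seed: int,
    restarts: int = 10,
    ids: Sequence[str] | None = None,
) -> ClusterAssignment:
    """Lloyd K-means, best of ``restarts`` seeded random initializations.

    ``total_cost`` is the within-cluster sum of squares of the best run.
    Empty clusters cannot persist: the solver relocates an empty center
    to the point contributing most to the objective. Labels are
    renumbered 1..k in order of first appearance, so results are
    deterministic given (X, k, seed, restarts).
    """
    if isinstance(X, pd.DataFrame):
        if ids is None:
            ids = tuple(str(i) for i in X.index)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if ids is None:
            ids = tuple(str(i) for i in range(X.shape[0]))
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    km = KMeans(
        n_clusters=k,
        init="random",
        n_init=restarts,
        random_state=seed,
        algorithm="lloyd",
    ).fit(X)
    remap: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, c in enumerate(km.labels_):
        if c not in remap:
            remap[int(c)] = len(remap) + 1
        labels[i] = remap[int(c)]
    centroids = np.vstack(
        [km.cluster_centers_[orig] for orig in sorted(remap, key=remap.get)]
    )
    return ClusterAssignment(
        ids=tuple(ids),
        labels=labels,
        k=k,
        method="kmeans",
        total_cost=float(km.inertia_),
        extras={"centroids": centroids, "seed": seed, "restarts": restarts},
    )
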