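"""Cluster composition against gene annotations.

Boolean gene attributes (yeast ortholog, transmembrane domain, GPCR,
kinase/phosphatase/transcription-factor class, phosphoprotein, MAPK
target flags) are tabulated per phenotypic cluster as percentages of
cluster size. Also provides multi-pathway MAPK target counting and the
chi-square goodness-of-fit test of the dataset's chromosome (linkage
group) distribution against the genome's.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cluster import ClusterAssignment

MAPK_TARGET_FLAGS = ("target_MAK1", "target_MAK2", "target_OS2")

BOOLEAN_ATTRIBUTES = (
    "yeast_ortholog",
    "has_TM",
    "is_GPCR",
    "is_ST_kinase",
    "is_phosphatase",
    "is_TF",
    "is_metabolic",
    "is_phosphoprotein",
) + MAPK_TARGET_FLAGS

_TRUTHY = {"1", "true", "yes", "y", "t"}
_FALSY = {"0", "false", "no", "n", "f", ""}


def read_annotations(path_or_buf, sep: str = ",") -> pd.DataFrame:
    """Read a gene annotation table (gene_id + boolean/integer columns).

    Boolean columns are coerced from 0/1, true/false or yes/no. A
    ``linkage_group`` column, if present, is kept as integers 1..7.
    """
    df = pd.read_csv(path_or_buf, sep=sep, dtype=str, keep_default_na=False)
    if "gene_id" not in df.columns:
        raise ValueError("annotation table must have a gene_id column")
    if df["gene_id"].duplicated().any():
        raise ValueError("annotation table has duplicate gene_id rows")
    out = pd.DataFrame({"gene_id": df["gene_id"]})
    for col in df.columns:
        if col == "gene_id":
            continue
        if col == "linkage_group":
            out[col] = pd.to_numeric(df[col], errors="raise").astype(int)
            continue
        lowered = df[col].str.strip().str.lower()
        bad = ~lowered.isin(_TRUTHY | _FALSY)
        if bad.any():
            raise ValueError(
                f"column {col}: non-boolean values {sorted(df[col][bad].unique())[:5]}"
            )
        out[col] = lowered.isin(_TRUTHY)
    _validate(out)
    return out


def _validate(annotations: pd.DataFrame) -> None:
    if "is_GPCR" in annotations.columns and "has_TM" in annotations.columns:
        orphan = annotations["is_GPCR"] & ~annotations["has_TM"]
        if orphan.any():
            raise ValueError(
                "is_GPCR implies has_TM; violated for "
                f"{list(annotations['gene_id'][orphan])[:5]}"
            )
    if "linkage_group" in annotations.columns:
        lg = annotations["linkage_group"]
        if ((lg < 1) | (lg > 7)).any():
            raise ValueError("linkage_group must be in 1..7")


def _attribute_series(
    assignment: ClusterAssignment, annotations: pd.DataFrame, attribute: str
) -> pd.Series:
    if attribute not in annotations.columns:
        raise KeyError(f"unknown attribute {attribute!r}")
    ann = annotations.set_index("gene_id")[attribute]
    missing = [g for g in assignment.ids if g not in ann.index]
    if missing:
        warnings.warn(
            f"{len(missing)} assigned genes lack annotation; counted as False",
            stacklevel=3,
        )
    return pd.Series(
        [bool(ann.get(g, False)) for g in assignment.ids], index=list(assignment.ids)
    )


def composition(
    assignment: ClusterAssignment, annotations: pd.DataFrame, attribute: str
) -> tuple[pd.DataFrame, float]:
    """Per-cluster percentage of genes carrying a boolean attribute.

    The denominator is cluster size (genes without an annotation row
    count as False, with a warning). Returns the per-cluster table
    (cluster, size, n_true, percent to 1 decimal) and the dataset-level
    percentage.
    """
    flags = _attribute_series(assignment, annotations, attribute)
    rows = []
    for c in range(1, assignment.k + 1):
        in_cluster = assignment.labels == c
        size = int(in_cluster.sum())
        n_true = int(flags.to_numpy()[in_cluster].sum())
        rows.append(
            {
                "cluster": c,
                "size": size,
                "n_true": n_true,
                "percent": round(100.0 * n_true / size, 1),
            }
        )
    overall = round(100.0 * flags.sum() / len(flags), 1)
    return pd.DataFrame(rows), float(overall)


def multi_pathway_targets(
    annotations: pd.DataFrame, assignment: ClusterAssignment
) -> pd.DataFrame:
    """Count genes targeted by 1, 2 or 3 MAPK pathways, per cluster and overall.

    Pathway membership comes from the three target flags (MAK-1, MAK-2,
    OS-2). Returns one row per cluster plus an ``overall`` row with
    columns ``n_1``, ``n_2``, ``n_3`` (and ``n_0`` for completeness).
    """
    for flag in MAPK_TARGET_FLAGS:
        if flag not in annotations.columns:
            raise KeyError(f"annotation table lacks {flag}")
    ann = annotations.set_index("gene_id")
    pathway_count = pd.Series(
        [int(sum(bool(ann[f].get(g, False)) for f in MAPK_TARGET_FLAGS)) for g in assignment.ids],
        index=list(assignment.ids),
    )
    rows = []
    counts = pathway_count.to_numpy()
    for c in range(1, assignment.k + 1):
        sub = counts[assignment.labels == c]
        rows.append(
            {"cluster": str(c), **{f"n_{i}": int((sub == i).sum()) for i in range(4)}}
        )
    rows.append(
        {"cluster": "overall", **{f"n_{i}": int((counts == i).sum()) for i in range(4)}}
    )
    return pd.DataFrame(rows)


def chromosome_gof(
    dataset_counts: Sequence[int], genome_counts: Sequence[int]
) -> tuple[float, int, float]:
    """Chi-square goodness of fit of dataset vs genome chromosome counts.

    Expected counts are the dataset total apportioned by the genome
    proportions over the seven linkage groups; the statistic is
    Pearson's X^2 with 6 degrees of freedom and an upper-tail p-value.
    """
    obs = np.asarray(dataset_counts, dtype=float)
    genome = np.asarray(genome_counts, dtype=float)
    if obs.shape != (7,) or genome.shape != (7,):
        raise ValueError("need exactly 7 counts per linkage group")
    if (genome <= 0).any():
        raise ValueError("genome counts must all be positive")
    total = obs.sum()
    if total <= 0:
        raise ValueError("dataset total must be positive")
    expected = total * genome / genome.sum()
    if (expected <= 0).any():
        raise ValueError("zero expected cell")
    stat, p = stats.chisquare(obs, f_exp=expected)
    return float(stat), 6, float(p)
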