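"""Pairwise dissimilarity construction for mixed phenotype data.

Two metrics are provided: trait-weighted Gower dissimilarity for the
mixed continuous/categorical table (the substrate for PAM and Ward's),
and one-minus-Pearson distance for the ordinal-converted numeric
pipeline. Weight presets reproduce the seven weighting schemes used in
the model-selection scan; trait order in a weight vector follows the
schema positions (eight categorical traits, then growth rate, then
aerial height).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phenotypes import ALL_TRAITS, CATEGORICAL_TRAITS, CONTINUOUS_TRAITS, PhenotypeTable


@dataclass(frozen=True)
class WeightVector:
    """Ten non-negative trait weights in schema-position order."""

    weights: tuple[float, ...]
    name: str = "custom"

    def __post_init__(self) -> None:
        if len(self.weights) != 10:
            raise ValueError(f"weight vector must have 10 entries, got {len(self.weights)}")
        w = np.asarray(self.weights, dtype=float)
        if (w < 0).any():
            raise ValueError("weights must be non-negative")
        if not (w > 0).any():
            raise ValueError("at least one weight must be positive")


#: Weighting presets scanned during model selection. Positions 9-10
#: (growth rate, aerial height) carry the up-weighting in W1-W6.
PRESETS: dict[str, WeightVector] = {
    "NoWeight": WeightVector((1, 1, 1, 1, 1, 1, 1, 1, 1, 1), "NoWeight"),
    "W1": WeightVector((1, 1, 1, 1, 1, 1, 1, 1, 2, 2), "W1"),
    "W2": WeightVector((1, 0.5, 1, 0.5, 1, 0.5, 1, 0.5, 2, 2), "W2"),
    "W3": WeightVector((2, 2, 1, 1, 1, 1, 1, 1, 6, 2), "W3"),
    "W4": WeightVector((0.5, 0.5, 1, 1, 1, 1, 1, 1, 6, 5), "W4"),
    "W5": WeightVector((1, 1, 1, 1, 1, 1, 1, 1, 6, 4), "W5"),
    "W6": WeightVector((1, 1, 1, 1, 1, 1, 1, 1, 6, 6), "W6"),
}


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise dissimilarities with their gene-ID order."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.ids = tuple(self.ids)
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("dissimilarity matrix must be symmetric")
        if (np.diag(v) != 0).any():
            raise ValueError("diagonal must be exactly zero")
        if (v < -1e-12).any():
            raise ValueError("dissimilarities must be non-negative")
        self.values = np.clip(v, 0.0, None)

    def __len__(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))

    def to_csv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf)

    @classmethod
    def from_csv(cls, path_or_buf) -> "DissimilarityMatrix":
        df = pd.read_csv(path_or_buf, index_col=0)
        if list(df.index) != list(df.columns):
            raise ValueError("row and column headers disagree")
        return cls(ids=tuple(str(i) for i in df.index), values=df.to_numpy(dtype=float))


def gower_matrix(table: PhenotypeTable, weights: WeightVector) -> DissimilarityMatrix:
    """Weighted Gower dissimilarity over the ten-trait table.

    d(i,j) = sum_t w_t * delta_t(i,j) / sum_t w_t, where delta_t is
    |x_i - x_j| / range_t for a continuous trait (range taken over the
    analyzed table) and a 0/1 mismatch for a categorical trait.
    Categorical traits are treated as nominal: ordered-looking labels
    still contribute a full mismatch. A continuous trait with zero range
    contributes 0 (its weight stays in the denominator) with a warning.
    """
    if not table.complete_mask.all():
        raise ValueError("Gower requires a complete table; apply filter_complete first")
    w = np.asarray(weights.weights, dtype=float)
    n = len(table)
    d = table.data
    num = np.zeros((n, n))
    for pos, trait in enumerate(ALL_TRAITS):
        if trait in CATEGORICAL_TRAITS:
            codes = pd.factorize(d[trait])[0]
            delta = (codes[:, None] != codes[None, :]).astype(float)
        else:
            x = d[trait].astype(float).to_numpy()
            rng = float(x.max() - x.min())
            if rng <= 0:
                warnings.warn(
                    f"continuous trait {trait} has zero range; it contributes 0",
                    stacklevel=2,
                )
                continue
            delta = np.abs(x[:, None] - x[None, :]) / rng
        num += w[pos] * delta
    values = num / w.sum()
    np.fill_diagonal(values, 0.0)
    values = (values + values.T) / 2.0
    return DissimilarityMatrix(ids=table.gene_ids, values=values)


def pearson_distance_matrix(
    matrix: pd.DataFrame | np.ndarray,
    ids: tuple[str, ...] | None = None,
) -> DissimilarityMatrix:
    """One-minus-Pearson distance between rows of a numeric matrix.

    d(i,j) = 1 - r(row_i, row_j), in [0, 2]. Rows with zero variance
    have undefined correlation and raise, naming the offending gene.
    """
    if isinstance(matrix, pd.DataFrame):
        if ids is None:
            ids = tuple(str(i) for i in matrix.index)
        X = matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
        if ids is None:
            ids = tuple(str(i) for i in range(X.shape[0]))
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 columns")
    sd = X.std(axis=1)
    if (sd == 0).any():
        bad = [ids[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance rows (correlation undefined): {bad}")
    values = 1.0 - np.corrcoef(X)
    np.fill_diagonal(values, 0.0)
    values = np.clip((values + values.T) / 2.0, 0.0, 2.0)
    return DissimilarityMatrix(ids=ids, values=values)
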