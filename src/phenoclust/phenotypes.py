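"""Phenotype table data model for knockout-mutant phenomes.

A phenome table has one row per knockout mutant and ten traits: two
continuous (basal hyphal growth rate in mm/day, aerial hyphae height in
mm) and eight categorical, scored visually (number and morphology of
conidia, protoperithecia, perithecia and ascospores). This module owns
reading/validation, completeness filtering, the wild-type-anchored
binning of the continuous traits, the ordinal conversion used by the
numeric (Pearson/K-means) pipelines, and the global classification of
mutants into growth / asexual / sexual defect classes.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# Trait names in weight-vector order: positions 1-8 categorical,
# positions 9-10 continuous.
CATEGORICAL_TRAITS: tuple[str, ...] = (
    "conidia_number",
    "conidia_morphology",
    "protoperithecia_number",
    "protoperithecia_morphology",
    "perithecia_number",
    "perithecia_morphology",
    "ascospore_number",
    "ascospore_morphology",
)
CONTINUOUS_TRAITS: tuple[str, ...] = ("growth_rate", "aerial_height")
ALL_TRAITS: tuple[str, ...] = CATEGORICAL_TRAITS + CONTINUOUS_TRAITS

#: The four semi-quantitative abundance traits amenable to ordinal conversion.
ABUNDANCE_TRAITS: tuple[str, ...] = (
    "conidia_number",
    "protoperithecia_number",
    "perithecia_number",
    "ascospore_number",
)

ABUNDANCE_VOCABULARY: tuple[str, ...] = (
    "Not Formed",
    "Severely Reduced",
    "Reduced",
    "Slightly Reduced",
    "Normal",
    "Increased",
)
MORPHOLOGY_VOCABULARY: tuple[str, ...] = ("Not Formed", "Abnormal", "Normal")

#: Severity scale for the ordinal conversion of the abundance traits.
DEFAULT_ORDINAL_MAP: dict[str, float] = {
    "Not Formed": 0.0,
    "Severely Reduced": 0.25,
    "Reduced": 0.5,
    "Slightly Reduced": 0.75,
    "Normal": 1.0,
    "Increased": 1.5,
}

BIN_LABELS: tuple[str, ...] = (
    "Severely Reduced",
    "Reduced",
    "Slightly Reduced",
    "Normal Low",
    "Normal Average",
    "Normal High",
    "Increased",
)

NORMAL_BINS: frozenset[str] = frozenset({"Normal Low", "Normal Average", "Normal High"})

# Bins are right-closed on the printed upper boundary after rounding to
# one decimal; the short unprinted gap in the aerial scale (29.1-29.9)
# falls to the next bin up, so binning is total on [0, inf).
_GROWTH_BIN_EDGES: tuple[tuple[float, str], ...] = (
    (39.9, "Severely Reduced"),
    (64.9, "Reduced"),
    (74.9, "Slightly Reduced"),
    (77.5, "Normal Low"),
    (82.5, "Normal Average"),
    (85.0, "Normal High"),
    (math.inf, "Increased"),
)
_AERIAL_BIN_EDGES: tuple[tuple[float, str], ...] = (
    (14.9, "Severely Reduced"),
    (24.9, "Reduced"),
    (29.0, "Slightly Reduced"),
    (35.0, "Normal Low"),
    (39.9, "Normal Average"),
    (45.0, "Normal High"),
    (math.inf, "Increased"),
)


class SchemaError(ValueError):
    """The input does not conform to the declared trait schema."""


class ValidationError(ValueError):
    """Record-level content violates schema constraints."""


@dataclass(frozen=True)
class TraitSchema:
    """Declaration of a single trait: kind, unit, vocabulary and position."""

    trait_name: str
    kind: str  # "continuous" | "categorical"
    unit: str = ""
    vocabulary: tuple[str, ...] = ()
    position: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "categorical"):
            raise SchemaError(f"unknown trait kind {self.kind!r}")
        if self.kind == "categorical":
            if not self.vocabulary:
                raise SchemaError(f"trait {self.trait_name}: empty vocabulary")
            if len(set(self.vocabulary)) != len(self.vocabulary):
                raise SchemaError(f"trait {self.trait_name}: duplicate labels")


def default_schema() -> tuple[TraitSchema, ...]:
    """The ten-trait schema in weight-vector order."""
    schemas = []
    for pos, name in enumerate(CATEGORICAL_TRAITS, start=1):
        vocab = (
            ABUNDANCE_VOCABULARY if name in ABUNDANCE_TRAITS else MORPHOLOGY_VOCABULARY
        )
        schemas.append(
            TraitSchema(trait_name=name, kind="categorical", vocabulary=vocab, position=pos)
        )
    schemas.append(
        TraitSchema(trait_name="growth_rate", kind="continuous", unit="mm/day", position=9)
    )
    schemas.append(
        TraitSchema(trait_name="aerial_height", kind="continuous", unit="mm", position=10)
    )
    return tuple(schemas)


def _check_schema(schema: Sequence[TraitSchema]) -> tuple[TraitSchema, ...]:
    schema = tuple(sorted(schema, key=lambda s: s.position))
    if len(schema) != 10:
        raise SchemaError(f"expected 10 traits, got {len(schema)}")
    kinds = [s.kind for s in schema]
    if kinds[:8] != ["categorical"] * 8 or kinds[8:] != ["continuous"] * 2:
        raise SchemaError("positions 1-8 must be categorical, 9-10 continuous")
    return schema


@dataclass
class PhenotypeTable:
    """An ordered table of mutants x 10 traits.

    ``data`` holds one row per mutant with a ``gene_id`` column plus one
    column per trait; missing values are NaN. Row order is stable and
    drives deterministic tie-breaking downstream.
    """

    schema: tuple[TraitSchema, ...]
    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.schema = _check_schema(self.schema)
        missing = [c for c in ("gene_id",) + ALL_TRAITS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"table missing columns: {missing}")
        dup = self.data["gene_id"][self.data["gene_id"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate gene_id: {sorted(dup.unique())}")
        # canonical column order: gene_id, then traits in schema position order
        self.data = self.data[["gene_id", *ALL_TRAITS]].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(self.data["gene_id"])

    @property
    def complete_mask(self) -> pd.Series:
        """True where all 10 traits are present."""
        return self.data[list(ALL_TRAITS)].notna().all(axis=1)

    def trait_schema(self, name: str) -> TraitSchema:
        for s in self.schema:
            if s.trait_name == name:
                return s
        raise KeyError(name)

    def to_csv(self, path_or_buf) -> None:
        self.data.to_csv(path_or_buf, index=False)


def read_phenotype_table(
    source,
    schema: Sequence[TraitSchema] | None = None,
    column_map: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> PhenotypeTable:
    """Read a delimited phenotype table and validate it against the schema.

    Parameters
    ----------
    source
        Path or file-like object; CSV by default, TSV if ``sep='\\t'`` or
        the filename ends in ``.tsv``.
    schema
        Trait schema set; defaults to :func:`default_schema`.
    column_map
        Optional mapping trait name -> column name in the file (and
        ``"gene_id"`` -> the gene-ID column name).

    Raises
    ------
    SchemaError
        If a required column is absent.
    ValidationError
        If a gene ID is duplicated or a categorical value is outside its
        trait's vocabulary (the error names gene, trait and label).
    """
    schema = _check_schema(schema or default_schema())
    if sep is None:
        name = getattr(source, "name", source if isinstance(source, str) else "")
        sep = "\t" if str(name).endswith(".tsv") else ","
    raw = pd.read_csv(source, sep=sep, dtype=str, keep_default_na=False)
    raw = raw.replace({"": np.nan, "NA": np.nan, "na": np.nan})

    colmap = dict(column_map or {})
    columns = {}
    for trait in ("gene_id",) + ALL_TRAITS:
        col = colmap.get(trait, trait)
        if col not in raw.columns:
            raise SchemaError(f"required column {col!r} (trait {trait}) not in header")
        columns[trait] = col

    out = pd.DataFrame({"gene_id": raw[columns["gene_id"]]})
    problems: list[str] = []
    for s in schema:
        col = raw[columns[s.trait_name]]
        if s.kind == "continuous":
            parsed = pd.to_numeric(col, errors="coerce")
            bad = col.notna() & parsed.isna()
            for i in np.flatnonzero(bad.to_numpy()):
                problems.append(
                    f"gene {out['gene_id'][i]}: trait {s.trait_name}: "
                    f"unparseable numeric value {col[i]!r}"
                )
            out[s.trait_name] = parsed
        else:
            known = col.isna() | col.isin(s.vocabulary)
            for i in np.flatnonzero(~known.to_numpy()):
                problems.append(
                    f"gene {out['gene_id'][i]}: trait {s.trait_name}: "
                    f"label {col[i]!r} not in vocabulary"
                )
            out[s.trait_name] = col.where(known)
    if problems:
        raise ValidationError("; ".join(problems))
    return PhenotypeTable(schema=schema, data=out)


def filter_complete(table: PhenotypeTable) -> PhenotypeTable:
    """Keep only records with all 10 traits present, preserving order."""
    mask = table.complete_mask
    kept = int(mask.sum())
    dropped = len(table) - kept
    logger.info("filter_complete: retained %d records, dropped %d", kept, dropped)
    if kept == 0:
        logger.warning("filter_complete: no complete records remain")
    return PhenotypeTable(schema=table.schema, data=table.data[mask].reset_index(drop=True))


def bin_continuous(value: float, trait: str) -> str:
    """Bin a continuous trait value against the wild-type reference range.

    Wild-type growth rate is 75-85 mm/day and wild-type aerial height
    30-45 mm; each scale is split into seven severity bins anchored on
    those ranges. Values are rounded to one decimal before comparison so
    that every non-negative value falls in exactly one bin.
    """
    if trait in ("growth", "growth_rate"):
        edges = _GROWTH_BIN_EDGES
    elif trait in ("aerial", "aerial_height"):
        edges = _AERIAL_BIN_EDGES
    else:
        raise ValueError(f"unknown continuous trait {trait!r}")
    if not np.isfinite(value) or value < 0:
        raise ValueError(f"continuous value must be finite and >= 0, got {value}")
    v = round(float(value), 1)
    for upper, label in edges:
        if v <= upper:
            return label
    raise AssertionError("unreachable")  # pragma: no cover


def bin_series(values: Iterable[float], trait: str) -> pd.Series:
    """Vectorized :func:`bin_continuous` over a sequence."""
    return pd.Series([bin_continuous(v, trait) for v in values], dtype="object")


class ConversionError(ValueError):
    """A categorical label has no entry in the ordinal mapping."""


def to_ordinal(
    table: PhenotypeTable,
    mapping: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Convert the table into the numeric matrix used by Pearson/K-means.

    Only the four abundance traits are amenable to the 0-1.5 severity
    scale; morphology traits are excluded. The two continuous traits are
    z-scored over the table (mean 0, sample SD 1) so mm-scale values and
    the ordinal scale are commensurable.

    Returns a DataFrame indexed by gene_id with columns
    ``growth_rate``, ``aerial_height`` (z-scored) followed by the four
    converted abundance traits.
    """
    mapping = dict(DEFAULT_ORDINAL_MAP if mapping is None else mapping)
    if not table.complete_mask.all():
        raise ValidationError("ordinal conversion requires a complete table")
    out = pd.DataFrame(index=pd.Index(table.gene_ids, name="gene_id"))
    for trait in CONTINUOUS_TRAITS:
        x = table.data[trait].astype(float).to_numpy()
        sd = x.std(ddof=1) if len(x) > 1 else 0.0
        out[trait] = (x - x.mean()) / sd if sd > 0 else 0.0
    for trait in ABUNDANCE_TRAITS:
        labels = table.data[trait]
        unknown = sorted(set(labels) - set(mapping))
        if unknown:
            raise ConversionError(
                f"trait {trait}: labels {unknown} not covered by the ordinal mapping"
            )
        out[trait] = labels.map(mapping).to_numpy()
    return out


@dataclass
class GlobalPhenotypeSummary:
    """Per-mutant defect flags and the three-class global summary."""

    flags: pd.DataFrame  # gene_id, growth_defect, asexual_defect, sexual_defect, any_defect
    class_counts: dict[str, int]
    venn: dict[str, int]
    total_global_phenotypes: int
    n_with_phenotype: int
    n_no_phenotype: int


def classify_global_phenotypes(table: PhenotypeTable) -> GlobalPhenotypeSummary:
    """Classify each mutant into growth / asexual / sexual defect classes.

    A growth defect is any growth-rate bin outside the three Normal
    bins (Increased counts as a defect). An asexual defect is an
    abnormal aerial-height bin or a non-Normal conidial trait. A sexual
    defect is any non-Normal value among the six sexual-structure
    traits. The total global phenotype count is the sum of the three
    class counts, so a mutant defective in two classes contributes two.
    """
    if not table.complete_mask.all():
        raise ValidationError("global classification requires a complete table")
    d = table.data
    growth_bin = bin_series(d["growth_rate"].astype(float), "growth")
    aerial_bin = bin_series(d["aerial_height"].astype(float), "aerial")

    growth = ~growth_bin.isin(NORMAL_BINS)
    asexual = (
        ~aerial_bin.isin(NORMAL_BINS)
        | (d["conidia_number"] != "Normal")
        | (d["conidia_morphology"] != "Normal")
    )
    sexual_traits = [t for t in CATEGORICAL_TRAITS if not t.startswith("conidia")]
    sexual = (d[sexual_traits] != "Normal").any(axis=1)
    any_defect = growth | asexual | sexual

    flags = pd.DataFrame(
        {
            "gene_id": d["gene_id"],
            "growth_defect": growth.to_numpy(),
            "asexual_defect": asexual.to_numpy(),
            "sexual_defect": sexual.to_numpy(),
            "any_defect": any_defect.to_numpy(),
        }
    )
    counts = {
        "growth": int(growth.sum()),
        "asexual": int(asexual.sum()),
        "sexual": int(sexual.sum()),
    }
    venn = {
        "growth_only": int((growth & ~asexual & ~sexual).sum()),
        "asexual_only": int((~growth & asexual & ~sexual).sum()),
        "sexual_only": int((~growth & ~asexual & sexual).sum()),
        "growth+asexual": int((growth & asexual & ~sexual).sum()),
        "growth+sexual": int((growth & ~asexual & sexual).sum()),
        "asexual+sexual": int((~growth & asexual & sexual).sum()),
        "growth+asexual+sexual": int((growth & asexual & sexual).sum()),
    }
    return GlobalPhenotypeSummary(
        flags=flags,
        class_counts=counts,
        venn=venn,
        total_global_phenotypes=sum(counts.values()),
        n_with_phenotype=int(any_defect.sum()),
        n_no_phenotype=int((~any_defect).sum()),
    )
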