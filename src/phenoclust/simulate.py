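"""Seeded generators for phenotype tables, expression time courses and
annotation tables with planted structure.

Each generator is a pure function of its configuration and seed, and
its output round-trips through the corresponding reader. Planted truth
labels are returned alongside the data so recovery can be scored with
the adjusted Rand index.

The bundled "collection-like" phenotype configuration emulates the
marginal structure of a large knockout-collection phenome: 1168 mutants
in 40 clusters with sizes from 5 to 171, two continuous and eight
categorical traits, 95% within-cluster categorical consensus and
continuous spread of 5% of the cluster mean. Cluster archetypes are
sampled with a minimum pairwise separation so that the planted
partition is recoverable in principle; how cleanly a given algorithm
recovers it is then a property of the algorithm, not the generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .phenotypes import (
    ABUNDANCE_TRAITS,
    ALL_TRAITS,
    CATEGORICAL_TRAITS,
    CONTINUOUS_TRAITS,
    PhenotypeTable,
    TraitSchema,
    default_schema,
)

#: Cluster sizes of a 1168-mutant, 40-cluster knockout collection
#: (min 5, median 14, max 171) used by :func:`collection_like_config`.
COLLECTION_SIZES: tuple[int, ...] = (
    28, 10, 171, 82, 73, 23, 130, 38, 82, 8,
    8, 8, 12, 9, 77, 21, 12, 8, 25, 19,
    42, 32, 11, 13, 11, 15, 15, 15, 9, 7,
    36, 9, 6, 12, 10, 33, 13, 9, 5, 21,
)

#: Plausible physical ranges for the two continuous traits (mm/day, mm).
CONTINUOUS_RANGES: dict[str, tuple[float, float]] = {
    "growth_rate": (20.0, 100.0),
    "aerial_height": (5.0, 60.0),
}


@dataclass(frozen=True)
class ClusterArchetype:
    """Per-cluster trait profile: continuous mean/SD and categorical modal label."""

    cont_mean: Mapping[str, float]
    cont_sd: Mapping[str, float]
    cat_modal: Mapping[str, str]
    consensus: Mapping[str, float]  # per categorical trait, P(modal label)


@dataclass(frozen=True)
class PhenotypeSimConfig:
    sizes: tuple[int, ...]
    archetypes: tuple[ClusterArchetype, ...]
    schema: tuple[TraitSchema, ...] = field(default_factory=default_schema)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.sizes) != len(self.archetypes):
            raise ValueError("one archetype per cluster size required")
        if any(s < 1 for s in self.sizes):
            raise ValueError("cluster sizes must be >= 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        vocab = {s.trait_name: s.vocabulary for s in self.schema if s.kind == "categorical"}
        for a in self.archetypes:
            for trait, p in a.consensus.items():
                if not (1.0 / len(vocab[trait]) < p <= 1.0):
                    raise ValueError(
                        f"consensus for {trait} must be in (1/|vocab|, 1], got {p}"
                    )
            for trait, label in a.cat_modal.items():
                if label not in vocab[trait]:
                    raise ValueError(f"modal label {label!r} not in {trait} vocabulary")
            if any(sd < 0 for sd in a.cont_sd.values()):
                raise ValueError("continuous SDs must be >= 0")


def _archetype_distance(a: ClusterArchetype, b: ClusterArchetype) -> float:
    """Unweighted Gower distance between two archetypes (range-normalized)."""
    total = 0.0
    for trait in CATEGORICAL_TRAITS:
        total += float(a.cat_modal[trait] != b.cat_modal[trait])
    for trait in CONTINUOUS_TRAITS:
        lo, hi = CONTINUOUS_RANGES[trait]
        total += abs(a.cont_mean[trait] - b.cont_mean[trait]) / (hi - lo)
    return total / len(ALL_TRAITS)


def random_archetypes(
    n_clusters: int,
    rng: np.random.Generator,
    schema: Sequence[TraitSchema] | None = None,
    consensus: float = 0.95,
    cont_sd_frac: float = 0.05,
    min_separation: float = 0.25,
    max_tries: int = 200,
) -> tuple[ClusterArchetype, ...]:
    """Sample mutually separated cluster archetypes.

    Continuous means are uniform within the physical trait ranges and
    per-cluster SDs are ``cont_sd_frac`` of the mean; categorical modal
    labels are uniform over each vocabulary. A candidate archetype is
    resampled until its unweighted Gower distance to every accepted
    archetype is at least ``min_separation``.
    """
    schema = tuple(schema or default_schema())
    vocab = {s.trait_name: s.vocabulary for s in schema if s.kind == "categorical"}
    accepted: list[ClusterArchetype] = []
    for _ in range(n_clusters):
        for attempt in range(max_tries):
            cont_mean = {
                t: float(rng.uniform(*CONTINUOUS_RANGES[t])) for t in CONTINUOUS_TRAITS
            }
            candidate = ClusterArchetype(
                cont_mean=cont_mean,
                cont_sd={t: cont_sd_frac * cont_mean[t] for t in CONTINUOUS_TRAITS},
                cat_modal={t: str(rng.choice(vocab[t])) for t in CATEGORICAL_TRAITS},
                consensus={t: consensus for t in CATEGORICAL_TRAITS},
            )
            if all(_archetype_distance(candidate, a) >= min_separation for a in accepted):
                accepted.append(candidate)
                break
        else:
            raise RuntimeError(
                f"could not place {n_clusters} archetypes at separation {min_separation}"
            )
    return tuple(accepted)


def collection_like_config(seed: int = 0, missing_rate: float = 0.0) -> PhenotypeSimConfig:
    """The bundled 1168-gene, 40-cluster configuration (see module docstring)."""
    rng = np.random.default_rng(seed)
    archetypes = random_archetypes(len(COLLECTION_SIZES), rng)
    return PhenotypeSimConfig(
        sizes=COLLECTION_SIZES,
        archetypes=archetypes,
        missing_rate=missing_rate,
        seed=seed,
    )


def simulate_phenotypes(config: PhenotypeSimConfig) -> tuple[PhenotypeTable, np.ndarray]:
    """Generate a phenotype table with planted clusters.

    Continuous values are normal around the archetype mean (clipped at
    0, growth and height being physical quantities); categorical values
    are the modal label with the archetype's consensus probability, else
    uniform over the remaining vocabulary. Missingness, if requested, is
    applied uniformly per cell. Returns the table and the planted
    cluster label (1-based) per gene.
    """
    rng = np.random.default_rng(config.seed)
    vocab = {s.trait_name: s.vocabulary for s in config.schema if s.kind == "categorical"}
    n = sum(config.sizes)
    rows: list[dict[str, object]] = []
    truth = np.empty(n, dtype=int)
    g = 0
    for c, (size, arch) in enumerate(zip(config.sizes, config.archetypes), start=1):
        for _ in range(size):
            row: dict[str, object] = {"gene_id": f"SYN{g + 1:05d}"}
            for trait in CONTINUOUS_TRAITS:
                value = rng.normal(arch.cont_mean[trait], arch.cont_sd[trait])
                row[trait] = max(0.0, float(value))
            for trait in CATEGORICAL_TRAITS:
                modal = arch.cat_modal[trait]
                if rng.random() < arch.consensus[trait]:
                    row[trait] = modal
                else:
                    others = [lab for lab in vocab[trait] if lab != modal]
                    row[trait] = str(rng.choice(others))
            truth[g] = c
            rows.append(row)
            g += 1
    data = pd.DataFrame(rows)
    if config.missing_rate > 0:
        mask = rng.random((n, len(ALL_TRAITS))) < config.missing_rate
        for j, trait in enumerate(ALL_TRAITS):
            data.loc[mask[:, j], trait] = np.nan
    return PhenotypeTable(schema=config.schema, data=data), truth


# ---------------------------------------------------------------------------
# Expression time courses


def _template_bank(n_timepoints: int) -> np.ndarray:
    """A bank of distinct profile shapes over [0, 1], standardized to
    mean 0 / SD 2 to match the downstream standardization."""
    t = np.linspace(0.0, 1.0, n_timepoints)
    shapes = [
        np.exp(-((t - 0.0) ** 2) / 0.03),               # peak at start, decay
        np.exp(-((t - 0.3) ** 2) / 0.02),               # early-mid pulse
        np.exp(-((t - 0.55) ** 2) / 0.02),              # mid-course pulse
        np.exp(-((t - 1.0) ** 2) / 0.03),               # late induction
        t,                                              # monotone rise
        -np.exp(-((t - 0.8) ** 2) / 0.02),              # late dip
        np.cos(2.0 * np.pi * t),                        # down-up-down cycle
        np.minimum(1.0, np.maximum(0.0, 2.0 - 2.4 * t)),  # plateau then fall
    ]
    out = []
    for s in shapes:
        s = s - s.mean()
        out.append(2.0 * s / s.std(ddof=1))
    return np.vstack(out)


@dataclass(frozen=True)
class ExpressionSimConfig:
    n_profiles: int = 6
    genes_per_profile: int = 40
    n_timepoints: int = 8
    noise_sd: float = 0.25
    seed: int = 0
    templates: np.ndarray | None = None  # overrides the built-in bank

    def __post_init__(self) -> None:
        if self.n_profiles < 2:
            raise ValueError("need at least 2 profiles")
        if self.genes_per_profile < 1:
            raise ValueError("genes_per_profile must be >= 1")
        if self.n_timepoints < 2:
            raise ValueError("need at least 2 time points")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.templates is None and self.n_profiles > 8:
            raise ValueError("built-in template bank has 8 shapes")


def simulate_expression(config: ExpressionSimConfig) -> tuple[ExpressionMatrix, np.ndarray]:
    """Generate a time-course matrix with planted expression profiles.

    Each gene's curve is its profile template plus i.i.d. normal noise.
    Templates must be pairwise distinguishable (correlation < 0.9),
    enforced at generation time.
    """
    rng = np.random.default_rng(config.seed)
    if config.templates is not None:
        templates = np.asarray(config.templates, dtype=float)
        if templates.shape != (config.n_profiles, config.n_timepoints):
            raise ValueError("templates shape must be (n_profiles, n_timepoints)")
    else:
        templates = _template_bank(config.n_timepoints)[: config.n_profiles]
    corr = np.corrcoef(templates)
    np.fill_diagonal(corr, -1.0)
    if corr.max() >= 0.9:
        # anti-correlated shapes are still distinct; only near-duplicates fail
        raise ValueError("profile templates are too correlated (r >= 0.9)")

    n = config.n_profiles * config.genes_per_profile
    truth = np.repeat(np.arange(1, config.n_profiles + 1), config.genes_per_profile)
    values = templates[truth - 1] + rng.normal(0.0, config.noise_sd, size=(n, config.n_timepoints))
    expr = ExpressionMatrix(
        ids=tuple(f"SYN{i + 1:05d}" for i in range(n)),
        timepoints=tuple(f"t{j}" for j in range(config.n_timepoints)),
        values=values,
    )
    return expr, truth


# ---------------------------------------------------------------------------
# Annotations


def simulate_annotations(
    ids: Sequence[str],
    labels: Sequence[int],
    enrichment: Mapping[str, Mapping[int, float] | float],
    seed: int = 0,
    genome_lg_props: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Generate boolean gene attributes enriched per planted cluster.

    ``enrichment`` maps attribute name to either a global Bernoulli
    probability or a per-cluster mapping {cluster label: probability};
    clusters absent from the mapping default to 0. ``is_GPCR`` draws
    force ``has_TM`` true so the implication holds. Linkage groups are
    multinomial over seven chromosomes with the given genome
    proportions (uniform by default).
    """
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels, dtype=int)
    if len(ids) != len(labels):
        raise ValueError("ids and labels length mismatch")
    n = len(ids)
    out = pd.DataFrame({"gene_id": list(ids)})
    for attr, spec in enrichment.items():
        if isinstance(spec, Mapping):
            p = np.array([float(spec.get(int(c), 0.0)) for c in labels])
        else:
            p = np.full(n, float(spec))
        if ((p < 0) | (p > 1)).any():
            raise ValueError(f"probabilities for {attr} must be in [0, 1]")
        out[attr] = rng.random(n) < p
    if "is_GPCR" in out.columns:
        if "has_TM" not in out.columns:
            out["has_TM"] = False
        out["has_TM"] = out["has_TM"] | out["is_GPCR"]
    props = np.asarray(
        genome_lg_props if genome_lg_props is not None else np.full(7, 1.0 / 7.0),
        dtype=float,
    )
    if props.shape != (7,) or not np.isclose(props.sum(), 1.0):
        raise ValueError("genome_lg_props must be 7 proportions summing to 1")
    out["linkage_group"] = rng.choice(np.arange(1, 8), size=n, p=props)
    return out
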