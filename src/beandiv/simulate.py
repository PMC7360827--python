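"""Synthetic germplasm collections with known gene-pool structure.

Real accession-level trait matrices for regional common bean
collections are rarely deposited, so the pipeline is exercised on
simulated collections built from two pool archetypes: quantitative
traits are Gaussian per pool (truncated at zero where the unit demands
positivity), qualitative states are categorical draws, and the derived
seed length/width ratio is recomputed from the drawn lengths.
Introgressed accessions are trait-wise mosaics: each trait comes from
the Andean parent with probability lambda, else from the Mesoamerican
parent. Every simulated accession carries its true pool label, so
cluster recovery and classifier accuracy can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .catalog import TraitCatalog, default_catalog
from .collection import Accession, GermplasmCollection
from .genepool import ANDEAN, INTROGRESSED, MESOAMERICAN

#: traits that must be strictly positive; draws are resampled until valid
_TRUNCATE_AT_ZERO = frozenset(
    {"DF", "DM", "PH", "NS", "NB", "NP", "PL", "PW", "NSP", "SL", "SW", "HSW"})

_REGIONS = ("I", "II", "III", "IV")

#: default region mix per pool: Mesoamerican types relatively more
#: frequent in region I, Andean in II-IV, introgressed in III-IV
_DEFAULT_REGION_WEIGHTS = {
    ANDEAN: {"I": 0.03, "II": 0.42, "III": 0.25, "IV": 0.30},
    MESOAMERICAN: {"I": 0.15, "II": 0.40, "III": 0.20, "IV": 0.25},
    INTROGRESSED: {"I": 0.02, "II": 0.30, "III": 0.33, "IV": 0.35},
}


@dataclass
class PoolArchetype:
    """Trait distributions of one gene pool."""

    name: str
    quantitative_params: dict[str, tuple[float, float]]  # trait -> (mean, sd)
    qualitative_params: dict[str, dict[int, float]]  # trait -> level -> prob

    def __post_init__(self) -> None:
        for code, (_, sd) in self.quantitative_params.items():
            if sd <= 0:
                raise ValueError(f"{self.name}: sd of {code} must be > 0")
        for code, probs in self.qualitative_params.items():
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9 or any(p < 0 for p in probs.values()):
                raise ValueError(
                    f"{self.name}: probabilities of {code} must be a "
                    f"distribution (sum {total})")


@dataclass
class SimulationConfig:
    """Study conditions for one simulated collection.

    Defaults reproduce a 115-accession regional collection: 52 pure
    Andean and 40 pure Mesoamerican draws plus an introgressed share of
    0.2 (23 accessions), i.e. a 45.2 / 34.8 / 20 percent pool split.
    """

    n_per_pool: dict[str, int] = field(
        default_factory=lambda: {ANDEAN: 52, MESOAMERICAN: 40})
    introgression_fraction: float = 0.2
    introgression_lambda: float = 0.5
    region_weights: dict[str, dict[str, float]] = field(
        default_factory=lambda: {p: dict(w) for p, w in _DEFAULT_REGION_WEIGHTS.items()})
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.n_per_pool.values()):
            raise ValueError("pool counts must be >= 0")
        if not 0 <= self.introgression_fraction < 1:
            raise ValueError("introgression_fraction must be in [0, 1)")
        if not 0 <= self.introgression_lambda <= 1:
            raise ValueError("introgression_lambda must be in [0, 1]")
        for pool, weights in self.region_weights.items():
            total = sum(weights.values())
            if abs(total - 1.0) > 1e-9 or any(w < 0 for w in weights.values()):
                raise ValueError(f"region weights of {pool} must be a distribution")

    @property
    def n_introgressed(self) -> int:
        f = self.introgression_fraction
        n_pure = sum(self.n_per_pool.values())
        return int(round(f / (1.0 - f) * n_pure))


@dataclass
class LabeledCollection:
    collection: GermplasmCollection
    true_pool: dict[str, str]  # accession id -> pool label


def _archetype_from_mapping(m: dict) -> PoolArchetype:
    return PoolArchetype(
        name=str(m["name"]),
        quantitative_params={
            str(k): (float(v[0]), float(v[1])) for k, v in m["quantitative"].items()},
        qualitative_params={
            str(k): {int(level): float(p) for level, p in probs.items()}
            for k, probs in m["qualitative"].items()},
    )


def _archetype_to_mapping(a: PoolArchetype) -> dict:
    return {
        "name": a.name,
        "quantitative": {k: [m, s] for k, (m, s) in a.quantitative_params.items()},
        "qualitative": {k: dict(v) for k, v in a.qualitative_params.items()},
    }


def load_archetypes(path: str | Path) -> tuple[PoolArchetype, PoolArchetype]:
    """Read the (andean, mesoamerican) archetype pair from a YAML file."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return (_archetype_from_mapping(raw["andean"]),
            _archetype_from_mapping(raw["mesoamerican"]))


def save_archetypes(andean: PoolArchetype, mesoamerican: PoolArchetype,
                    path: str | Path) -> Path:
    path = Path(path)
    payload = {"andean": _archetype_to_mapping(andean),
               "mesoamerican": _archetype_to_mapping(mesoamerican)}
    path.write_text(yaml.safe_dump(payload, sort_keys=False), encoding="utf-8")
    return path


def default_archetypes() -> tuple[PoolArchetype, PoolArchetype]:
    """The shipped (andean, mesoamerican) archetype pair."""
    ref = resources.files("beandiv").joinpath("data/archetypes.yaml")
    with resources.as_file(ref) as path:
        return load_archetypes(path)


def _draw_quantitative(mean: float, sd: float, code: str,
                       rng: np.random.Generator) -> float:
    v = rng.normal(mean, sd)
    if code in _TRUNCATE_AT_ZERO:
        while v <= 0:
            v = rng.normal(mean, sd)
    return float(v)


def sample_accession(archetype: PoolArchetype, catalog: TraitCatalog,
                     rng: np.random.Generator, acc_id: str = "acc") -> Accession:
    """Draw one accession from a single archetype.

    The seed length/width ratio (LWS) is recomputed from the drawn SL
    and SW rather than sampled independently.
    """
    acc = Accession(id=acc_id)
    for desc in catalog:
        if desc.code == "LWS":
            continue
        if desc.is_qualitative:
            if desc.code not in archetype.qualitative_params:
                raise KeyError(f"{archetype.name} archetype missing trait {desc.code}")
            probs = archetype.qualitative_params[desc.code]
            levels = sorted(probs)
            p = np.array([probs[lv] for lv in levels])
            acc.qualitative[desc.code] = int(rng.choice(levels, p=p / p.sum()))
        else:
            if desc.code not in archetype.quantitative_params:
                raise KeyError(f"{archetype.name} archetype missing trait {desc.code}")
            m, s = archetype.quantitative_params[desc.code]
            acc.quantitative[desc.code] = _draw_quantitative(m, s, desc.code, rng)
    if "LWS" in catalog:
        acc.quantitative["LWS"] = acc.quantitative["SL"] / acc.quantitative["SW"]
    return acc


def introgress(andean: PoolArchetype, mesoamerican: PoolArchetype,
               lambda_: float, catalog: TraitCatalog,
               rng: np.random.Generator, acc_id: str = "acc") -> Accession:
    """Draw a trait-wise mosaic accession.

    Each trait independently comes from the Andean archetype with
    probability ``lambda_`` and from the Mesoamerican archetype
    otherwise; LWS is recomputed from the drawn SL and SW.
    """
    if not 0 <= lambda_ <= 1:
        raise ValueError("lambda must be in [0, 1]")
    acc = Accession(id=acc_id)
    for desc in catalog:
        if desc.code == "LWS":
            continue
        parent = andean if rng.random() < lambda_ else mesoamerican
        if desc.is_qualitative:
            probs = parent.qualitative_params[desc.code]
            levels = sorted(probs)
            p = np.array([probs[lv] for lv in levels])
            acc.qualitative[desc.code] = int(rng.choice(levels, p=p / p.sum()))
        else:
            m, s = parent.quantitative_params[desc.code]
            acc.quantitative[desc.code] = _draw_quantitative(m, s, desc.code, rng)
    if "LWS" in catalog:
        acc.quantitative["LWS"] = acc.quantitative["SL"] / acc.quantitative["SW"]
    return acc


def simulate_collection(config: SimulationConfig | None = None,
                        catalog: TraitCatalog | None = None,
                        archetypes: tuple[PoolArchetype, PoolArchetype] | None = None,
                        ) -> LabeledCollection:
    """Generate a labeled collection under *config*.

    Deterministic given (config, catalog, archetypes): the same seed
    yields the same accessions, regions and labels.
    """
    config = config or SimulationConfig()
    catalog = catalog or default_catalog()
    andean, meso = archetypes or default_archetypes()
    by_name = {ANDEAN: andean, MESOAMERICAN: meso}
    rng = np.random.default_rng(config.seed)

    plan: list[str] = []
    for pool in sorted(config.n_per_pool):
        plan.extend([pool] * config.n_per_pool[pool])
    plan.extend([INTROGRESSED] * config.n_introgressed)

    accessions: list[Accession] = []
    true_pool: dict[str, str] = {}
    width = max(3, len(str(len(plan))))
    for i, pool in enumerate(plan):
        acc_id = f"CQ{i + 1:0{width}d}"
        if pool == INTROGRESSED:
            acc = introgress(andean, meso, config.introgression_lambda,
                             catalog, rng, acc_id)
        else:
            acc = sample_accession(by_name[pool], catalog, rng, acc_id)
        weights = config.region_weights.get(pool)
        if weights:
            regions = sorted(weights)
            p = np.array([weights[r] for r in regions])
            acc.region = str(rng.choice(regions, p=p / p.sum()))
        accessions.append(acc)
        true_pool[acc_id] = pool
    return LabeledCollection(GermplasmCollection(catalog, accessions), true_pool)
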