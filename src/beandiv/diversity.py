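"""Phenotypic diversity: class binning, Shannon-Weaver H', CV, aggregation.

Quantitative traits are discretized into ten classes centered on the
trait mean X with half-standard-deviation widths: class 1 collects
values below X - 2s, class 10 values above X + 2s, and the eight
interior classes tile [X - 2s, X + 2s] in steps of 0.5 s. The
Shannon-Weaver index

    H' = -sum_i p_i ln p_i

is then computed over the class (or, for qualitative traits, the raw
level) frequencies, with the natural logarithm. The coefficient of
variation CV = s / X uses the sample (n-1) standard deviation.

Organ-level diversity is the arithmetic mean of the member traits' H',
and the collection-wide index is the arithmetic mean over all traits.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np

from .catalog import ORGANS, TraitCatalog
from .collection import GermplasmCollection

N_CLASSES = 10


def round_half_up(x: float, ndigits: int = 3) -> float:
    """Round with ties away from zero (0.0005 -> 0.001), as trait tables do."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ClassBinning:
    """Ten-class discretization of one quantitative trait."""

    mean: float
    sd: float
    boundaries: np.ndarray  # 9 ascending cut points b_k = X - 2s + (k-1) 0.5s
    assignments: np.ndarray  # class index 1..10 per observation

    @property
    def counts(self) -> dict[int, int]:
        return {c: int((self.assignments == c).sum()) for c in range(1, N_CLASSES + 1)}


@dataclass
class DiversityIndex:
    """Per-trait diversity summary."""

    trait_code: str
    H: float
    class_counts: dict[int, int]
    cv: float | None = None  # quantitative traits only

    @property
    def n_classes_occupied(self) -> int:
        return sum(1 for c in self.class_counts.values() if c > 0)


@dataclass
class DiversityReport:
    per_trait: list[DiversityIndex]
    per_organ: dict[tuple[str, str], float]  # (organ, kind) -> mean H'
    overall_mean: float
    per_region: dict[str, float] = field(default_factory=dict)
    dropped: dict[str, int] = field(default_factory=dict)  # trait -> n missing dropped

    def trait(self, code: str) -> DiversityIndex:
        for t in self.per_trait:
            if t.trait_code == code:
                return t
        raise KeyError(code)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["trait", "H", "cv", "n_classes_occupied", "n_obs"])
            for t in self.per_trait:
                w.writerow([
                    t.trait_code,
                    round_half_up(t.H, 3),
                    "" if t.cv is None else round_half_up(t.cv, 4),
                    t.n_classes_occupied,
                    sum(t.class_counts.values()),
                ])
        return path

    def to_json(self) -> str:
        payload = {
            "per_trait": [
                {"trait": t.trait_code, "H": t.H, "cv": t.cv,
                 "class_counts": {str(k): v for k, v in t.class_counts.items()}}
                for t in self.per_trait
            ],
            "per_organ": {f"{o}/{k}": v for (o, k), v in self.per_organ.items()},
            "overall_mean": self.overall_mean,
            "per_region": self.per_region,
            "dropped": self.dropped,
        }
        return json.dumps(payload, indent=2)


def frequency_table(values: list[int]) -> dict[int, float]:
    """Observed-level proportions; proportions sum to one."""
    if len(values) == 0:
        raise ValueError("frequency_table requires a non-empty list")
    n = len(values)
    out: dict[int, float] = {}
    for v in values:
        out[v] = out.get(v, 0.0) + 1.0
    return {k: out[k] / n for k in sorted(out)}


def shannon_index(counts: dict) -> float:
    """Shannon-Weaver H' = -sum p_i ln p_i over non-empty classes (nats).

    *counts* maps class/level -> count (any non-negative weights work;
    only the proportions matter). Empty classes contribute nothing.
    """
    vals = np.asarray(list(counts.values()), dtype=float)
    if (vals < 0).any():
        raise ValueError("counts must be non-negative")
    total = vals.sum()
    if total <= 0:
        raise ValueError("shannon_index requires a positive total count")
    p = vals[vals > 0] / total
    return float(-(p * np.log(p)).sum())


def assign_classes(values) -> ClassBinning:
    """Bin observations into the ten 0.5 s classes around the mean.

    Class 1 iff x < X - 2s; class 10 iff x > X + 2s; interior class j
    (2..9) covers [b_{j-1}, b_j) with b_k = X - 2s + (k-1) 0.5 s, except
    that x exactly equal to X + 2s stays in class 9 (the upper tail is
    strict). Degenerate s = 0 puts everything in class 6, whose lower
    bound is the mean.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("assign_classes requires at least 2 values")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    boundaries = mean - 2.0 * sd + 0.5 * sd * np.arange(9)
    if sd == 0.0:
        classes = np.full(x.shape, 6, dtype=int)
        return ClassBinning(mean, sd, boundaries, classes)
    # searchsorted(side="right"): x < b1 -> 0, b_k <= x < b_{k+1} -> k, x >= b9 -> 9
    classes = np.searchsorted(boundaries, x, side="right") + 1
    classes[x == boundaries[-1]] = 9  # X + 2s itself stays in class 9
    return ClassBinning(mean, sd, boundaries, classes.astype(int))


def coefficient_of_variation(values) -> float:
    """CV = s / X with the sample (n-1) standard deviation."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("coefficient_of_variation requires at least 2 values")
    mean = x.mean()
    if mean == 0:
        raise ValueError("coefficient_of_variation undefined for zero mean")
    return float(x.std(ddof=1) / mean)


def quantitative_trait_diversity(values, trait_code: str = "") -> DiversityIndex:
    """H' of the ten-class binning, plus CV, for one quantitative trait."""
    binning = assign_classes(values)
    counts = {c: n for c, n in binning.counts.items()}
    return DiversityIndex(
        trait_code=trait_code,
        H=shannon_index({c: n for c, n in counts.items() if n > 0}),
        class_counts=counts,
        cv=coefficient_of_variation(values),
    )


def qualitative_trait_diversity(values: list[int], trait_code: str = "") -> DiversityIndex:
    """H' over raw level frequencies for one qualitative trait."""
    if len(values) < 2:
        raise ValueError("need at least 2 observations")
    counts: dict[int, int] = {}
    for v in values:
        counts[v] = counts.get(v, 0) + 1
    return DiversityIndex(trait_code=trait_code, H=shannon_index(counts),
                          class_counts=counts, cv=None)


def organ_diversity(trait_H) -> float:
    """Organ-level H': arithmetic mean of the member traits' indices."""
    hs = list(trait_H)
    if not hs:
        raise ValueError("organ_diversity requires at least one trait")
    return float(np.mean(hs))


def _per_trait_indices(collection: GermplasmCollection) -> tuple[list[DiversityIndex], dict[str, int]]:
    indices: list[DiversityIndex] = []
    dropped: dict[str, int] = {}
    n = len(collection)
    for desc in collection.catalog:
        vals = collection.trait_values(desc.code)
        n_missing = n - len(vals)
        if n_missing:
            dropped[desc.code] = n_missing
        if len(vals) < 2:
            raise ValueError(
                f"trait {desc.code} has {len(vals)} non-missing observation(s); "
                "need at least 2")
        if desc.is_qualitative:
            indices.append(qualitative_trait_diversity(vals, desc.code))
        else:
            indices.append(quantitative_trait_diversity(vals, desc.code))
    return indices, dropped


def diversity_report(collection: GermplasmCollection) -> DiversityReport:
    """Full diversity analysis of a collection.

    Per-trait H' (qualitative from level frequencies, quantitative from
    the ten-class binning, with CV), organ-level means split by trait
    kind, the overall mean over every trait, and per-region overall
    means recomputed on each region's accession subset.
    """
    indices, dropped = _per_trait_indices(collection)
    h_by_code = {t.trait_code: t.H for t in indices}
    catalog: TraitCatalog = collection.catalog

    per_organ: dict[tuple[str, str], float] = {}
    for organ in ORGANS:
        for kind in ("qualitative", "quantitative"):
            members = catalog.by_organ(organ, kind)
            if members:
                per_organ[(organ, kind)] = organ_diversity(
                    [h_by_code[d.code] for d in members])

    overall = organ_diversity(list(h_by_code.values()))

    per_region: dict[str, float] = {}
    regions = sorted({a.region for a in collection if a.region is not None})
    for region in regions:
        sub = GermplasmCollection(
            catalog, [a for a in collection if a.region == region])
        try:
            sub_indices, _ = _per_trait_indices(sub)
        except ValueError:
            continue  # region too small to score every trait
        per_region[region] = organ_diversity([t.H for t in sub_indices])

    return DiversityReport(per_trait=indices, per_organ=per_organ,
                           overall_mean=overall, per_region=per_region,
                           dropped=dropped)
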