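"""Rule-based Andean / Mesoamerican / introgressed gene-pool assignment.

Domesticated common bean comprises two major lineages. Andean types
typically carry large (high hundred-seed weight), speckled seeds, erect
or determinate plants, and white-to-pink flowers; Mesoamerican types
carry small speckle-free seeds with plain black/yellow/white coats on
prostrate, indeterminate plants. Each diagnostic signal fires one rule;
a subject is called for a pool only when its score exceeds the rival
pool's score by at least two rules, otherwise it is called introgressed
(trait combinations from both pools).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from .clustering import GroupProfile
from .collection import Accession, GermplasmCollection

ANDEAN = "Andean"
MESOAMERICAN = "Mesoamerican"
INTROGRESSED = "Introgressed"

#: hundred-seed-weight market classes, g per 100 seeds
SMALL_SEED_MAX = 25.0
LARGE_SEED_MIN = 40.0
#: HSW at or above this fires the Andean large/medium-large seed rule
ANDEAN_SEED_MIN = 35.0
#: score margin required for a pure-pool call
CALL_MARGIN = 2

_WHITE_PINK_FLOWERS = {1, 2, 3}  # white, pinkish-white, pinkish-red
_PLAIN_MESO_COATS = {2, 3, 4}  # yellow, white, black
_SSC_FREE = 0
_GH_ERECT, _GH_PROSTRATE = 1, 2
_PHA_DETERMINATE, _PHA_INDETERMINATE = 1, 2


@dataclass(frozen=True)
class SeedSizeClass:
    value: str  # small | medium | large


@dataclass
class GenePoolCall:
    subject: str
    call: str
    andean_score: int
    mesoamerican_score: int
    evidence: list[str] = field(default_factory=list)


def classify_seed_size(hsw: float) -> SeedSizeClass:
    """Market seed-size class from hundred-seed weight (g)."""
    if hsw <= 0:
        raise ValueError(f"HSW must be positive, got {hsw}")
    if hsw < SMALL_SEED_MAX:
        return SeedSizeClass("small")
    if hsw > LARGE_SEED_MIN:
        return SeedSizeClass("large")
    return SeedSizeClass("medium")


def _score(subject: str, hsw, gh, pha, ssc, scc, cs) -> GenePoolCall:
    evidence: list[str] = []
    andean = 0
    meso = 0
    if hsw is not None and hsw >= ANDEAN_SEED_MIN:
        andean += 1
        evidence.append("andean:large-or-medium-large-seed")
    if ssc is not None and ssc != _SSC_FREE:
        andean += 1
        evidence.append("andean:speckled-seed-coat")
    if (gh == _GH_ERECT) or (pha == _PHA_DETERMINATE):
        andean += 1
        evidence.append("andean:erect-or-determinate")
    if cs is not None and cs in _WHITE_PINK_FLOWERS:
        andean += 1
        evidence.append("andean:white-pink-flower")
    if hsw is not None and hsw < SMALL_SEED_MAX:
        meso += 1
        evidence.append("mesoamerican:small-seed")
    if ssc is not None and ssc == _SSC_FREE:
        meso += 1
        evidence.append("mesoamerican:speckle-free-coat")
    if (gh == _GH_PROSTRATE) and (pha == _PHA_INDETERMINATE):
        meso += 1
        evidence.append("mesoamerican:prostrate-indeterminate")
    if scc is not None and scc in _PLAIN_MESO_COATS:
        meso += 1
        evidence.append("mesoamerican:plain-black-yellow-white-coat")
    if not evidence:
        evidence.append("no-diagnostic-trait-available")

    if andean >= meso + CALL_MARGIN:
        call = ANDEAN
    elif meso >= andean + CALL_MARGIN:
        call = MESOAMERICAN
    else:
        call = INTROGRESSED
    return GenePoolCall(subject, call, andean, meso, evidence)


def classify_gene_pool(profile: GroupProfile) -> GenePoolCall:
    """Call the gene pool of a cluster group from its trait profile.

    Uses the group HSW mean and the modal levels of GH, PHA, SSC, SCC
    and CS. Missing summaries simply leave their rules unfired.
    """
    hsw = profile.quantitative_summary.get("HSW", (None,))[0]
    modal = {c: profile.qualitative_summary.get(c, (None,))[0]
             for c in ("GH", "PHA", "SSC", "SCC", "CS")}
    return _score(profile.group_label, hsw, modal["GH"], modal["PHA"],
                  modal["SSC"], modal["SCC"], modal["CS"])


def classify_accession(accession: Accession) -> GenePoolCall:
    """Apply the same diagnostic rules to a single accession's raw values."""
    return _score(
        accession.id,
        accession.quantitative.get("HSW"),
        accession.qualitative.get("GH"),
        accession.qualitative.get("PHA"),
        accession.qualitative.get("SSC"),
        accession.qualitative.get("SCC"),
        accession.qualitative.get("CS"),
    )


def regional_composition(collection: GermplasmCollection,
                         calls: dict[str, GenePoolCall]) -> dict:
    """Region x gene-pool contingency with within-total percentages.

    Returns ``{"total": {pool: {"count", "pct"}}, "by_region": {region:
    {pool: {"count", "pct"}}}}``; percentages are of the full collection
    (1 dp), so the pool percentages inside one region sum to that
    region's share.
    """
    pools = (ANDEAN, MESOAMERICAN, INTROGRESSED)
    n = len(collection)
    if n == 0:
        raise ValueError("empty collection")
    total = {p: 0 for p in pools}
    by_region: dict[str, dict[str, int]] = {}
    for acc in collection:
        if acc.id not in calls:
            raise KeyError(f"no gene-pool call for accession {acc.id}")
        if acc.region is None:
            raise ValueError(f"accession {acc.id} lacks a region")
        pool = calls[acc.id].call
        total[pool] += 1
        by_region.setdefault(acc.region, {p: 0 for p in pools})[pool] += 1

    def pct(c: int) -> float:
        return round(c / n * 100.0, 1)

    return {
        "n": n,
        "total": {p: {"count": c, "pct": pct(c)} for p, c in total.items()},
        "by_region": {
            r: {p: {"count": c, "pct": pct(c)} for p, c in row.items()}
            for r, row in sorted(by_region.items())
        },
    }


def composition_to_csv(composition: dict, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["region", "pool", "count", "pct"])
        for pool, cell in composition["total"].items():
            w.writerow(["all", pool, cell["count"], cell["pct"]])
        for region, row in composition["by_region"].items():
            for pool, cell in row.items():
                w.writerow([region, pool, cell["count"], cell["pct"]])
    return path
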