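"""Shared fixtures and independent brute-force oracles.

The oracles deliberately re-derive their results by enumeration or
double loops so they stay independent of the vectorized implementation
paths they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from beandiv import (
    Accession,
    GermplasmCollection,
    SimulationConfig,
    default_catalog,
    simulate_collection,
)


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


def make_accession(catalog, acc_id="A1", region="I", **overrides):
    """A fully populated, valid accession with optional trait overrides."""
    qual = {d.code: min(d.levels) for d in catalog.qualitative}
    quant = {
        "DF": 45.0, "DM": 75.0, "PH": 80.0, "NS": 12.0, "NB": 4.0,
        "NP": 8.0, "PL": 12.0, "PW": 1.1, "NSP": 5.0,
        "SL": 1.5, "SW": 0.9, "LWS": 1.5 / 0.9, "HSW": 35.0,
    }
    for code, value in overrides.items():
        if code in qual:
            qual[code] = value
        else:
            quant[code] = value
    return Accession(id=acc_id, region=region, county="Wulong",
                     qualitative=qual, quantitative=quant)


@pytest.fixture
def accession_factory(catalog):
    return lambda **kw: make_accession(catalog, **kw)


@pytest.fixture
def small_collection(catalog):
    """Three valid hand-built accessions with a little trait variation."""
    rng = np.random.default_rng(7)
    accs = []
    for i in range(3):
        acc = make_accession(
            catalog, acc_id=f"A{i + 1}", region=["I", "II", "II"][i],
            HSW=30.0 + 5 * i, PH=70.0 + 10 * i, GH=1 + i % 2)
        for code in acc.quantitative:
            if code != "LWS":
                acc.quantitative[code] *= float(1 + 0.05 * rng.normal())
        acc.quantitative["LWS"] = acc.quantitative["SL"] / acc.quantitative["SW"]
        accs.append(acc)
    return GermplasmCollection(catalog, accs)


@pytest.fixture(scope="session")
def default_simulated():
    """One default 115-accession simulated collection (seeded)."""
    return simulate_collection(SimulationConfig(seed=11))


# ---------------------------------------------------------------- oracles

def binning_oracle(values):
    """Enumerate the 9 boundaries and bin each value by linear scan."""
    x = np.asarray(values, dtype=float)
    mean = x.mean()
    sd = x.std(ddof=1)
    if sd == 0:
        return [6] * len(x)
    b = [mean - 2 * sd + (k - 1) * 0.5 * sd for k in range(1, 10)]
    out = []
    for v in x:
        if v < b[0]:
            out.append(1)
        elif v > b[8]:
            out.append(10)
        elif v == b[8]:
            out.append(9)
        else:
            for j in range(2, 10):
                if b[j - 2] <= v < b[j - 1]:
                    out.append(j)
                    break
            else:  # v == b[8] handled above; floating edge lands in 9
                out.append(9)
    return out


def naive_upgma_heights(dist):
    """O(n^3) UPGMA: average distances recomputed over original leaf pairs."""
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    clusters = [{i} for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = np.mean([dist[a, b] for a in clusters[i] for b in clusters[j]])
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        heights.append(d)
        clusters[i] = clusters[i] | clusters[j]
        del clusters[j]
    return heights


def shannon_oracle(counts):
    """Literal -sum p ln p over positive counts."""
    import math

    total = sum(counts.values())
    return -sum((c / total) * math.log(c / total) for c in counts.values() if c > 0)
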