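"""Trait catalog for common bean morpho-agronomic characterization.

The catalog holds the 29 descriptors used to characterize common bean
(*Phaseolus vulgaris* L.) germplasm: 13 quantitative traits (days to
flowering, plant height, hundred-seed weight, ...) and 16 qualitative
traits whose states are recorded as small integer codes (growth habit
1 = erect / 2 = prostrate, speckle of seed coat 0 = free / 1 = punctiform
/ 2 = stripe / 3 = reticulate, ...). Each descriptor knows the plant
organ (variable set) it belongs to, which drives the organ-level
aggregation of diversity indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

ORGANS = ("phenology", "plant", "leaf", "flower", "pod", "seed")
KINDS = ("qualitative", "quantitative")


@dataclass(frozen=True)
class TraitDescriptor:
    """One morpho-agronomic character.

    Parameters
    ----------
    code : str
        Short symbol, e.g. ``"HSW"`` for hundred-seed weight.
    name : str
        Human-readable character name.
    organ : str
        Variable set (plant organ): one of ``phenology``, ``plant``,
        ``leaf``, ``flower``, ``pod``, ``seed``.
    kind : str
        ``"quantitative"`` (real-valued, with a unit) or
        ``"qualitative"`` (integer-coded states).
    levels : dict[int, str]
        Ordered map level code -> label; qualitative traits only.
    unit : str
        Measurement unit; quantitative traits only (may be "" for
        dimensionless counts and ratios).
    """

    code: str
    name: str
    organ: str
    kind: str
    levels: dict[int, str] = field(default_factory=dict)
    unit: str = ""

    def __post_init__(self) -> None:
        if self.organ not in ORGANS:
            raise ValueError(f"unknown organ {self.organ!r} for trait {self.code}")
        if self.kind not in KINDS:
            raise ValueError(f"unknown kind {self.kind!r} for trait {self.code}")
        if self.kind == "qualitative":
            if len(self.levels) < 2:
                raise ValueError(f"qualitative trait {self.code} needs >=2 levels")
        elif self.levels:
            raise ValueError(f"quantitative trait {self.code} must not declare levels")

    @property
    def is_qualitative(self) -> bool:
        return self.kind == "qualitative"


@dataclass(frozen=True)
class TraitCatalog:
    """Ordered, code-unique set of trait descriptors."""

    descriptors: tuple[TraitDescriptor, ...]

    def __post_init__(self) -> None:
        codes = [d.code for d in self.descriptors]
        if len(set(codes)) != len(codes):
            dupes = sorted({c for c in codes if codes.count(c) > 1})
            raise ValueError(f"duplicate trait codes in catalog: {dupes}")

    def __iter__(self):
        return iter(self.descriptors)

    def __len__(self) -> int:
        return len(self.descriptors)

    def __contains__(self, code: str) -> bool:
        return any(d.code == code for d in self.descriptors)

    def __getitem__(self, code: str) -> TraitDescriptor:
        for d in self.descriptors:
            if d.code == code:
                return d
        raise KeyError(code)

    @property
    def codes(self) -> list[str]:
        return [d.code for d in self.descriptors]

    @property
    def qualitative(self) -> list[TraitDescriptor]:
        return [d for d in self.descriptors if d.kind == "qualitative"]

    @property
    def quantitative(self) -> list[TraitDescriptor]:
        return [d for d in self.descriptors if d.kind == "quantitative"]

    def by_organ(self, organ: str, kind: str | None = None) -> list[TraitDescriptor]:
        out = [d for d in self.descriptors if d.organ == organ]
        if kind is not None:
            out = [d for d in out if d.kind == kind]
        return out


_FLOWER_COLORS = {
    1: "white",
    2: "pinkish-white",
    3: "pinkish-red",
    4: "purple",
    5: "light purple",
}


def default_catalog() -> TraitCatalog:
    """The standard 29-trait descriptor set (13 quantitative, 16 qualitative)."""
    q = TraitDescriptor  # local alias keeps the table readable
    descriptors = (
        # phenology -------------------------------------------------- quantitative
        q("DF", "days to flowering", "phenology", "quantitative", unit="d"),
        q("DM", "days to physiological maturity", "phenology", "quantitative", unit="d"),
        # plant
        q("PH", "plant height", "plant", "quantitative", unit="cm"),
        q("NS", "node number of the main stem", "plant", "quantitative", unit=""),
        q("NB", "number of primary branches", "plant", "quantitative", unit=""),
        # pod
        q("NP", "number of pods per plant", "pod", "quantitative", unit=""),
        q("PL", "pod length", "pod", "quantitative", unit="cm"),
        q("PW", "pod width", "pod", "quantitative", unit="cm"),
        q("NSP", "number of seeds per pod", "pod", "quantitative", unit=""),
        # seed
        q("SL", "seed length", "seed", "quantitative", unit="cm"),
        q("SW", "seed width", "seed", "quantitative", unit="cm"),
        q("LWS", "length/width of seed", "seed", "quantitative", unit=""),
        q("HSW", "hundred-seed weight", "seed", "quantitative", unit="g"),
        # plant ------------------------------------------------------- qualitative
        q("HP", "hypocotyl pigmentation", "plant", "qualitative",
          levels={1: "green", 2: "purple"}),
        q("GH", "growth habit", "plant", "qualitative",
          levels={1: "erect", 2: "prostrate"}),
        q("PHA", "podding habit", "plant", "qualitative",
          levels={1: "determinate", 2: "indeterminate"}),
        q("ST", "stem type", "plant", "qualitative",
          levels={1: "normal stem", 2: "clasp stem"}),
        # leaf
        q("LS", "leaf shape", "leaf", "qualitative",
          levels={1: "ovate", 2: "rhombic ovate"}),
        # flower
        q("CS", "color of standard", "flower", "qualitative", levels=dict(_FLOWER_COLORS)),
        q("CW", "color of wings", "flower", "qualitative", levels=dict(_FLOWER_COLORS)),
        # pod
        q("PC", "pod color", "pod", "qualitative",
          levels={1: "stripe", 2: "light brown", 3: "yellowish white", 4: "brown"}),
        q("SP", "shape of pod", "pod", "qualitative",
          levels={1: "round curved", 2: "short flat strip", 3: "long flat strip",
                  4: "sickle-shaped", 5: "sword-shaped", 6: "round curved stick-shaped",
                  7: "short round stick-shaped", 8: "long round stick-shaped"}),
        q("SPA", "shape of pod apex", "pod", "qualitative",
          levels={1: "acute apex", 2: "obtuse apex"}),
        q("PS", "pod surface", "pod", "qualitative",
          levels={1: "tiny protruding", 2: "protruding", 3: "flat"}),
        # seed
        q("SS", "seed shape", "seed", "qualitative",
          levels={1: "long elliptic", 2: "ovate", 3: "flat round", 4: "square",
                  5: "short cylinder", 6: "elliptic", 7: "kidney-shaped", 8: "round"}),
        q("SCC", "seed coat color", "seed", "qualitative",
          levels={1: "stripe", 2: "yellow", 3: "white", 4: "black", 5: "brown",
                  6: "yellowish-white", 7: "pinkish-red", 8: "milk white",
                  9: "deep yellow", 10: "red"}),
        q("SSC", "speckle of seed coat", "seed", "qualitative",
          levels={0: "free", 1: "punctiform", 2: "stripe", 3: "reticulate"}),
        q("CSSC", "color speckle of seed coat", "seed", "qualitative",
          levels={0: "free", 1: "brown", 2: "pink", 3: "black",
                  4: "light brown", 5: "red"}),
        q("HC", "hilum color", "seed", "qualitative",
          levels={1: "yellowish-white", 2: "white", 3: "light brown"}),
    )
    return TraitCatalog(descriptors)
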