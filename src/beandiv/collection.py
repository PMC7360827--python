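"""Germplasm collection data model and tabular I/O.

A collection is a set of accessions (seed lots), each carrying metadata
(id, natural ecological region I-IV, county of origin), integer-coded
qualitative trait states and real-valued quantitative traits, all
validated against a :class:`~beandiv.catalog.TraitCatalog`.

File dialect: UTF-8 CSV, one row per accession, header row of
``id,region,county`` plus trait codes; empty cell = missing value.
Qualitative cells hold the integer state codes, never the labels.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .catalog import TraitCatalog, default_catalog

REGIONS = ("I", "II", "III", "IV")

#: quantitative traits that must be strictly positive / non-negative
_POSITIVE_TRAITS = frozenset({"HSW", "PH", "PL", "PW", "SL", "SW", "LWS", "DF", "DM"})
_COUNT_TRAITS = frozenset({"NS", "NB", "NP", "NSP"})

_META_COLUMNS = ("id", "region", "county")


@dataclass
class Accession:
    id: str
    region: str | None = None
    county: str = ""
    qualitative: dict[str, int] = field(default_factory=dict)
    quantitative: dict[str, float] = field(default_factory=dict)

    def value(self, code: str) -> float | int | None:
        """Trait value by code, or None if missing."""
        if code in self.qualitative:
            return self.qualitative[code]
        return self.quantitative.get(code)


@dataclass(frozen=True)
class Violation:
    accession: str
    trait: str
    rule: str
    message: str


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __len__(self) -> int:
        return len(self.violations)

    def to_json(self) -> str:
        return json.dumps(
            [v.__dict__ for v in self.violations], indent=2, ensure_ascii=False
        )


class CollectionError(ValueError):
    """Raised for structurally invalid collection files."""


@dataclass
class GermplasmCollection:
    catalog: TraitCatalog
    accessions: list[Accession]

    def __post_init__(self) -> None:
        ids = [a.id for a in self.accessions]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CollectionError(f"duplicate accession ids: {dupes}")

    def __len__(self) -> int:
        return len(self.accessions)

    def __iter__(self):
        return iter(self.accessions)

    @property
    def ids(self) -> list[str]:
        return [a.id for a in self.accessions]

    def trait_values(self, code: str, drop_missing: bool = True) -> list:
        """All values of one trait across accessions, missing dropped."""
        vals = [a.value(code) for a in self.accessions]
        if drop_missing:
            vals = [v for v in vals if v is not None]
        return vals

    def subset(self, ids: list[str]) -> "GermplasmCollection":
        wanted = set(ids)
        return GermplasmCollection(
            self.catalog, [a for a in self.accessions if a.id in wanted]
        )

    def to_frame(self) -> pd.DataFrame:
        """Wide DataFrame: metadata columns then traits in catalog order."""
        rows = []
        for a in self.accessions:
            row: dict = {"id": a.id, "region": a.region, "county": a.county or None}
            for d in self.catalog:
                row[d.code] = a.value(d.code)
            rows.append(row)
        df = pd.DataFrame(rows, columns=list(_META_COLUMNS) + self.catalog.codes)
        for d in self.catalog.qualitative:
            df[d.code] = df[d.code].astype("Int64")
        return df


def validate_collection(collection: GermplasmCollection) -> ValidationReport:
    """Check every accession against the catalog's invariants.

    Violations are returned as data, never raised: a curation workflow
    wants the full list, not the first failure.
    """
    report = ValidationReport()
    cat = collection.catalog
    for acc in collection:
        if acc.region is not None and acc.region not in REGIONS:
            report.violations.append(
                Violation(acc.id, "region", "region-domain",
                          f"region {acc.region!r} not one of {REGIONS}")
            )
        for code, level in acc.qualitative.items():
            if code not in cat:
                report.violations.append(
                    Violation(acc.id, code, "unknown-trait", f"trait {code} not in catalog"))
                continue
            desc = cat[code]
            if not desc.is_qualitative:
                report.violations.append(
                    Violation(acc.id, code, "kind-mismatch",
                              f"{code} is quantitative but stored as a level"))
            elif level not in desc.levels:
                report.violations.append(
                    Violation(acc.id, code, "level-domain",
                              f"level {level} not declared for {code} "
                              f"(allowed {sorted(desc.levels)})"))
        for code, value in acc.quantitative.items():
            if code not in cat:
                report.violations.append(
                    Violation(acc.id, code, "unknown-trait", f"trait {code} not in catalog"))
                continue
            if not math.isfinite(value):
                report.violations.append(
                    Violation(acc.id, code, "finite", f"{code} = {value} is not finite"))
                continue
            if code in _POSITIVE_TRAITS and value <= 0:
                report.violations.append(
                    Violation(acc.id, code, "positive", f"{code} = {value} must be > 0"))
            if code in _COUNT_TRAITS and value < 0:
                report.violations.append(
                    Violation(acc.id, code, "non-negative", f"{code} = {value} must be >= 0"))
    return report


def load_collection(path: str | Path, catalog: TraitCatalog | None = None,
                    strict: bool = True) -> GermplasmCollection:
    """Read a collection from CSV and validate it against *catalog*.

    Raises :class:`CollectionError` on unknown trait columns, qualitative
    values outside the declared level set, duplicated accession ids, or
    unparseable cells. With ``strict=False`` level/range violations are
    tolerated (use :func:`validate_collection` to enumerate them).
    """
    catalog = catalog or default_catalog()
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "id" not in df.columns:
        raise CollectionError(f"{path}: missing required 'id' column")
    unknown = [c for c in df.columns if c not in _META_COLUMNS and c not in catalog]
    if unknown:
        raise CollectionError(f"{path}: unknown trait column(s) {unknown}")

    accessions: list[Accession] = []
    for _, row in df.iterrows():
        acc_id = row["id"].strip()
        if not acc_id:
            raise CollectionError(f"{path}: empty accession id")
        region = row.get("region", "").strip() or None
        county = row.get("county", "").strip()
        acc = Accession(id=acc_id, region=region, county=county)
        for col in df.columns:
            if col in _META_COLUMNS:
                continue
            cell = row[col].strip()
            if cell == "":
                continue  # missing stays missing, never coerced to zero
            desc = catalog[col]
            if desc.is_qualitative:
                try:
                    level = int(cell)
                except ValueError:
                    raise CollectionError(
                        f"{path}: accession {acc_id}, trait {col}: "
                        f"non-integer level {cell!r}") from None
                if strict and level not in desc.levels:
                    raise CollectionError(
                        f"{path}: accession {acc_id}, trait {col}: level {level} "
                        f"not in declared levels {sorted(desc.levels)}")
                acc.qualitative[col] = level
            else:
                try:
                    acc.quantitative[col] = float(cell)
                except ValueError:
                    raise CollectionError(
                        f"{path}: accession {acc_id}, trait {col}: "
                        f"non-numeric value {cell!r}") from None
        accessions.append(acc)
    return GermplasmCollection(catalog, accessions)


def write_collection(collection: GermplasmCollection, path: str | Path) -> Path:
    """Write a collection as CSV; inverse of :func:`load_collection`.

    Floats are written with ``repr`` so that read-back reproduces the
    collection bit for bit; missing cells are written empty.
    """
    path = Path(path)
    codes = collection.catalog.codes
    lines = [",".join(list(_META_COLUMNS) + codes)]
    for acc in collection:
        cells = [acc.id, acc.region or "", acc.county or ""]
        for code in codes:
            v = acc.value(code)
            if v is None:
                cells.append("")
            elif isinstance(v, int):
                cells.append(str(v))
            else:
                cells.append(repr(float(v)))
        lines.append(",".join(cells))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
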