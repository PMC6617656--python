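"""Verbal-autopsy records, cause-of-death category schemes, and ICD-10 mapping.

A verbal autopsy (VA) record pairs a free-text narrative — a family member's
account of the events preceding a death — with physician-assigned labels:
an ICD-10 code and/or a broader cause-of-death (CoD) category.  Records are
stratified into three age groups (adult 15-69 years, child 29 days-14 years,
neonate <29 days) because neonatal deaths use a separate, smaller category
scheme.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

AGE_GROUPS = ("adult", "child", "neonate")

#: Days per year used when converting ages between units.
DAYS_PER_YEAR = 365.25

# 15-category scheme shared by adult (15-69 y) and child (29 d - 14 y) deaths.
ADULT_CHILD_CATEGORIES: tuple[str, ...] = (
    "Acute respiratory infections",
    "Diarrhea",
    "Pulmonary tuberculosis",
    "Other and unspecified infections",
    "Neoplasms",
    "Nutrition",
    "Cardiovascular disease",
    "Chronic respiratory disease",
    "Liver cirrhosis",
    "Other non-communicable diseases",
    "Road and transport injuries",
    "Other injuries",
    "Ill-defined",
    "Suicide",
    "Maternal",
)

# 5-category scheme for neonatal (<29 d) deaths.
NEONATE_CATEGORIES: tuple[str, ...] = (
    "Prematurity/low birth weight",
    "Neonatal infections",
    "Birth asphyxia/trauma",
    "Ill-defined or cause unknown",
    "Other",
)


class UnmappedICDError(KeyError):
    """Raised when an ICD-10 code has no match in the scheme's mapping table."""

    def __init__(self, code: str):
        super().__init__(code)
        self.code = code

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"ICD-10 code {self.code!r} has no category mapping"


class DuplicateRecordIDError(ValueError):
    """Raised when a corpus file contains repeated record ids."""


@dataclass
class VARecord:
    """One death: id, age stratum, narrative, optional ICD-10 code and CoD label."""

    record_id: str
    age_group: str
    narrative: str
    icd10: str | None = None
    category: str | None = None
    source_tag: str | None = None

    def __post_init__(self) -> None:
        if self.age_group not in AGE_GROUPS:
            raise ValueError(
                f"age_group must be one of {AGE_GROUPS}, got {self.age_group!r}"
            )


@dataclass
class AgeBounds:
    """Age-stratum boundaries, in the study's convention.

    Neonate: [0, 29) days; child: [29 days, 15 years); adult: [15, 69] years.
    Ages above ``max_adult_years`` are out of range (the study capped at 70).
    """

    neonate_max_days: float = 29.0
    child_max_years: float = 15.0
    max_adult_years: float = 69.0


class OutOfRangeAgeError(ValueError):
    """Age exceeds the configured maximum (default 69 years)."""


def assign_age_group(
    age_value: float, unit: str, bounds: AgeBounds | None = None
) -> str:
    """Assign an age stratum from an age value with unit ``"days"`` or ``"years"``.

    Raises :class:`OutOfRangeAgeError` above the adult cap and ``ValueError``
    for negative ages or unknown units.
    """
    bounds = bounds or AgeBounds()
    if age_value < 0:
        raise ValueError(f"age must be non-negative, got {age_value}")
    if unit == "days":
        days = float(age_value)
        years = days / DAYS_PER_YEAR
    elif unit == "years":
        years = float(age_value)
        days = years * DAYS_PER_YEAR
    else:
        raise ValueError(f"unit must be 'days' or 'years', got {unit!r}")
    if days < bounds.neonate_max_days:
        return "neonate"
    if years < bounds.child_max_years:
        return "child"
    if years <= bounds.max_adult_years:
        return "adult"
    raise OutOfRangeAgeError(
        f"age {age_value} {unit} exceeds the {bounds.max_adult_years}-year cap"
    )


def _normalize_icd(code: str) -> str:
    return code.strip().upper().replace(".", "")


@dataclass
class CoDScheme:
    """A named CoD category scheme: per-age-group category lists + ICD-10 lookup.

    ``icd_map`` keys are dot-stripped uppercase ICD-10 code *prefixes*; lookup
    is by longest matching prefix (standard ICD grouping practice), with an
    exact-only mode available.
    """

    name: str
    categories_by_age_group: dict[str, tuple[str, ...]]
    icd_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.categories_by_age_group = {
            g: tuple(cats) for g, cats in self.categories_by_age_group.items()
        }
        self.icd_map = {_normalize_icd(k): v for k, v in self.icd_map.items()}
        all_cats = {c for cats in self.categories_by_age_group.values() for c in cats}
        bad = sorted(set(self.icd_map.values()) - all_cats)
        if bad:
            raise ValueError(f"icd_map targets categories not in any list: {bad}")

    def categories(self, age_group: str) -> tuple[str, ...]:
        try:
            return self.categories_by_age_group[age_group]
        except KeyError:
            raise KeyError(f"scheme {self.name!r} has no categories for {age_group!r}")

    def map_icd(self, icd10: str, age_group: str, exact: bool = False) -> str:
        """Map an ICD-10 code to its CoD category for ``age_group``.

        Matching is by longest code prefix unless ``exact`` is set.  Raises
        :class:`UnmappedICDError` on a lookup miss, and ``ValueError`` if the
        mapped category is not in the age group's list.
        """
        code = _normalize_icd(icd10)
        category = None
        if exact:
            category = self.icd_map.get(code)
        else:
            for length in range(len(code), 0, -1):
                category = self.icd_map.get(code[:length])
                if category is not None:
                    break
        if category is None:
            raise UnmappedICDError(icd10)
        if category not in self.categories(age_group):
            raise ValueError(
                f"code {icd10!r} maps to {category!r}, which is not a "
                f"{age_group} category in scheme {self.name!r}"
            )
        return category

    def to_json(self, path: str | Path) -> None:
        payload = {
            "name": self.name,
            "categories_by_age_group": {
                g: list(c) for g, c in self.categories_by_age_group.items()
            },
            "icd_map": dict(self.icd_map),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "CoDScheme":
        payload = json.loads(Path(path).read_text())
        return cls(
            name=payload["name"],
            categories_by_age_group=payload["categories_by_age_group"],
            icd_map=payload.get("icd_map", {}),
        )


def default_scheme(icd_map: Mapping[str, str] | None = None) -> CoDScheme:
    """The study's default scheme: 15 adult + 15 child + 5 neonatal categories."""
    return CoDScheme(
        name="mds15",
        categories_by_age_group={
            "adult": ADULT_CHILD_CATEGORIES,
            "child": ADULT_CHILD_CATEGORIES,
            "neonate": NEONATE_CATEGORIES,
        },
        icd_map=dict(icd_map or {}),
    )


def load_icd_map(path: str | Path) -> dict[str, str]:
    """Read a two-column CSV mapping table: ``code_prefix,category``."""
    df = pd.read_csv(path, dtype=str)
    cols = [c.strip() for c in df.columns]
    if cols[:2] != ["code_prefix", "category"]:
        raise ValueError(
            f"mapping file must have columns code_prefix,category; got {cols}"
        )
    keys = [_normalize_icd(k) for k in df.iloc[:, 0]]
    dupes = sorted({k for k in keys if keys.count(k) > 1})
    if dupes:
        raise ValueError(f"duplicate code prefixes in mapping file: {dupes}")
    return dict(zip(keys, df.iloc[:, 1]))


_COLUMNS = ["record_id", "age_group", "narrative", "icd10", "category", "source_tag"]


def load_records(
    path: str | Path,
    dialect: str = "delimited",
    bounds: AgeBounds | None = None,
) -> list[VARecord]:
    """Load a VA corpus from a delimited (CSV) or JSON-lines file.

    Each row needs ``record_id``, ``narrative``, and either ``age_group`` or
    ``age_value`` + ``age_unit``.  Rows with an empty narrative, or with an
    age outside the study range, are skipped with a warning naming the line;
    duplicate ``record_id`` values are fatal.  Loaded/skipped counts are
    logged.
    """
    path = Path(path)
    if dialect == "delimited":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    elif dialect == "json-lines":
        df = pd.read_json(path, lines=True, dtype=str).fillna("")
        df = df.astype(str)
    else:
        raise ValueError(f"dialect must be 'delimited' or 'json-lines', got {dialect!r}")

    if "record_id" not in df.columns or "narrative" not in df.columns:
        raise ValueError("required columns missing: need record_id and narrative")
    has_group = "age_group" in df.columns
    has_age = "age_value" in df.columns and "age_unit" in df.columns
    if not (has_group or has_age):
        raise ValueError("need an age_group column or age_value+age_unit columns")

    ids = list(df["record_id"])
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise DuplicateRecordIDError(f"duplicate record_id values: {dupes}")

    records: list[VARecord] = []
    skipped = 0
    for line_no, row in enumerate(df.to_dict("records"), start=2):
        narrative = str(row.get("narrative", "")).strip()
        if not narrative:
            warnings.warn(f"{path.name} line {line_no}: empty narrative, row skipped")
            skipped += 1
            continue
        if has_group and str(row.get("age_group", "")).strip():
            group = str(row["age_group"]).strip()
        else:
            try:
                group = assign_age_group(
                    float(row["age_value"]), str(row["age_unit"]).strip(), bounds
                )
            except OutOfRangeAgeError as exc:
                warnings.warn(f"{path.name} line {line_no}: {exc}; row skipped")
                skipped += 1
                continue
        records.append(
            VARecord(
                record_id=str(row["record_id"]),
                age_group=group,
                narrative=narrative,
                icd10=str(row["icd10"]).strip() or None if "icd10" in row else None,
                category=str(row["category"]).strip() or None
                if "category" in row
                else None,
                source_tag=str(row["source_tag"]).strip() or None
                if "source_tag" in row
                else None,
            )
        )
    logger.info("loaded %d records from %s (%d skipped)", len(records), path, skipped)
    return records


def write_records(
    records: Iterable[VARecord], path: str | Path, dialect: str = "delimited"
) -> None:
    """Write a corpus to CSV or JSON-lines; inverse of :func:`load_records`."""
    rows = [asdict(r) for r in records]
    df = pd.DataFrame(rows, columns=_COLUMNS).fillna("")
    if dialect == "delimited":
        df.to_csv(path, index=False)
    elif dialect == "json-lines":
        df.to_json(path, orient="records", lines=True)
    else:
        raise ValueError(f"dialect must be 'delimited' or 'json-lines', got {dialect!r}")


def split_by_age_group(records: Sequence[VARecord]) -> dict[str, list[VARecord]]:
    """Partition a corpus into the three age strata (every record in exactly one)."""
    out: dict[str, list[VARecord]] = {g: [] for g in AGE_GROUPS}
    for r in records:
        out[r.age_group].append(r)
    return out
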