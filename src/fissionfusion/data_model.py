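"""Sightings data model, season calendars, and study-cohort selection.

The raw observational unit is a *sighting*: one identified individual seen in
one field group on one day.  Groups are opaque labels, unique within a day.
Seasons are user-supplied calendars mapping (year, month) pairs to ordered
season labels (e.g. a transitional period followed by alternating dry and wet
monsoon seasons).  Cohort selection reproduces the two-stage filter used in
longitudinal association studies: *residents* are seen in every season (more
than once, or at least once in association with others), and *core*
individuals are residents with a minimum total number of sightings.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SightingRecord",
    "SightingTable",
    "SeasonPartition",
    "CohortSpec",
    "read_sightings",
    "classify_months",
    "select_cohort",
]


@dataclass(frozen=True, order=True)
class SightingRecord:
    """One identified individual in one group encounter on one day."""

    day: _dt.date
    group_label: str
    individual_id: str

    def __post_init__(self) -> None:
        if not self.individual_id:
            raise ValueError("individual_id must be non-empty")


@dataclass
class SightingTable:
    """Ordered collection of sighting records with the derived id universe."""

    records: list[SightingRecord] = field(default_factory=list)

    @property
    def id_universe(self) -> frozenset[str]:
        return frozenset(r.individual_id for r in self.records)

    @property
    def days(self) -> list[_dt.date]:
        """Sorted unique sampling days (days with at least one record)."""
        return sorted({r.day for r in self.records})

    def __len__(self) -> int:
        return len(self.records)

    def sighting_counts(self) -> dict[str, int]:
        """Number of sighting rows per individual."""
        counts: dict[str, int] = {}
        for r in self.records:
            counts[r.individual_id] = counts.get(r.individual_id, 0) + 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "date": [r.day for r in self.records],
                "group_id": [r.group_label for r in self.records],
                "individual_id": [r.individual_id for r in self.records],
            }
        )

    @classmethod
    def from_records(
        cls, records: Iterable[SightingRecord], *, dedupe: bool = True
    ) -> "SightingTable":
        """Build a table, dropping duplicate (day, group, id) triples."""
        seen: set[SightingRecord] = set()
        out: list[SightingRecord] = []
        n_dup = 0
        for r in records:
            if dedupe and r in seen:
                n_dup += 1
                continue
            seen.add(r)
            out.append(r)
        if n_dup:
            logger.warning("dropped %d duplicate sighting rows", n_dup)
        return cls(out)


@dataclass
class SeasonPartition:
    """Ordered season calendar: label -> set of (year, month) pairs.

    Seasons are ordered chronologically by their earliest month; month sets
    must be disjoint and labels unique.
    """

    seasons: list[tuple[str, frozenset[tuple[int, int]]]]

    def __post_init__(self) -> None:
        labels = [lab for lab, _ in self.seasons]
        if len(set(labels)) != len(labels):
            raise ValueError("season labels must be unique")
        seen: set[tuple[int, int]] = set()
        for lab, months in self.seasons:
            if seen & set(months):
                raise ValueError(f"season {lab!r} overlaps an earlier season")
            seen |= set(months)
        self.seasons = sorted(self.seasons, key=lambda e: min(e[1]))

    @property
    def labels(self) -> list[str]:
        return [lab for lab, _ in self.seasons]

    def season_of(self, day: _dt.date) -> str | None:
        ym = (day.year, day.month)
        for lab, months in self.seasons:
            if ym in months:
                return lab
        return None

    def split(self, table: SightingTable) -> dict[str, SightingTable]:
        """Partition a table into per-season tables; out-of-calendar rows dropped."""
        buckets: dict[str, list[SightingRecord]] = {lab: [] for lab in self.labels}
        for r in table.records:
            lab = self.season_of(r.day)
            if lab is not None:
                buckets[lab].append(r)
        return {lab: SightingTable(rows) for lab, rows in buckets.items()}

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Iterable[Sequence[int]]]) -> "SeasonPartition":
        """Build from e.g. {"T1": [(2007, 1), (2007, 2)], ...}."""
        return cls(
            [
                (lab, frozenset((int(y), int(m)) for y, m in months))
                for lab, months in mapping.items()
            ]
        )


def uda_walawe_seasons() -> SeasonPartition:
    """The five-season study calendar: a four-month transitional period (T1),
    then alternating dry (May-Sept) and wet (Oct-Dec) monsoon seasons over
    two years (D1, W1, D2, W2)."""
    cal = {
        "T1": [(2007, m) for m in range(1, 5)],
        "D1": [(2007, m) for m in range(5, 10)],
        "W1": [(2007, m) for m in range(10, 13)],
        "D2": [(2008, m) for m in range(5, 10)],
        "W2": [(2008, m) for m in range(10, 13)],
    }
    return SeasonPartition.from_mapping(cal)


@dataclass(frozen=True)
class CohortSpec:
    """Thresholds for cohort selection.

    min_total_sightings: total sightings across the study required for the
        "core" cohort (the study used 30).
    top_n: companion slots per season used downstream (the study used 5).
    """

    min_total_sightings: int = 30
    top_n: int = 5

    def __post_init__(self) -> None:
        if self.min_total_sightings < 0:
            raise ValueError("min_total_sightings must be >= 0")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")


class ConfigurationError(ValueError):
    """A required column or configuration key could not be resolved."""


_DEFAULT_DIALECT = {"date": "date", "group_id": "group_id", "individual_id": "individual_id"}


def read_sightings(
    path,
    dialect: Mapping[str, str] | None = None,
    *,
    sep: str = ",",
    unidentified_sentinel: str = "",
) -> SightingTable:
    """Read a delimited sightings file into a :class:`SightingTable`.

    ``dialect`` maps the canonical column roles (date, group_id,
    individual_id) to the file's actual header names.  Rows whose individual
    id equals ``unidentified_sentinel`` (or is missing) are excluded:
    unidentified animals are counted in the field but excluded from analysis.
    Duplicate (day, group, id) triples are dropped with a logged warning.
    """
    colmap = dict(_DEFAULT_DIALECT)
    if dialect:
        colmap.update(dialect)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for role, col in colmap.items():
        if col not in df.columns:
            raise ConfigurationError(
                f"column {col!r} (role {role!r}) not found in {path}; "
                f"available: {list(df.columns)}"
            )
    records: list[SightingRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        raw = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        ind = raw[colmap["individual_id"]].strip()
        if ind == unidentified_sentinel:
            continue
        try:
            day = _dt.date.fromisoformat(raw[colmap["date"]].strip())
        except ValueError as exc:
            raise ValueError(f"{path} line {i}: unparseable date {raw[colmap['date']]!r}") from exc
        records.append(SightingRecord(day, raw[colmap["group_id"]].strip(), ind))
    return SightingTable.from_records(records)


def classify_months(
    monthly_rainfall: Mapping[tuple[int, int], float], threshold: float
) -> dict[tuple[int, int], str]:
    """Label each (year, month) wet or dry by total rainfall.

    A month is wet iff its rainfall strictly exceeds ``threshold`` (months
    exactly at the long-run monthly average are dry).  Units are carried
    opaquely: the threshold is in whatever units the gauge record uses.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    out: dict[tuple[int, int], str] = {}
    for ym, depth in monthly_rainfall.items():
        if depth < 0:
            raise ValueError(f"negative rainfall for {ym}")
        out[ym] = "wet" if depth > threshold else "dry"
    return out


def select_cohort(
    seasonal_tables: Sequence[SightingTable],
    daily_sets,  # Sequence[list[DailyAssociationSet]], one list per season
    spec: CohortSpec,
    season_labels: Sequence[str] | None = None,
) -> tuple[frozenset[str], frozenset[str]]:
    """Select the resident and core cohorts.

    Residents are individuals present in *every* season, and within every
    season either seen more than once or seen at least once in association
    with another individual (a merged daily part of size >= 2).  Core
    individuals are residents whose total sighting count across all seasons
    is at least ``spec.min_total_sightings``.
    """
    if season_labels is None:
        season_labels = [f"season_{i}" for i in range(len(seasonal_tables))]
    if len(daily_sets) != len(seasonal_tables):
        raise ValueError("need one daily-association list per season table")

    per_season_ok: list[set[str]] = []
    for lab, table, days in zip(season_labels, seasonal_tables, daily_sets):
        if len(table) == 0:
            raise ValueError(f"season {lab!r} has no sightings")
        counts = table.sighting_counts()
        associated: set[str] = set()
        for das in days:
            for part in das.parts:
                if len(part) >= 2:
                    associated |= set(part)
        ok = {i for i, c in counts.items() if c > 1} | (associated & set(counts))
        per_season_ok.append(ok)

    residents = frozenset(set.intersection(*per_season_ok)) if per_season_ok else frozenset()
    totals: dict[str, int] = {}
    for table in seasonal_tables:
        for i, c in table.sighting_counts().items():
            totals[i] = totals.get(i, 0) + c
    core = frozenset(i for i in residents if totals.get(i, 0) >= spec.min_total_sightings)
    return residents, core
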