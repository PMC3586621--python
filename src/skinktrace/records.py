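"""Biosecurity interception records: data model, bundled fixtures, summaries.

The package ships the published interception tables for the two skink
species as plain CSV fixtures (new arrivals from Australia, human-assisted
movements within New Zealand, and the congener's interceptions), together
with the established-range locality list and the locality-equivalence
table used when scoring the agency's origin predictions.  The analytics
here reproduce the per-interception proportions the study reports: season
of detection, transport class, border vs post-border stage, survival,
life stage, and origin/destination tallies.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .alignment import InputError
from .assignment import RegionEquivalence, normalize_locality, score_prediction

__all__ = [
    "InterceptionRecord",
    "load_records",
    "load_table1",
    "load_table2",
    "load_table3",
    "load_equivalences",
    "established_localities",
    "season_of",
    "summarize_records",
    "prediction_accuracy",
    "PredictionAccuracy",
    "origin_and_destination_counts",
    "OriginDestinationCounts",
    "data_path",
]

MONTHS = (
    "January", "February", "March", "April", "May", "June",
    "July", "August", "September", "October", "November", "December",
)
_MONTH_NUM = {name: i + 1 for i, name in enumerate(MONTHS)}

TRANSPORT_LEVELS = {
    "air": "air",
    "sea": "sea",
    "truck": "truck",
    "rail": "rail",
    "truck or rail": "truck-or-rail",
    "rail or sea": "rail-or-sea",
    "unknown": "unknown",
}

STAGES = {"border", "post-border", "n/a"}


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class InterceptionRecord:
    """One biosecurity detection with its record metadata."""

    sample_code: str
    species: str  # delicata | guichenoti
    record_class: str  # new-arrival | within-nz | local
    location: str
    month: int  # 1-12
    transport: str
    stage: str
    cargo: str
    svl_mm: float
    adult: bool
    alive: bool
    predicted_origin: str | None
    confirmed_origin: str | None
    haplotype: str
    group_size: int = 1

    def __post_init__(self) -> None:
        if not 1 <= self.month <= 12:
            raise InputError(f"{self.sample_code}: invalid month {self.month}")
        if self.svl_mm <= 0:
            raise InputError(f"{self.sample_code}: SVL must be positive")
        if self.group_size < 1:
            raise InputError(f"{self.sample_code}: group size must be >= 1")
        if self.transport not in TRANSPORT_LEVELS.values():
            raise InputError(f"{self.sample_code}: unknown transport {self.transport!r}")
        if self.stage not in STAGES:
            raise InputError(f"{self.sample_code}: unknown stage {self.stage!r}")


def data_path(name: str) -> Path:
    """Path of a bundled data file."""
    return Path(str(resources.files("skinktrace") / "data" / name))


def _parse_row(row, line_no: int, species: str, record_class: str) -> InterceptionRecord:
    month_name = str(row["month"]).strip()
    if month_name not in _MONTH_NUM:
        raise InputError(f"line {line_no}: invalid month {month_name!r}")
    transport_raw = str(row["transport"]).strip().lower()
    if transport_raw in TRANSPORT_LEVELS:
        transport = TRANSPORT_LEVELS[transport_raw]
    elif transport_raw in TRANSPORT_LEVELS.values():
        transport = transport_raw
    else:
        raise InputError(f"line {line_no}: invalid transport {row['transport']!r}")
    stage = str(row.get("stage", "n/a")).strip().lower()
    if stage not in STAGES:
        raise InputError(f"line {line_no}: invalid stage {row['stage']!r}")

    def flag(col: str, yes: str, no: str) -> bool:
        val = str(row[col]).strip().lower()
        if val == yes:
            return True
        if val == no:
            return False
        raise InputError(f"line {line_no}: invalid {col} value {row[col]!r}")

    def text_or_none(col: str) -> str | None:
        val = row.get(col)
        if val is None or (isinstance(val, float) and math.isnan(val)):
            return None
        return str(val).strip()

    return InterceptionRecord(
        sample_code=str(row["sample_code"]).strip(),
        species=species,
        record_class=record_class,
        location=str(row["location"]).strip(),
        month=_MONTH_NUM[month_name],
        transport=transport,
        stage=stage,
        cargo=str(row.get("cargo", "")).strip(),
        svl_mm=float(row["svl_mm"]),
        adult=flag("adult", "y", "n"),
        alive=flag("alive", "alive", "dead"),
        predicted_origin=text_or_none("predicted_origin"),
        confirmed_origin=text_or_none("confirmed_origin"),
        haplotype=str(row["haplotype"]).strip(),
        group_size=int(row.get("group_size", 1) or 1),
    )


def load_records(
    path: str | Path, species: str, record_class: str
) -> list[InterceptionRecord]:
    """Load interception records from a delimited file with a header row.

    Row-level validation errors carry the 1-based data line number.
    """
    df = pd.read_csv(path)
    required = {"sample_code", "location", "month", "transport", "svl_mm",
                "adult", "alive", "haplotype"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for i, row in enumerate(df.to_dict(orient="records"), start=1):
        records.append(_parse_row(row, i, species, record_class))
    return records


def load_table1() -> list[InterceptionRecord]:
    """Bundled fixture: delicate-skink new arrivals from Australia (13 records)."""
    return load_records(
        data_path("table1_delicata_new_arrivals.csv"), "delicata", "new-arrival"
    )


def load_table2() -> list[InterceptionRecord]:
    """Bundled fixture: delicate-skink movements within New Zealand (24 records)."""
    return load_records(
        data_path("table2_delicata_within_nz.csv"), "delicata", "within-nz"
    )


def load_table3() -> list[InterceptionRecord]:
    """Bundled fixture: garden-skink interceptions (4 records, one a group of 8)."""
    return load_records(
        data_path("table3_guichenoti.csv"), "guichenoti", "new-arrival"
    )


def load_equivalences() -> RegionEquivalence:
    """Bundled locality-equivalence table (documented geographic pairings)."""
    return RegionEquivalence.from_csv(data_path("region_equivalences.csv"))


def established_localities(as_of_year: int | None = None) -> frozenset[str]:
    """Localities of the established invaded range.

    Localities carrying an establishment year (an emerging population) are
    included only when ``as_of_year`` reaches that year; by default they
    are excluded, matching how the interception records were classified.
    """
    df = pd.read_csv(data_path("established_range.csv"))
    out = []
    for row in df.itertuples():
        year = row.established_from_year
        if pd.isna(year):
            out.append(row.locality)
        elif as_of_year is not None and as_of_year >= int(year):
            out.append(row.locality)
    return frozenset(out)


def season_of(month: int) -> str:
    """Austral season of a calendar month (Dec-Feb summer, Mar-May autumn,
    Jun-Aug winter, Sep-Nov spring)."""
    if not 1 <= month <= 12:
        raise InputError(f"invalid month {month}")
    if month in (12, 1, 2):
        return "summer"
    if month in (3, 4, 5):
        return "autumn"
    if month in (6, 7, 8):
        return "winter"
    return "spring"


_DIMENSIONS = ("season", "transport-class", "stage", "alive", "adult", "location", "origin")


def _level_of(rec: InterceptionRecord, dimension: str) -> str:
    if dimension == "season":
        return season_of(rec.month)
    if dimension == "transport-class":
        return rec.transport
    if dimension == "stage":
        return rec.stage
    if dimension == "alive":
        return "alive" if rec.alive else "dead"
    if dimension == "adult":
        return "Y" if rec.adult else "N"
    if dimension == "location":
        return rec.location
    if dimension == "origin":
        return rec.predicted_origin or "Unknown"
    raise InputError(f"unknown dimension {dimension!r}; choose from {_DIMENSIONS}")


def summarize_records(
    records: list[InterceptionRecord], dimension: str
) -> pd.DataFrame:
    """Counts, raw fractions and integer-rounded percents per level.

    Denominators count detection events (records), not individuals, so a
    group detection contributes once.  Percents are rounded half away from
    zero.
    """
    if not records:
        raise InputError("no records to summarize")
    counts = Counter(_level_of(rec, dimension) for rec in records)
    total = len(records)
    rows = [
        {
            "level": level,
            "count": count,
            "fraction": count / total,
            "percent": _round_half_away(100.0 * count / total),
        }
        for level, count in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["level", "count", "fraction", "percent"])


@dataclass(frozen=True)
class PredictionAccuracy:
    n: int
    tiers: tuple[str, ...]
    counts: dict[str, int]
    exact_count: int
    exact_percent: float  # one decimal
    exact_or_near_count: int
    exact_or_near_percent: int  # integer

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"tier": t, "count": c} for t, c in sorted(self.counts.items())]
        )


def prediction_accuracy(
    records: list[InterceptionRecord], eq: RegionEquivalence | None = None
) -> PredictionAccuracy:
    """Score recorded origin predictions against the confirmed origins.

    Every record is a denominator entry; records without a usable
    prediction count as ``no-prediction`` (and hence as misses).  Reports
    the exact-tier share to one decimal and the exact-or-near share as an
    integer percent.
    """
    eq = eq or RegionEquivalence()
    tiers = tuple(
        score_prediction(rec.confirmed_origin or "", rec.predicted_origin, eq)
        for rec in records
    )
    counts = dict(Counter(tiers))
    n = len(records)
    exact = counts.get("exact", 0)
    near = counts.get("near", 0)
    return PredictionAccuracy(
        n=n,
        tiers=tiers,
        counts=counts,
        exact_count=exact,
        exact_percent=round(100.0 * exact / n, 1) if n else 0.0,
        exact_or_near_count=exact + near,
        exact_or_near_percent=_round_half_away(100.0 * (exact + near) / n) if n else 0,
    )


@dataclass(frozen=True)
class OriginDestinationCounts:
    origins: dict[str, int]
    destinations: dict[str, int]
    in_range: int
    out_of_range: int
    unresolved: int


def origin_and_destination_counts(
    records: list[InterceptionRecord],
    established: frozenset[str] | set[str],
    known_localities: frozenset[str] | set[str] | None = None,
) -> OriginDestinationCounts:
    """Tally recorded freight origins and interception locations, and split
    locations into the established range vs beyond it.

    A location in neither the established list nor (when supplied) the
    known-locality list is counted under ``unresolved``, never dropped.
    """
    origins = Counter(rec.predicted_origin or "Unknown" for rec in records)
    destinations = Counter(rec.location for rec in records)
    est_norm = {normalize_locality(loc) for loc in established}
    known_norm = (
        None if known_localities is None
        else {normalize_locality(loc) for loc in known_localities}
    )
    in_range = out_of_range = unresolved = 0
    for rec in records:
        norm = normalize_locality(rec.location)
        if norm in est_norm:
            in_range += 1
        elif known_norm is None or norm in known_norm:
            out_of_range += 1
        else:
            unresolved += 1
    return OriginDestinationCounts(
        origins=dict(origins),
        destinations=dict(destinations),
        in_range=in_range,
        out_of_range=out_of_range,
        unresolved=unresolved,
    )
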