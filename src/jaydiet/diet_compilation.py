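"""Compilation and partitioning of the consolidated diet-observation dataset.

Observations come from three methods — direct observation (DO), stomach
contents (SC) and fecal metabarcoding (FS) — and are partitioned by age
class, food group (A arthropods, P "plants" including fungi and slime moulds,
V vertebrate tissue), and season. The seasonal windows are winter
(Nov 1 - Mar 31) and non-winter (May 1 - Oct 31); April belongs to neither
and is reported as its own category rather than silently assigned.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

METHODS = ("DO", "SC", "FS")
FOOD_GROUPS = ("A", "P", "V")
AGE_CLASSES = ("adult", "juvenile", "nestling")
PLANT_SUBCATEGORIES = ("vascular", "fungus", "slime_mould")
VERTEBRATE_SUBCATEGORIES = ("egg", "carrion", "live_prey")
SEASONS = ("winter", "non_winter", "neither")

#: Column schema of the S1/S2-style observation table. Optional columns may
#: be absent or empty.
REQUIRED_COLUMNS = ("obs_id", "date", "location", "method", "age_class",
                    "food_group", "taxon")
OPTIONAL_COLUMNS = ("rank", "to_species", "subcategory", "sac_id", "source",
                    "life_stage", "station", "designation")


@dataclass(frozen=True)
class DietObservation:
    """One dated, located, method-tagged food-item record."""

    obs_id: str
    date: Optional[dt.date]  # None if only a partial date is known
    location: str
    method: str
    age_class: str
    food_group: str
    taxon: str
    rank: str = "species"
    to_species: bool = True
    subcategory: Optional[str] = None
    sac_id: Optional[str] = None
    source: str = ""
    life_stage: Optional[str] = None
    station: Optional[str] = None
    month: Optional[int] = None  # known even for some partial dates
    day: Optional[int] = None


@dataclass
class RowError:
    obs_id: str
    field: str
    message: str


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (printed-percentage
    convention: 121/662 -> 18%)."""
    return int(x + 0.5) if x >= 0 else -int(-x + 0.5)


def pct(count: int, total: int) -> int:
    return round_half_away(100.0 * count / total) if total else 0


def season_of(date) -> str:
    """Season of a calendar date, year-agnostic.

    Accepts a ``datetime.date``, anything pandas can parse, or ``None`` /
    ``NaT`` (unknown month -> 'neither').
    """
    if date is None:
        return "neither"
    if isinstance(date, int):  # bare month
        month = date
    else:
        ts = pd.Timestamp(date)
        if pd.isna(ts):
            return "neither"
        month = ts.month
    if month in (11, 12, 1, 2, 3):
        return "winter"
    if 5 <= month <= 10:
        return "non_winter"
    return "neither"


def _parse_date(raw) -> tuple[Optional[dt.date], Optional[int], Optional[int], bool]:
    """Parse a possibly partial ISO date.

    Returns (date, month, day, ok). Partial dates ('1987', '1987-06') yield
    date=None with month filled where known; unparseable strings fail.
    """
    s = str(raw).strip()
    if not s or s.lower() in ("nan", "none", "nat"):
        return None, None, None, True
    parts = s.split("-")
    try:
        if len(parts) == 3:
            d = dt.date(int(parts[0]), int(parts[1]), int(parts[2]))
            return d, d.month, d.day, True
        if len(parts) == 2:
            month = int(parts[1])
            if not 1 <= month <= 12:
                return None, None, None, False
            return None, month, None, True
        if len(parts) == 1:
            int(parts[0])
            return None, None, None, True
    except ValueError:
        pass
    return None, None, None, False


def load_observations(path) -> tuple[pd.DataFrame, list[RowError]]:
    """Load and validate an S1/S2-style observation CSV.

    Invalid rows are collected into the error report, never silently
    dropped; the returned frame contains only valid rows, augmented with
    parsed ``date`` (NaT for partial dates), ``month``, ``day``,
    ``partial_date`` and ``season`` columns.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"observation file missing columns: {missing}")
    return validate_observations(raw)


def validate_observations(raw: pd.DataFrame) -> tuple[pd.DataFrame, list[RowError]]:
    errors: list[RowError] = []
    rows = []
    for _, row in raw.iterrows():
        obs_id = str(row.get("obs_id", "?"))
        ok = True
        if row["method"] not in METHODS:
            errors.append(RowError(obs_id, "method",
                                   f"unknown method code {row['method']!r}"))
            ok = False
        if row["food_group"] not in FOOD_GROUPS:
            errors.append(RowError(obs_id, "food_group",
                                   f"unknown food group {row['food_group']!r}"))
            ok = False
        if row["age_class"] not in AGE_CLASSES:
            errors.append(RowError(obs_id, "age_class",
                                   f"unknown age class {row['age_class']!r}"))
            ok = False
        date, month, day, date_ok = _parse_date(row["date"])
        if not date_ok:
            errors.append(RowError(obs_id, "date",
                                   f"unparseable date {row['date']!r}"))
            ok = False
        if ok:
            rec = dict(row)
            rec["date"] = pd.Timestamp(date) if date else pd.NaT
            rec["month"] = month
            rec["day"] = day
            rec["partial_date"] = date is None
            rec["season"] = season_of(month) if month else "neither"
            if "to_species" in rec:
                rec["to_species"] = str(rec["to_species"]).strip().lower() in (
                    "true", "1", "yes")
            rows.append(rec)
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.reset_index(drop=True)
    return df, errors


def tally(observations: pd.DataFrame, by: Sequence[str]
          ) -> pd.DataFrame:
    """Contingency counts and whole-number percentages over partition keys.

    ``by`` may name any observation column; ``season`` is derived from the
    date when absent. Partial-date rows are excluded (and counted in the
    frame's ``attrs['excluded_partial']``) whenever ``season`` is a key.
    Percentages use the printed-value convention (half away from zero) and
    marginal totals are conserved.
    """
    df = observations
    if df is None or len(df) == 0:
        out = pd.DataFrame(columns=[*by, "count", "pct"])
        out.attrs["total"] = 0
        return out
    df = df.copy()
    excluded = 0
    if "season" in by:
        if "season" not in df.columns:
            df["season"] = df["date"].map(season_of)
        if "partial_date" in df.columns:
            excluded = int(df["partial_date"].sum())
            df = df[~df["partial_date"]]
    for key in by:
        if key not in df.columns:
            raise KeyError(f"unknown partition key {key!r}")
    counts = (df.groupby(list(by), dropna=False, observed=True)
                .size().rename("count").reset_index())
    total = int(counts["count"].sum())
    counts["pct"] = counts["count"].map(lambda c: pct(int(c), total))
    counts = counts.sort_values(list(by)).reset_index(drop=True)
    counts.attrs["total"] = total
    counts.attrs["excluded_partial"] = excluded
    return counts
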