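"""Cached-vs-fresh designation of winter-adult and nestling food items.

Each food item identified to species is assigned one of four designations.
"Likely cached" requires at least one of four natural-history criteria to
hold on the observation date:

  C1  the species is migratory and entirely absent locally on that date;
  C2  the identified life stage is known not to be present on that date;
  C3  all individuals of the taxon are underground when and where observed;
  C4  snow depth on that date exceeded the item's height above the substrate,
      precluding access to a fresh item in situ.

Failing all four, a taxon present and accessible year-round is "either
possible"; an item inside a declared window of wide non-cached availability
is "likely fresh" (strengthened when it was unavailable in the preceding
summer/fall storage season); anything else remains "either possible". Items
not identified to species, or whose natural history is unknown, are
"unknown". Published expert determinations can be supplied as a per-item
override column that takes precedence over the rule evaluation.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from jaydiet.diet_compilation import (
    DietObservation,
    FOOD_GROUPS,
    pct,
    season_of,
)

DESIGNATIONS = ("unknown", "either_possible", "likely_fresh", "likely_cached")
CRITERIA = ("C1", "C2", "C3", "C4")
DEFAULT_MAX_GAP_DAYS = 3


# ---------------------------------------------------------------------------
# Month/day windows (may wrap the year end, e.g. 11-01:03-31)

@dataclass(frozen=True)
class MonthDayWindow:
    start: tuple[int, int]  # (month, day) inclusive
    end: tuple[int, int]    # (month, day) inclusive

    def __post_init__(self):
        for m, d in (self.start, self.end):
            dt.date(2000, m, d)  # leap year accepts Feb 29

    @property
    def wraps(self) -> bool:
        return self.end < self.start

    def contains(self, month: int, day: int) -> bool:
        md = (month, day)
        if self.wraps:
            return md >= self.start or md <= self.end
        return self.start <= md <= self.end

    def __str__(self) -> str:
        return "{:02d}-{:02d}:{:02d}-{:02d}".format(*self.start, *self.end)


def parse_windows(text: str) -> tuple[MonthDayWindow, ...]:
    """Parse ';'-separated 'MM-DD:MM-DD' window lists (empty -> none)."""
    text = (text or "").strip()
    if not text:
        return ()
    windows = []
    for part in text.split(";"):
        lo, hi = part.strip().split(":")
        m1, d1 = map(int, lo.split("-"))
        m2, d2 = map(int, hi.split("-"))
        windows.append(MonthDayWindow((m1, d1), (m2, d2)))
    return tuple(windows)


def _in_any(windows: Sequence[MonthDayWindow], month: int, day: int) -> bool:
    return any(w.contains(month, day) for w in windows)


# ---------------------------------------------------------------------------
# Natural-history profiles

@dataclass(frozen=True)
class NaturalHistoryProfile:
    """What is known about a food taxon's local phenology and accessibility."""

    taxon: str
    known: bool = True
    migratory_absence: tuple[MonthDayWindow, ...] = ()
    stage_phenology: Mapping[str, tuple[MonthDayWindow, ...]] = \
        field(default_factory=dict)
    underground_window: tuple[MonthDayWindow, ...] = ()
    substrate_height_cm: Optional[float] = None
    year_round: bool = False
    fresh_windows: tuple[MonthDayWindow, ...] = ()
    storable_season_available: bool = True

    def __post_init__(self):
        if self.known and self.year_round and self.migratory_absence:
            raise ValueError(
                f"profile {self.taxon!r}: year_round contradicts a declared "
                "migratory absence window")


def profiles_from_csv(path) -> dict[str, NaturalHistoryProfile]:
    """Read a trait table (one row per taxon; windows as 'MM-DD:MM-DD' lists,
    stage phenology as 'stage=MM-DD:MM-DD;...|stage2=...')."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return {row["taxon"]: _profile_from_row(row) for _, row in df.iterrows()}


def _profile_from_row(row) -> NaturalHistoryProfile:
    def _bool(v, default=False):
        s = str(v).strip().lower()
        if not s:
            return default
        return s in ("true", "1", "yes")

    stages = {}
    for chunk in str(row.get("stage_phenology", "")).split("|"):
        chunk = chunk.strip()
        if not chunk:
            continue
        stage, wins = chunk.split("=", 1)
        stages[stage.strip()] = parse_windows(wins)
    height = str(row.get("substrate_height_cm", "")).strip()
    return NaturalHistoryProfile(
        taxon=row["taxon"],
        known=_bool(row.get("known", "true"), default=True),
        migratory_absence=parse_windows(row.get("migratory_absence", "")),
        stage_phenology=stages,
        underground_window=parse_windows(row.get("underground_window", "")),
        substrate_height_cm=float(height) if height else None,
        year_round=_bool(row.get("year_round", "")),
        fresh_windows=parse_windows(row.get("fresh_windows", "")),
        storable_season_available=_bool(
            row.get("storable_season_available", "true"), default=True),
    )


def profiles_to_frame(profiles: Iterable[NaturalHistoryProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        rows.append({
            "taxon": p.taxon,
            "known": str(p.known).lower(),
            "migratory_absence": ";".join(map(str, p.migratory_absence)),
            "stage_phenology": "|".join(
                f"{s}={';'.join(map(str, ws))}"
                for s, ws in p.stage_phenology.items()),
            "underground_window": ";".join(map(str, p.underground_window)),
            "substrate_height_cm": ("" if p.substrate_height_cm is None
                                    else p.substrate_height_cm),
            "year_round": str(p.year_round).lower(),
            "fresh_windows": ";".join(map(str, p.fresh_windows)),
            "storable_season_available":
                str(p.storable_season_available).lower(),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Snow depth lookup (ECCC-style daily records)

def snow_depth_at(records: pd.DataFrame, station: str, date,
                  max_gap_days: int = DEFAULT_MAX_GAP_DAYS) -> Optional[float]:
    """Depth on the exact date if recorded, else the nearest record within
    ``max_gap_days`` (earlier wins ties), else None."""
    sub = records[records["station"] == station]
    if sub.empty:
        raise KeyError(f"unknown snow station {station!r}")
    target = pd.Timestamp(date)
    dates = pd.to_datetime(sub["date"])
    deltas = (dates - target).abs()
    i = deltas.idxmin()
    if deltas.loc[i] > pd.Timedelta(days=max_gap_days):
        return None
    exact = sub[dates == target]
    if not exact.empty:
        return float(exact.iloc[0]["depth_cm"])
    best = deltas.min()
    tied = sub[deltas == best].sort_values("date")
    return float(tied.iloc[0]["depth_cm"])


# ---------------------------------------------------------------------------
# Classification

@dataclass(frozen=True)
class CacheDesignation:
    value: str
    criteria_fired: tuple[str, ...] = ()
    rationale: str = ""

    def __post_init__(self):
        if self.value not in DESIGNATIONS:
            raise ValueError(f"unknown designation {self.value!r}")
        if (self.value == "likely_cached") != bool(self.criteria_fired):
            raise ValueError(
                "likely_cached iff at least one criterion fired")


def classify(obs: DietObservation, profile: Optional[NaturalHistoryProfile],
             snow: Optional[float] = None,
             life_stage: Optional[str] = None) -> CacheDesignation:
    """Designate one food item. All four criteria are evaluated; any firing
    makes the item likely cached regardless of year-round or fresh-window
    flags."""
    if profile is None or not profile.known or not obs.to_species:
        return CacheDesignation("unknown", (), "natural history unknown or "
                                               "not identified to species")
    month, day = obs.month, obs.day
    if month is None or day is None:
        if obs.date is not None:
            month, day = obs.date.month, obs.date.day
        else:
            return CacheDesignation("unknown", (),
                                    "observation date not resolvable")
    stage = life_stage if life_stage is not None else obs.life_stage

    fired = []
    if _in_any(profile.migratory_absence, month, day):
        fired.append("C1")
    if stage and stage in profile.stage_phenology and \
            not _in_any(profile.stage_phenology[stage], month, day):
        fired.append("C2")
    if _in_any(profile.underground_window, month, day):
        fired.append("C3")
    if snow is not None and profile.substrate_height_cm is not None and \
            snow > profile.substrate_height_cm:
        fired.append("C4")
    if fired:
        return CacheDesignation("likely_cached", tuple(fired),
                                "criteria fired: " + ",".join(fired))
    if profile.year_round:
        return CacheDesignation("either_possible", (),
                                "present and accessible year round")
    if _in_any(profile.fresh_windows, month, day):
        strength = ("fresh_strong" if not profile.storable_season_available
                    else "fresh")
        return CacheDesignation("likely_fresh", (),
                                f"within fresh-availability window ({strength})")
    return CacheDesignation("either_possible", (),
                            "no criterion fired; availability inconclusive")


def classify_dataset(observations: pd.DataFrame,
                     profiles: Optional[Mapping[str, NaturalHistoryProfile]]
                     = None,
                     snow: Optional[pd.DataFrame] = None,
                     override_col: str = "designation",
                     max_gap_days: int = DEFAULT_MAX_GAP_DAYS
                     ) -> tuple[pd.DataFrame, dict]:
    """Designate every observation and tally the winter-adult and nestling
    cohorts.

    A non-empty value in ``override_col`` (published expert determinations)
    takes precedence over rule evaluation and is logged in the output's
    ``designation_source`` column. Summary tallies cover the two cohorts of
    the study — adults in winter and nestlings — overall and per food group,
    with the identified-to-species denominator reported separately from the
    full denominator.
    """
    profiles = profiles or {}
    df = observations.copy()
    if df.empty:
        return df.assign(designation=pd.Series(dtype=str),
                         criteria_fired=pd.Series(dtype=str),
                         designation_source=pd.Series(dtype=str)), \
            {"winter_adult": _empty_cohort(), "nestling": _empty_cohort()}

    values, criteria, sources = [], [], []
    for _, row in df.iterrows():
        override = str(row.get(override_col, "") or "").strip()
        if override and override.lower() not in ("nan", "none"):
            if override not in DESIGNATIONS:
                raise ValueError(f"row {row.get('obs_id')}: unknown override "
                                 f"designation {override!r}")
            values.append(override)
            criteria.append("")
            sources.append("override")
            continue
        obs = _row_to_obs(row)
        depth = None
        if snow is not None and obs.station and obs.date is not None:
            try:
                depth = snow_depth_at(snow, obs.station, obs.date,
                                      max_gap_days)
            except KeyError:
                depth = None
        d = classify(obs, profiles.get(obs.taxon), snow=depth)
        values.append(d.value)
        criteria.append(",".join(d.criteria_fired))
        sources.append("rules")
    df["designation"] = values
    df["criteria_fired"] = criteria
    df["designation_source"] = sources

    if "season" not in df.columns:
        df["season"] = df["date"].map(season_of)
    winter_adult = df[(df["age_class"] == "adult") &
                      (df["season"] == "winter")]
    nestling = df[df["age_class"] == "nestling"]
    summary = {"winter_adult": _cohort_summary(winter_adult),
               "nestling": _cohort_summary(nestling)}
    return df, summary


def _row_to_obs(row) -> DietObservation:
    date = row.get("date")
    if pd.isna(date):
        date = None
    elif isinstance(date, pd.Timestamp):
        date = date.date()
    month = row.get("month")
    day = row.get("day")
    return DietObservation(
        obs_id=str(row.get("obs_id", "?")),
        date=date,
        location=str(row.get("location", "")),
        method=row["method"],
        age_class=row["age_class"],
        food_group=row["food_group"],
        taxon=str(row.get("taxon", "")),
        to_species=bool(row.get("to_species", True)),
        life_stage=(str(row["life_stage"]) or None)
        if "life_stage" in row and str(row.get("life_stage", "")).strip()
        else None,
        station=(str(row["station"]) or None)
        if "station" in row and str(row.get("station", "")).strip() else None,
        month=int(month) if pd.notna(month) else None,
        day=int(day) if pd.notna(day) else None,
    )


def _empty_cohort() -> dict:
    return {"n_total": 0, "n_to_species": 0, "n_designated": 0,
            "counts": {d: 0 for d in DESIGNATIONS},
            "pct_designated": {}, "by_group": {}}


def _cohort_summary(df: pd.DataFrame) -> dict:
    out = _empty_cohort()
    out["n_total"] = int(len(df))
    if df.empty:
        return out
    out["n_to_species"] = int(df.get(
        "to_species", pd.Series(True, index=df.index)).sum())
    counts = df["designation"].value_counts()
    out["counts"] = {d: int(counts.get(d, 0)) for d in DESIGNATIONS}
    designated = df[df["designation"] != "unknown"]
    n_desig = int(len(designated))
    out["n_designated"] = n_desig
    out["pct_designated"] = {
        d: pct(out["counts"][d], n_desig)
        for d in ("likely_cached", "either_possible", "likely_fresh")}
    for g in FOOD_GROUPS:
        sub = designated[designated["food_group"] == g]
        gc = sub["designation"].value_counts()
        gtot = int(len(sub))
        out["by_group"][g] = {
            "n_designated": gtot,
            "counts": {d: int(gc.get(d, 0)) for d in DESIGNATIONS
                       if d != "unknown"},
            "pct": {d: pct(int(gc.get(d, 0)), gtot)
                    for d in ("likely_cached", "either_possible",
                              "likely_fresh")},
        }
    return out


def sac_level_cached_presence(observations: pd.DataFrame
                              ) -> Optional[tuple[int, int, float]]:
    """Fraction of nestling fecal sacs containing at least one likely-cached
    item: (n_sacs_with_cached, n_sacs_with_designated_item, fraction).

    The denominator counts sacs with at least one designated (non-unknown)
    item; returns None when there are no FS observations with sac ids.
    """
    if "sac_id" not in observations.columns:
        return None
    fs = observations[(observations["method"] == "FS") &
                      (observations["sac_id"].astype(str).str.len() > 0) &
                      (observations["sac_id"].astype(str) != "nan")]
    if fs.empty:
        return None
    designated = fs[fs["designation"].isin(
        ("likely_cached", "either_possible", "likely_fresh"))]
    denom_sacs = set(designated["sac_id"])
    if not denom_sacs:
        return None
    cached_sacs = set(
        designated[designated["designation"] == "likely_cached"]["sac_id"])
    num, denom = len(cached_sacs), len(denom_sacs)
    return num, denom, num / denom
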