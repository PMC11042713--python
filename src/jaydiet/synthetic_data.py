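"""Synthetic data with known ground truth for every pipeline stage.

Four generators emulate the study's inputs: aligned reference libraries with
controlled within- and between-taxon divergence, error-bearing amplicon reads
with Phred qualities and primer flanks, dated diet observations with hidden
cached/fresh ground truth plus a matching trait table and snow series, and
daily snow-depth records.

Divergence model
----------------
Sequences evolve from a common base sequence by Jukes-Cantor-style uniform
random substitutions on a two-level star tree (base -> taxon ancestor ->
sequence). Per-branch substitution probabilities are chosen by exact JC
branch composition (the non-uniform eigenvalue ``u = 1 - 4/3 q`` multiplies
along a path) so that ``intra_divergence`` and ``inter_divergence`` are the
*expected pairwise p-distances* within and between taxa. When
``inter_divergence <= intra_divergence`` the ancestor branch clamps to zero
length, producing overlapping clusters with no barcode gap — the scenario in
which assignments must fall back to coarser ranks.

Ground-truth cached observations are constructed criterion-first: a cache
criterion is drawn, then the taxon's trait-table row and the observation date
are forced so that the criterion provably holds; fresh observations are
constructed so that no criterion can fire and the date lies inside the
taxon's fresh-availability window.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from jaydiet._seq import decode, encode, revcomp
from jaydiet.cache_classifier import (
    MonthDayWindow,
    NaturalHistoryProfile,
    profiles_to_frame,
)
from jaydiet.read_qc import Read
from jaydiet.taxonomy import ReferenceRecord, Taxon

DEFAULT_STATION = "SYNTH-APP"


def _require(condition: bool, field_name: str, message: str) -> None:
    if not condition:
        raise ValueError(f"{field_name}: {message}")


# ---------------------------------------------------------------------------
# Reference libraries

@dataclass(frozen=True)
class RefLibrarySpec:
    n_taxa: int
    seqs_per_taxon: int
    seq_length: int
    intra_divergence: float
    inter_divergence: float
    ambiguity_rate: float = 0.0
    terminal_gap_run: int = 0
    rank_labels: Optional[dict] = None  # species -> (genus, family)
    marker: str = "COI-5P"
    seed: int = 0

    def __post_init__(self):
        _require(self.n_taxa >= 1, "n_taxa", "must be >= 1")
        _require(self.seqs_per_taxon >= 1, "seqs_per_taxon", "must be >= 1")
        _require(self.seq_length >= 1, "seq_length", "must be >= 1")
        _require(0 <= self.intra_divergence <= 1, "intra_divergence",
                 "must be in [0, 1]")
        _require(0 <= self.inter_divergence <= 1, "inter_divergence",
                 "must be in [0, 1]")
        _require(0 <= self.ambiguity_rate <= 1, "ambiguity_rate",
                 "must be in [0, 1]")
        _require(self.terminal_gap_run >= 0, "terminal_gap_run",
                 "must be >= 0")
        _require(2 * self.terminal_gap_run <= self.seq_length,
                 "terminal_gap_run", "gap runs exceed sequence length")


def _jc_branch_probs(intra: float, inter: float) -> tuple[float, float]:
    """Per-branch substitution probabilities (q_seq, q_ancestor) so expected
    pairwise p-distances hit the intra/inter targets under JC composition."""
    u_s2 = max(0.0, 1.0 - 4.0 / 3.0 * intra)
    u_s = math.sqrt(u_s2)
    q_s = 0.75 * (1.0 - u_s)
    u_target = max(0.0, 1.0 - 4.0 / 3.0 * inter)
    u_a2 = min(1.0, u_target / u_s2) if u_s2 > 0 else 1.0
    q_a = 0.75 * (1.0 - math.sqrt(u_a2))
    return q_s, q_a


def _mutate(codes: np.ndarray, q: float, rng: np.random.Generator
            ) -> np.ndarray:
    """Substitute each site with probability q to a uniformly random other
    base (JC-style)."""
    out = codes.copy()
    mask = rng.random(codes.shape[0]) < q
    if mask.any():
        out[mask] = (out[mask] + rng.integers(1, 4, mask.sum())) % 4
    return out


def default_rank_labels(n_taxa: int) -> dict[str, tuple[str, str]]:
    """Auto ranks: species paired two-per-genus, genera two-per-family, so
    every species has congeners and every genus confamilials (n_taxa >= 2)."""
    labels = {}
    for i in range(n_taxa):
        labels[f"sp{i:03d}"] = (f"g{i // 2:03d}", f"f{i // 4:03d}")
    return labels


def gen_reference_library(spec: RefLibrarySpec) -> list[ReferenceRecord]:
    """Generate an aligned reference library with taxon labels.

    Reproducible given the seed; expected mean pairwise p-distance within a
    taxon equals ``intra_divergence`` and between taxa ``inter_divergence``
    (before ambiguity/gap injection, which removes sites from comparison but
    does not bias the remainder).
    """
    rng = np.random.default_rng(spec.seed)
    labels = spec.rank_labels or default_rank_labels(spec.n_taxa)
    species = sorted(labels)
    _require(len(species) >= spec.n_taxa, "rank_labels",
             "fewer labels than n_taxa")
    q_s, q_a = _jc_branch_probs(spec.intra_divergence, spec.inter_divergence)
    base = rng.integers(0, 4, spec.seq_length).astype(np.uint8)
    records = []
    for sp in species[:spec.n_taxa]:
        genus, family = labels[sp]
        ancestor = _mutate(base, q_a, rng)
        for k in range(spec.seqs_per_taxon):
            codes = _mutate(ancestor, q_s, rng)
            seq = list(decode(codes))
            if spec.ambiguity_rate > 0:
                amb = rng.random(spec.seq_length) < spec.ambiguity_rate
                for i in np.flatnonzero(amb):
                    seq[i] = "N"
            for i in range(spec.terminal_gap_run):
                seq[i] = "-"
                seq[spec.seq_length - 1 - i] = "-"
            records.append(ReferenceRecord(
                record_id=f"{sp}_r{k:02d}", marker=spec.marker,
                taxon=Taxon(species=sp, genus=genus, family=family),
                aligned_sequence="".join(seq)))
    return records


# ---------------------------------------------------------------------------
# Reads

@dataclass(frozen=True)
class ReadSimSpec:
    reads_per_template: int
    error_rate: float
    primer_forward: str
    primer_reverse: str
    quality_mean: float = 32.0
    quality_sd: float = 4.0
    min_abundance_spike: Optional[int] = None
    sample_id: str = "S01"
    seed: int = 0

    def __post_init__(self):
        _require(self.reads_per_template >= 0, "reads_per_template",
                 "must be >= 0")
        _require(0 <= self.error_rate <= 1, "error_rate", "must be in [0, 1]")
        _require(0 <= self.quality_mean <= 60, "quality_mean",
                 "must be in [0, 60]")
        _require(self.quality_sd >= 0, "quality_sd", "must be >= 0")
        _require(bool(self.primer_forward and self.primer_reverse),
                 "primer_pair", "primers must be non-empty")
        if self.min_abundance_spike is not None:
            _require(self.min_abundance_spike >= 1, "min_abundance_spike",
                     "must be >= 1")


def gen_reads(templates: Sequence[ReferenceRecord], spec: ReadSimSpec
              ) -> list[Read]:
    """Simulate amplicon reads: forward primer + substitution-mutated
    template + reverse-complemented reverse primer, with truncated-normal
    Phred qualities (clipped to [0, 60]).

    If ``min_abundance_spike`` is set, the first template instead receives
    exactly that many error-free reads, pinning its dereplicated count.
    """
    templates = list(templates)
    if not templates:
        raise ValueError("templates: template set is empty")
    rng = np.random.default_rng(spec.seed)
    fwd = spec.primer_forward.upper()
    rev_rc = revcomp(spec.primer_reverse).upper()
    reads = []
    for t_idx, tmpl in enumerate(templates):
        body_codes = encode(tmpl.degapped)
        mutable = body_codes < 4  # ambiguity codes are never substituted
        n = spec.reads_per_template
        error = spec.error_rate
        if spec.min_abundance_spike is not None and t_idx == 0:
            n, error = spec.min_abundance_spike, 0.0
        for i in range(n):
            codes = body_codes.copy()
            if error > 0:
                mask = (rng.random(codes.shape[0]) < error) & mutable
                if mask.any():
                    codes[mask] = (codes[mask] +
                                   rng.integers(1, 4, mask.sum())) % 4
            body = "".join(
                c if b >= 4 else d
                for c, b, d in zip(tmpl.degapped, body_codes, decode(
                    np.where(codes < 4, codes, 0))))
            seq = fwd + body + rev_rc
            qual = np.clip(np.rint(rng.normal(spec.quality_mean,
                                              spec.quality_sd, len(seq))),
                           0, 60).astype(int)
            reads.append(Read(
                read_id=f"read_{tmpl.record_id}_{i:05d}",
                sample_id=spec.sample_id, marker=tmpl.marker,
                sequence=seq, quality=tuple(int(q) for q in qual)))
    return reads


# ---------------------------------------------------------------------------
# Snow series

def gen_snow_series(start: dt.date, end: dt.date,
                    depth_profile: Sequence[tuple[str, float]] = (),
                    seed: int = 0, station: str = DEFAULT_STATION,
                    noise_sd: float = 0.0) -> pd.DataFrame:
    """One record per day between start and end (inclusive).

    ``depth_profile`` is a list of ('MM-DD:MM-DD', depth_cm) pieces (first
    matching piece wins; days outside every piece get 0 cm). Optional
    Gaussian jitter is clipped so depths stay >= 0.
    """
    if start > end:
        raise ValueError("start: must be <= end")
    from jaydiet.cache_classifier import parse_windows

    pieces = [(parse_windows(win)[0], float(depth))
              for win, depth in depth_profile]
    rng = np.random.default_rng(seed)
    rows = []
    day = start
    while day <= end:
        depth = 0.0
        for window, d in pieces:
            if window.contains(day.month, day.day):
                depth = d
                break
        if noise_sd > 0:
            depth = max(0.0, depth + rng.normal(0.0, noise_sd))
        rows.append({"station": station, "date": pd.Timestamp(day),
                     "depth_cm": depth})
        day += dt.timedelta(days=1)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Diet observations with ground truth

@dataclass(frozen=True)
class ObservationSimSpec:
    n_items: int
    group_probs: tuple[float, float, float] = (0.6, 0.3, 0.1)
    cached_fraction: float = 0.5
    date_window: tuple[dt.date, dt.date] = (dt.date(2016, 11, 1),
                                            dt.date(2017, 3, 31))
    seed: int = 0

    def __post_init__(self):
        _require(self.n_items >= 0, "n_items", "must be >= 0")
        _require(abs(sum(self.group_probs) - 1.0) <= 1e-9, "group_probs",
                 "must sum to 1 within 1e-9")
        _require(all(p >= 0 for p in self.group_probs), "group_probs",
                 "must be non-negative")
        _require(0 <= self.cached_fraction <= 1, "cached_fraction",
                 "must be in [0, 1]")
        _require(self.date_window[0] <= self.date_window[1], "date_window",
                 "start must be <= end")


@dataclass
class ObservationBundle:
    """gen_observations output: the observation table plus everything needed
    to re-evaluate its hidden ground truth."""

    observations: pd.DataFrame
    traits: pd.DataFrame
    profiles: dict[str, NaturalHistoryProfile]
    snow: pd.DataFrame
    ground_truth: pd.Series  # obs_id -> True if constructed as cached


def _md_window(date: dt.date, before: int, after: int) -> MonthDayWindow:
    lo = date - dt.timedelta(days=before)
    hi = date + dt.timedelta(days=after)
    return MonthDayWindow((lo.month, lo.day), (hi.month, hi.day))


def _md_window_excluding(date: dt.date) -> MonthDayWindow:
    """A 60-day presence window safely away from the given date."""
    lo = date + dt.timedelta(days=60)
    hi = date + dt.timedelta(days=120)
    return MonthDayWindow((lo.month, lo.day), (hi.month, hi.day))


def gen_observations(spec: ObservationSimSpec,
                     traits: Optional[pd.DataFrame] = None
                     ) -> ObservationBundle:
    """Generate dated diet observations with known cached/fresh ground truth.

    Cached items are built criterion-first: one of C1-C4 is drawn and the
    taxon's profile plus the observation date are forced so it provably
    holds. Fresh items are built so that no criterion can fire (presence
    windows cover the date, no underground or absence window, unknown
    substrate height) and the date lies inside the taxon's
    fresh-availability window. Each item gets its own synthetic taxon. An
    optional caller-supplied trait table is appended to the emitted one.

    Half the items are emitted as FS nestling records grouped into fecal
    sacs, half as SC adult records, emulating the two sampled cohorts.
    """
    rng = np.random.default_rng(spec.seed)
    start, end = spec.date_window
    n_days = (end - start).days + 1
    snow = gen_snow_series(start - dt.timedelta(days=5),
                           end + dt.timedelta(days=5),
                           depth_profile=[("11-01:03-31", 40.0)],
                           seed=spec.seed, station=DEFAULT_STATION)
    snow_by_date = {ts.date(): d for ts, d in
                    zip(snow["date"], snow["depth_cm"])}
    snowy_days = [start + dt.timedelta(days=i) for i in range(n_days)
                  if snow_by_date[start + dt.timedelta(days=i)] > 5.0]

    groups = np.array(["A", "P", "V"])
    rows, profiles, truth = [], {}, {}
    n_sacs = max(1, spec.n_items // 10)
    for i in range(spec.n_items):
        obs_id = f"SYN{i:05d}"
        group = str(rng.choice(groups, p=np.asarray(spec.group_probs)))
        cached = bool(rng.random() < spec.cached_fraction)
        date = start + dt.timedelta(days=int(rng.integers(0, n_days)))
        taxon = f"Syntaxon species{i:05d}"
        life_stage = "adult"
        if cached:
            criterion = str(rng.choice(["C1", "C2", "C3", "C4"]))
            if criterion == "C4" and not snowy_days:
                criterion = "C1"
            if criterion == "C1":
                profile = NaturalHistoryProfile(
                    taxon=taxon, migratory_absence=(_md_window(date, 21, 21),))
            elif criterion == "C2":
                profile = NaturalHistoryProfile(
                    taxon=taxon,
                    stage_phenology={"adult": (_md_window_excluding(date),)})
            elif criterion == "C3":
                profile = NaturalHistoryProfile(
                    taxon=taxon,
                    underground_window=(_md_window(date, 21, 21),))
            else:  # C4: date forced onto a snowy day, item near the ground
                date = snowy_days[int(rng.integers(0, len(snowy_days)))]
                profile = NaturalHistoryProfile(
                    taxon=taxon, substrate_height_cm=5.0,
                    stage_phenology={"adult": (_md_window(date, 45, 45),)})
        else:
            profile = NaturalHistoryProfile(
                taxon=taxon,
                stage_phenology={"adult": (_md_window(date, 45, 45),)},
                fresh_windows=(_md_window(date, 45, 45),),
                storable_season_available=False)
        profiles[taxon] = profile
        truth[obs_id] = cached
        nestling = i % 2 == 0
        rows.append({
            "obs_id": obs_id,
            "date": pd.Timestamp(date),
            "location": "APP",
            "method": "FS" if nestling else "SC",
            "age_class": "nestling" if nestling else "adult",
            "food_group": group,
            "taxon": taxon,
            "rank": "species",
            "to_species": True,
            "subcategory": "",
            "sac_id": f"SAC{(i // 2) % n_sacs:03d}" if nestling else "",
            "source": "synthetic",
            "life_stage": life_stage,
            "station": DEFAULT_STATION,
            "designation": "",
            "month": date.month,
            "day": date.day,
            "partial_date": False,
        })
    observations = pd.DataFrame(
        rows, columns=["obs_id", "date", "location", "method", "age_class",
                       "food_group", "taxon", "rank", "to_species",
                       "subcategory", "sac_id", "source", "life_stage",
                       "station", "designation", "month", "day",
                       "partial_date"])
    traits_df = profiles_to_frame(profiles.values())
    if traits is not None and len(traits):
        traits_df = pd.concat([traits_df, traits], ignore_index=True)
    return ObservationBundle(
        observations=observations, traits=traits_df, profiles=profiles,
        snow=snow,
        ground_truth=pd.Series(truth, dtype=bool, name="cached"))
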