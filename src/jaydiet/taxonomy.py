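"""Taxonomic assignment of unique sequences and barcode-gap calibration.

Assignment proceeds in two steps. First, each query is compared against a
packaged aligned reference library with a naive local-alignment search (the
in-package stand-in for a BLAST query against BOLD/GenBank); hits below 95%
identity or spanning fewer than 100 bp are discarded and the best surviving
hit proposes a candidate species. Second, the candidate's rank is calibrated
by a barcode-gap analysis of the reference library: a taxon has a barcode gap
when the minimum p-distance to members outside the group strictly exceeds the
maximum p-distance within it. Without a species-level gap, animal (COI-5P)
identifications are pulled back to genus; plant (rbcLa) identifications are
pulled back to genus and, failing a genus-level gap, to family.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from jaydiet._align import smith_waterman
from jaydiet._seq import AMBIGUOUS, encode
from jaydiet.read_qc import StageLog, UniqueSequence

DEFAULT_MIN_IDENTITY = 95.0
DEFAULT_MIN_HIT_LEN = 100
DEFAULT_MAX_AMBIGUITY = 0.02
DEFAULT_MAX_TERMINAL_GAPS = 12

RANKS = ("species", "genus", "family")


@dataclass(frozen=True, order=True)
class Taxon:
    species: str
    genus: str
    family: str


@dataclass(frozen=True)
class Hit:
    query_id: str
    taxon: Taxon
    percent_identity: float
    alignment_length: int
    bitscore: float = 0.0

    def __post_init__(self):
        if not 0 <= self.percent_identity <= 100:
            raise ValueError("percent_identity must be in [0, 100]")
        if self.alignment_length < 1:
            raise ValueError("alignment_length must be >= 1")


@dataclass(frozen=True)
class ReferenceRecord:
    record_id: str
    marker: str
    taxon: Taxon
    aligned_sequence: str

    @property
    def degapped(self) -> str:
        return self.aligned_sequence.replace("-", "")


@dataclass(frozen=True)
class Candidate:
    """Best-hit proposal prior to rank calibration."""

    query_id: str
    rank: str  # 'species' | 'genus' | 'family'
    taxon: Taxon


@dataclass(frozen=True)
class GapResult:
    focal_taxon: str
    rank_tested: str
    max_intra: float
    min_inter: float
    has_gap: Optional[bool]  # None = undetermined (no intra or inter pairs)
    n_intra_pairs: int
    n_inter_pairs: int


@dataclass(frozen=True)
class TaxonAssignment:
    query_id: str
    assigned_rank: str  # 'species' | 'genus' | 'family' | 'unassigned'
    assigned_taxon: str
    fallback_reason: str = ""


# ---------------------------------------------------------------------------
# Hit filtering and selection

def filter_hits(hits: Iterable[Hit], min_identity: float = DEFAULT_MIN_IDENTITY,
                min_length: int = DEFAULT_MIN_HIT_LEN
                ) -> tuple[list[Hit], StageLog]:
    """Retain hits with identity >= min_identity across >= min_length bp
    (a 95.0% / 100 bp hit is retained; 94.9% or 99 bp is not)."""
    log = StageLog("filter_hits")
    kept = []
    for h in hits:
        log.n_in += 1
        if h.percent_identity >= min_identity and \
                h.alignment_length >= min_length:
            kept.append(h)
        else:
            log.reasons["below_identity_or_length"] += 1
    log.n_out = len(kept)
    return kept, log


def naive_search(query: UniqueSequence | str, refs: list[ReferenceRecord],
                 query_id: str = "query") -> list[Hit]:
    """Local-alignment search of one query against every reference.

    Stand-in for an external similarity search: per reference it reports the
    best Smith-Waterman local alignment as percent identity (matching columns
    over alignment columns) and alignment length (columns). Deterministic;
    hits are returned sorted best-first.
    """
    if not refs:
        raise ValueError("reference set is empty")
    if isinstance(query, UniqueSequence):
        seq, qid = query.sequence, f"{query.sample_id}|{query.marker}"
        markers = {r.marker for r in refs}
        if markers != {query.marker}:
            raise ValueError(
                f"marker mismatch: query {query.marker}, refs {markers}")
        query_id = qid if query_id == "query" else query_id
    else:
        seq = query
    q = encode(seq)
    hits = []
    for ref in refs:
        score, matches, cols = smith_waterman(q, encode(ref.degapped))
        if cols == 0:
            continue
        hits.append(Hit(query_id=query_id, taxon=ref.taxon,
                        percent_identity=100.0 * matches / cols,
                        alignment_length=cols, bitscore=float(score)))
    hits.sort(key=_hit_order)
    return hits


def _hit_order(h: Hit):
    return (-h.percent_identity, -h.alignment_length, -h.bitscore, h.taxon)


def candidate_species(query_id: str, filtered_hits: Iterable[Hit]
                      ) -> Optional[Candidate]:
    """Pick the top hit by (identity, length, bitscore) lexicographic order.

    If several distinct species tie exactly on all three keys, the candidate
    is promoted to their lowest common rank (genus if congeners, family if
    confamilials, otherwise no candidate).
    """
    hits = sorted((h for h in filtered_hits if h.query_id == query_id),
                  key=_hit_order)
    if not hits:
        return None
    best = hits[0]
    key = (best.percent_identity, best.alignment_length, best.bitscore)
    tied = {h.taxon for h in hits
            if (h.percent_identity, h.alignment_length, h.bitscore) == key}
    species = {t.species for t in tied}
    if len(species) == 1:
        return Candidate(query_id=query_id, rank="species", taxon=best.taxon)
    genera = {t.genus for t in tied}
    if len(genera) == 1:
        return Candidate(query_id=query_id, rank="genus", taxon=best.taxon)
    families = {t.family for t in tied}
    if len(families) == 1:
        return Candidate(query_id=query_id, rank="family", taxon=best.taxon)
    return None


# ---------------------------------------------------------------------------
# Reference QC and distances

def reference_qc(refs: Iterable[ReferenceRecord],
                 max_ambiguity: float = DEFAULT_MAX_AMBIGUITY,
                 max_terminal_gaps: int = DEFAULT_MAX_TERMINAL_GAPS
                 ) -> tuple[list[ReferenceRecord], StageLog]:
    """Drop aligned references with more than 2% unknown nucleotides or more
    than 12 gap characters at either end of the alignment."""
    refs = list(refs)
    lengths = {len(r.aligned_sequence) for r in refs}
    if len(lengths) > 1:
        raise ValueError(f"references are not aligned: lengths {sorted(lengths)}")
    log = StageLog("reference_qc")
    kept = []
    for r in refs:
        log.n_in += 1
        seq = r.aligned_sequence.upper()
        bases = seq.replace("-", "")
        ambiguous = sum(1 for c in bases if c in AMBIGUOUS)
        frac = ambiguous / len(bases) if bases else 1.0
        lead = len(seq) - len(seq.lstrip("-"))
        trail = len(seq) - len(seq.rstrip("-"))
        if frac > max_ambiguity:
            log.reasons["ambiguous_bases"] += 1
        elif lead > max_terminal_gaps or trail > max_terminal_gaps:
            log.reasons["terminal_gaps"] += 1
        else:
            kept.append(r)
    log.n_out = len(kept)
    return kept, log


def p_distance(a: str, b: str) -> float:
    """Proportion of differing sites among sites where neither sequence has a
    gap or ambiguous base (pairwise deletion). NaN if no comparable sites."""
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    comparable = 0
    diff = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in "ACGT" and y in "ACGT":
            comparable += 1
            if x != y:
                diff += 1
    if comparable == 0:
        return math.nan
    return diff / comparable


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    values: np.ndarray  # square, symmetric, zero diagonal

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])


def distance_matrix(refs: list[ReferenceRecord]) -> DistanceMatrix:
    n = len(refs)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = p_distance(refs[i].aligned_sequence, refs[j].aligned_sequence)
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels=tuple(r.record_id for r in refs),
                          values=values)


# ---------------------------------------------------------------------------
# Barcode-gap analysis and rank fallback

def _group_label(taxon: Taxon, rank: str) -> str:
    return getattr(taxon, rank)


def gap_analysis(refs: list[ReferenceRecord], focal_taxon: str,
                 rank: str = "species", comparison: str = "auto"
                 ) -> GapResult:
    """Compare the maximum within-group p-distance against the minimum
    distance from group members to outside members.

    The comparison universe defaults to congeners for species-level tests and
    confamilials for genus-level tests; ``comparison='all'`` widens it to the
    whole library. ``has_gap`` is True only if min_inter strictly exceeds
    max_intra, and None (undetermined) when either pair set is empty.
    """
    if rank not in ("species", "genus"):
        raise ValueError("rank must be 'species' or 'genus'")
    focal = [r for r in refs if _group_label(r.taxon, rank) == focal_taxon]
    if not focal:
        raise ValueError(f"focal taxon {focal_taxon!r} absent from references")
    if comparison == "auto":
        parent = "genus" if rank == "species" else "family"
        parent_label = _group_label(focal[0].taxon, parent)
        outside = [r for r in refs
                   if _group_label(r.taxon, rank) != focal_taxon
                   and _group_label(r.taxon, parent) == parent_label]
    elif comparison == "all":
        outside = [r for r in refs
                   if _group_label(r.taxon, rank) != focal_taxon]
    else:
        raise ValueError("comparison must be 'auto' or 'all'")

    intra = [p_distance(a.aligned_sequence, b.aligned_sequence)
             for a, b in itertools.combinations(focal, 2)]
    inter = [p_distance(a.aligned_sequence, b.aligned_sequence)
             for a in focal for b in outside]
    intra = [d for d in intra if not math.isnan(d)]
    inter = [d for d in inter if not math.isnan(d)]
    max_intra = max(intra) if intra else math.nan
    min_inter = min(inter) if inter else math.nan
    has_gap = (min_inter > max_intra) if intra and inter else None
    return GapResult(focal_taxon=focal_taxon, rank_tested=rank,
                     max_intra=max_intra, min_inter=min_inter,
                     has_gap=has_gap, n_intra_pairs=len(intra),
                     n_inter_pairs=len(inter))


def gap_analysis_all(refs: list[ReferenceRecord], comparison: str = "auto"
                     ) -> dict[tuple[str, str], GapResult]:
    """Run gap analysis for every species and genus in the library."""
    results: dict[tuple[str, str], GapResult] = {}
    for rank in ("species", "genus"):
        for label in sorted({_group_label(r.taxon, rank) for r in refs}):
            results[(label, rank)] = gap_analysis(refs, label, rank,
                                                  comparison)
    return results


def apply_rank_fallback(candidate: Candidate,
                        gap_results: Mapping[tuple[str, str], GapResult],
                        marker: str) -> TaxonAssignment:
    """Calibrate a candidate's rank against the library's barcode gaps.

    COI-5P (and ITS2): species if a species-level gap exists, else genus.
    rbcLa: species, else genus if a genus-level gap exists, else family.
    An undetermined gap verdict is treated as 'no gap' (conservative
    pullback); a missing gap result yields an unassigned, flagged result.
    The returned rank is never more specific than the candidate's rank, and
    family-rank assignments are only permitted for rbcLa.
    """
    qid = candidate.query_id
    plant = marker == "rbcLa"

    def _gap(label: str, rank: str):
        return gap_results.get((label, rank))

    rank = candidate.rank
    if rank == "species":
        g = _gap(candidate.taxon.species, "species")
        if g is None:
            return TaxonAssignment(qid, "unassigned", candidate.taxon.species,
                                   "missing species-level gap result")
        if g.has_gap:
            return TaxonAssignment(qid, "species", candidate.taxon.species)
        reason = ("species-level gap undetermined" if g.has_gap is None
                  else "no species-level barcode gap")
        rank = "genus"
    else:
        reason = f"candidate resolved only to {rank}"

    if rank == "genus":
        if not plant:
            return TaxonAssignment(qid, "genus", candidate.taxon.genus, reason)
        g = _gap(candidate.taxon.genus, "genus")
        if g is None:
            return TaxonAssignment(qid, "unassigned", candidate.taxon.genus,
                                   reason + "; missing genus-level gap result")
        if g.has_gap:
            return TaxonAssignment(qid, "genus", candidate.taxon.genus, reason)
        reason += ("; genus-level gap undetermined" if g.has_gap is None
                   else "; no genus-level barcode gap")
        rank = "family"

    if not plant:  # family rank is only valid for the plant marker
        return TaxonAssignment(qid, "unassigned", candidate.taxon.family,
                               reason + "; family rank not valid for " + marker)
    return TaxonAssignment(qid, "family", candidate.taxon.family, reason)


def assign_queries(queries: list[UniqueSequence], refs: list[ReferenceRecord],
                   gap_results: Mapping[tuple[str, str], GapResult],
                   marker: str,
                   min_identity: float = DEFAULT_MIN_IDENTITY,
                   min_hit_len: int = DEFAULT_MIN_HIT_LEN
                   ) -> list[TaxonAssignment]:
    """Full chain: search, filter hits, select candidate, calibrate rank."""
    assignments = []
    for i, q in enumerate(queries):
        qid = f"{q.sample_id}|{q.marker}|u{i:05d}"
        hits = naive_search(q, refs, query_id=qid)
        kept, _ = filter_hits(hits, min_identity, min_hit_len)
        cand = candidate_species(qid, kept)
        if cand is None:
            assignments.append(TaxonAssignment(qid, "unassigned", "",
                                               "no hit passed filters"))
        else:
            assignments.append(apply_rank_fallback(cand, gap_results, marker))
    return assignments


# ---------------------------------------------------------------------------
# I/O: aligned reference FASTA and tabular (outfmt-6 dialect) hit files

def write_reference_fasta(refs: Iterable[ReferenceRecord], path) -> None:
    """Headers encode taxon labels as ``record_id|species|genus|family``."""
    records = []
    for r in refs:
        rid = "|".join([r.record_id, r.taxon.species, r.taxon.genus,
                        r.taxon.family])
        records.append(SeqRecord(Seq(r.aligned_sequence), id=rid,
                                 description=""))
    SeqIO.write(records, str(path), "fasta")


def read_reference_fasta(path, marker: str) -> list[ReferenceRecord]:
    refs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) != 4:
            raise ValueError(
                f"header {rec.id!r} is not 'record_id|species|genus|family'")
        rid, species, genus, family = parts
        refs.append(ReferenceRecord(
            record_id=rid, marker=marker,
            taxon=Taxon(species=species, genus=genus, family=family),
            aligned_sequence=str(rec.seq)))
    return refs


def write_hits_tsv(hits: Iterable[Hit], path) -> None:
    """12-column tab-separated hit table (outfmt-6 dialect); the subject id
    encodes the taxon, unused columns are written as 0."""
    with open(path, "w") as fh:
        for h in hits:
            sid = "|".join(["ref", h.taxon.species, h.taxon.genus,
                            h.taxon.family])
            fh.write("\t".join(map(str, [
                h.query_id, sid, f"{h.percent_identity:.3f}",
                h.alignment_length, 0, 0, 0, 0, 0, 0, 0,
                f"{h.bitscore:.1f}"])) + "\n")


def read_hits_tsv(path) -> list[Hit]:
    hits = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 12:
                raise ValueError("expected 12 tab-separated columns")
            parts = f[1].split("|")
            if len(parts) != 4:
                raise ValueError(
                    f"subject id {f[1]!r} does not encode a taxon")
            _, species, genus, family = parts
            hits.append(Hit(query_id=f[0],
                            taxon=Taxon(species, genus, family),
                            percent_identity=float(f[2]),
                            alignment_length=int(f[3]),
                            bitscore=float(f[11])))
    return hits
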