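"""Amplicon read processing: primer trimming, length and quality filters,
exact dereplication and the minimum-abundance filter.

The stage order mirrors the study workflow for unidirectional Ion Torrent
amplicons: primers/adapters off first, then drop reads shorter than 100 bp,
trim from the point where windowed mean quality falls below Q20, re-apply the
length filter, collapse reads with 100% identity into unique sequences per
(sample, marker), and finally drop unique sequences carried by fewer than 100
reads.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from jaydiet._seq import hamming_iupac, is_iupac, revcomp

MARKERS = ("COI-5P", "ITS2", "rbcLa")

DEFAULT_MIN_LEN = 100
DEFAULT_MIN_Q = 20
DEFAULT_MIN_READS = 100
DEFAULT_WINDOW_FRAC = 0.1
DEFAULT_MAX_MISMATCH = 2


@dataclass(frozen=True)
class Read:
    """One demultiplexed amplicon read (sample and marker already known)."""

    read_id: str
    sample_id: str
    marker: str
    sequence: str
    quality: tuple[int, ...]

    def __post_init__(self):
        if len(self.sequence) != len(self.quality):
            raise ValueError(
                f"read {self.read_id}: sequence and quality lengths differ")
        if self.marker not in MARKERS:
            raise ValueError(f"read {self.read_id}: unknown marker "
                             f"{self.marker!r} (expected one of {MARKERS})")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class UniqueSequence:
    """A dereplicated sequence with its read count in one (sample, marker)."""

    sequence: str
    read_count: int
    sample_id: str
    marker: str

    def __post_init__(self):
        if self.read_count < 1:
            raise ValueError("read_count must be >= 1")


@dataclass(frozen=True)
class PrimerPair:
    forward: str
    reverse: str

    def __post_init__(self):
        if not self.forward or not self.reverse:
            raise ValueError("primers must be non-empty")
        for name in ("forward", "reverse"):
            p = getattr(self, name)
            if not is_iupac(p):
                raise ValueError(f"{name} primer contains non-IUPAC characters")


@dataclass
class StageLog:
    """Per-stage accounting: n_in = n_out + sum(dropped reasons)."""

    stage: str
    n_in: int = 0
    n_out: int = 0
    reasons: Counter = field(default_factory=Counter)

    @property
    def n_dropped(self) -> int:
        return sum(self.reasons.values())


def trim_primers(read: Read, primers: PrimerPair,
                 max_mismatch: int = DEFAULT_MAX_MISMATCH
                 ) -> tuple[Optional[Read], Optional[str]]:
    """Excise the forward primer at the 5' end and the reverse-complemented
    reverse primer at the 3' end (anchored, IUPAC-aware, up to
    ``max_mismatch`` mismatches per flank).

    Returns ``(trimmed_read, None)`` on success or ``(None, reason)`` when a
    flank cannot be located.
    """
    fwd = primers.forward.upper()
    rev_rc = revcomp(primers.reverse).upper()
    seq = read.sequence
    if len(seq) < len(fwd) + len(rev_rc):
        return None, "too_short_for_primers"
    if hamming_iupac(fwd, seq[:len(fwd)]) > max_mismatch:
        return None, "forward_primer_not_found"
    if hamming_iupac(rev_rc, seq[len(seq) - len(rev_rc):]) > max_mismatch:
        return None, "reverse_primer_not_found"
    lo, hi = len(fwd), len(seq) - len(rev_rc)
    return replace(read, sequence=seq[lo:hi],
                   quality=read.quality[lo:hi]), None


def trim_reads(reads: Iterable[Read], primers: PrimerPair,
               max_mismatch: int = DEFAULT_MAX_MISMATCH
               ) -> tuple[list[Read], StageLog]:
    log = StageLog("trim_primers")
    kept: list[Read] = []
    for read in reads:
        log.n_in += 1
        trimmed, reason = trim_primers(read, primers, max_mismatch)
        if trimmed is None:
            log.reasons[reason] += 1
        else:
            kept.append(trimmed)
    log.n_out = len(kept)
    return kept, log


def filter_length(reads: Iterable[Read], min_len: int = DEFAULT_MIN_LEN
                  ) -> tuple[list[Read], StageLog]:
    """Keep reads of length >= min_len (a 100 bp read is retained)."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    log = StageLog("filter_length")
    kept = []
    for read in reads:
        log.n_in += 1
        if len(read) >= min_len:
            kept.append(read)
        else:
            log.reasons["short"] += 1
    log.n_out = len(kept)
    return kept, log


def quality_trim_point(quality: Sequence[int], q_threshold: int,
                       window_frac: float) -> int:
    """Index at which to cut a read: the start of the first sliding window
    whose mean Phred drops below the threshold (whole read kept if none)."""
    n = len(quality)
    if n == 0:
        return 0
    w = max(1, round(window_frac * n))
    for i in range(n - w + 1):
        if sum(quality[i:i + w]) / w < q_threshold:
            return i
    return n


def filter_quality(reads: Iterable[Read], q_threshold: int = DEFAULT_MIN_Q,
                   window_frac: float = DEFAULT_WINDOW_FRAC
                   ) -> tuple[list[Read], StageLog]:
    """Windowed mean-quality 3' trimming (sickle-style single-end pass).

    Reads trimmed to zero length are dropped here; reads merely shortened are
    kept and are expected to face the length filter again downstream.
    """
    if not 0 < window_frac <= 1:
        raise ValueError("window_frac must be in (0, 1]")
    log = StageLog("filter_quality")
    kept = []
    for read in reads:
        log.n_in += 1
        cut = quality_trim_point(read.quality, q_threshold, window_frac)
        if cut == 0:
            log.reasons["low_quality"] += 1
        elif cut == len(read):
            kept.append(read)
        else:
            kept.append(replace(read, sequence=read.sequence[:cut],
                                quality=read.quality[:cut]))
    log.n_out = len(kept)
    return kept, log


def dereplicate(reads: Iterable[Read]) -> list[UniqueSequence]:
    """Collapse reads with 100% sequence identity per (sample, marker).

    Output order is canonical — by sample, marker, descending count, then
    sequence — and therefore independent of input order.
    """
    counts: Counter = Counter()
    for read in reads:
        counts[(read.sample_id, read.marker, read.sequence)] += 1
    uniques = [UniqueSequence(sequence=seq, read_count=c, sample_id=s, marker=m)
               for (s, m, seq), c in counts.items()]
    uniques.sort(key=lambda u: (u.sample_id, u.marker, -u.read_count,
                                u.sequence))
    return uniques


def filter_min_reads(uniques: Iterable[UniqueSequence],
                     min_reads: int = DEFAULT_MIN_READS
                     ) -> tuple[list[UniqueSequence], StageLog]:
    """Keep unique sequences with read_count >= min_reads (100 is retained;
    'fewer than 100 reads' excludes only counts below 100)."""
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    log = StageLog("filter_min_reads")
    kept = []
    for u in uniques:
        log.n_in += 1
        if u.read_count >= min_reads:
            kept.append(u)
        else:
            log.reasons["low_abundance"] += 1
    log.n_out = len(kept)
    return kept, log


# ---------------------------------------------------------------------------
# FASTQ I/O (Sanger Phred+33)

def write_fastq(reads: Iterable[Read], path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = list(r.quality)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_fastq(path, sample_id: str, marker: str) -> list[Read]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        reads.append(Read(
            read_id=rec.id, sample_id=sample_id, marker=marker,
            sequence=str(rec.seq),
            quality=tuple(rec.letter_annotations["phred_quality"])))
    return reads
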