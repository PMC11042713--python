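"""Independent brute-force oracles used to verify the implementation.

These are deliberately written as naive, direct enumerations, separate from
the package's code paths. Where a convention is needed (alignment
tie-breaking), it mirrors the documented package convention so exact
comparison is meaningful.
"""

from __future__ import annotations

import numpy as np

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def sw_align(a: str, b: str, match: int = 1, mismatch: int = -1,
             gap: int = -2) -> tuple[int, int, int]:
    """Plain-Python Smith-Waterman with full matrix and traceback.

    Returns (score, matching columns, alignment columns). Conventions match
    the package's documented ones: best cell = first maximum in row-major
    order; traceback prefers diagonal, then up, then left. Non-ACGT
    characters never match.
    """
    n, m = len(a), len(b)
    A, B = a.upper(), b.upper()
    H = [[0] * (m + 1) for _ in range(n + 1)]
    best = (0, 0, 0)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            good = A[i - 1] == B[j - 1] and A[i - 1] in "ACGT"
            s = match if good else mismatch
            v = max(0, H[i - 1][j - 1] + s, H[i - 1][j] + gap,
                    H[i][j - 1] + gap)
            H[i][j] = v
            if v > best[0]:
                best = (v, i, j)
    score, i, j = best
    matches = cols = 0
    while i > 0 and j > 0 and H[i][j] > 0:
        good = A[i - 1] == B[j - 1] and A[i - 1] in "ACGT"
        s = match if good else mismatch
        if H[i][j] == H[i - 1][j - 1] + s:
            matches += good
            cols += 1
            i, j = i - 1, j - 1
        elif H[i][j] == H[i - 1][j] + gap:
            cols += 1
            i -= 1
        else:
            cols += 1
            j -= 1
    return score, matches, cols


def find_primer(primer: str, seq: str) -> tuple[int, int]:
    """Exhaustive sliding-window IUPAC Hamming search.

    Returns (best offset, mismatches at that offset); earliest best wins.
    """
    best_off, best_mm = -1, len(primer) + 1
    for off in range(len(seq) - len(primer) + 1):
        mm = 0
        for p, c in zip(primer, seq[off:off + len(primer)]):
            if c.upper() not in IUPAC[p.upper()]:
                mm += 1
        if mm < best_mm:
            best_off, best_mm = off, mm
    return best_off, best_mm


def quality_cut(quality, q_threshold: int, window_frac: float) -> int:
    """Independent windowed-mean trim point via cumulative sums."""
    q = np.asarray(quality, dtype=float)
    n = q.size
    if n == 0:
        return 0
    w = max(1, round(window_frac * n))
    cs = np.concatenate([[0.0], np.cumsum(q)])
    means = (cs[w:] - cs[:-w]) / w  # mean of q[i:i+w] at index i
    bad = np.flatnonzero(means < q_threshold)
    return int(bad[0]) if bad.size else n


def pdist_naive(a: str, b: str) -> float:
    """Site-by-site p-distance with pairwise deletion (independent of the
    package implementation)."""
    comp = diff = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in "ACGT" and y in "ACGT":
            comp += 1
            diff += x != y
    return diff / comp if comp else float("nan")


def gap_stats(records, focal: str, rank: str) -> tuple[float, float, object]:
    """Exhaustive all-pairs barcode-gap statistics.

    ``records`` are (species, genus, family, aligned_sequence) tuples; the
    comparison universe is congeners for rank='species' and confamilials for
    rank='genus'. Returns (max_intra, min_inter, verdict) with verdict None
    when either pair set is empty.
    """
    idx = {"species": 0, "genus": 1}[rank]
    parent_idx = idx + 1
    group = [r for r in records if r[idx] == focal]
    parent = group[0][parent_idx]
    outside = [r for r in records
               if r[idx] != focal and r[parent_idx] == parent]
    intra = [pdist_naive(a[3], b[3])
             for i, a in enumerate(group) for b in group[i + 1:]]
    inter = [pdist_naive(a[3], b[3]) for a in group for b in outside]
    intra = [d for d in intra if d == d]
    inter = [d for d in inter if d == d]
    if not intra or not inter:
        return (max(intra) if intra else float("nan"),
                min(inter) if inter else float("nan"), None)
    return max(intra), min(inter), min(inter) > max(intra)


def random_library(rng: np.random.Generator, max_seqs: int = 50):
    """A random small labelled library as (species, genus, family, seq)
    tuples, with clustered divergence so gap verdicts vary."""
    n_taxa = int(rng.integers(2, 7))
    length = int(rng.integers(60, 121))
    seqs_per = int(rng.integers(1, max(2, max_seqs // n_taxa) + 1))
    bases = "ACGT"
    base = rng.integers(0, 4, length)
    records = []
    for t in range(n_taxa):
        anc_rate = rng.uniform(0.0, 0.15)
        anc = np.where(rng.random(length) < anc_rate,
                       (base + rng.integers(1, 4, length)) % 4, base)
        for s in range(min(seqs_per, max(1, max_seqs // n_taxa))):
            rate = rng.uniform(0.0, 0.12)
            seq = np.where(rng.random(length) < rate,
                           (anc + rng.integers(1, 4, length)) % 4, anc)
            records.append((f"sp{t}", f"g{t // 2}", f"f{t // 4}",
                            "".join(bases[c] for c in seq)))
    return records
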