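"""Smith-Waterman local alignment kernel.

Scoring is the simple unit scheme (match +1, mismatch -1, linear gap -2)
adequate for short amplicons against close references. The kernel returns the
best local score together with the match count and column count of the best
local alignment, from which percent identity is derived. Tie-breaking is
fixed: the best cell is the first maximum in row-major order and traceback
prefers diagonal over up over left, so results are deterministic.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MATCH = 1
MISMATCH = -1
GAP = -2


@njit(cache=False)
def _sw_kernel(a, b, match, mismatch, gap):  # pragma: no cover - jitted
    n, m = a.shape[0], b.shape[0]
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            # code 4 marks ambiguity/gap characters: never a match
            s = match if (a[i - 1] == b[j - 1] and a[i - 1] < 4) else mismatch
            h = H[i - 1, j - 1] + s
            up = H[i - 1, j] + gap
            left = H[i, j - 1] + gap
            v = h
            if up > v:
                v = up
            if left > v:
                v = left
            if v < 0:
                v = 0
            H[i, j] = v
            if v > best:
                best, bi, bj = v, i, j
    # traceback: diagonal > up > left
    matches = 0
    cols = 0
    i, j = bi, bj
    while i > 0 and j > 0 and H[i, j] > 0:
        s = match if (a[i - 1] == b[j - 1] and a[i - 1] < 4) else mismatch
        if H[i, j] == H[i - 1, j - 1] + s:
            if s == match:
                matches += 1
            cols += 1
            i -= 1
            j -= 1
        elif H[i, j] == H[i - 1, j] + gap:
            cols += 1
            i -= 1
        else:
            cols += 1
            j -= 1
    return best, matches, cols


def smith_waterman(a: np.ndarray, b: np.ndarray,
                   match: int = MATCH, mismatch: int = MISMATCH,
                   gap: int = GAP) -> tuple[int, int, int]:
    """Best local alignment of encoded sequences.

    Returns ``(score, n_matching_columns, n_alignment_columns)``.
    """
    if a.size == 0 or b.size == 0:
        return 0, 0, 0
    score, matches, cols = _sw_kernel(
        a.astype(np.uint8), b.astype(np.uint8),
        np.int32(match), np.int32(mismatch), np.int32(gap))
    return int(score), int(matches), int(cols)
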