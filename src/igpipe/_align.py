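"""Pairwise alignment kernels used across the pipeline.

Three flavours, each with fixed, documented scoring so results are exactly
reproducible and testable against brute-force oracles:

* unit-cost edit distance (duplicate detection, center selection),
* Needleman-Wunsch global alignment, match +1 / mismatch -1 / gap -2
  (center-star multiple alignment),
* Smith-Waterman local alignment with affine gaps, match +2 / mismatch -3 /
  gap open -5 / gap extend -2 (germline segment search).

Matrices are filled row-by-row with NumPy. The within-row (horizontal) gap
recurrence is resolved exactly with a running-extremum scan: because a gap
opening costs at least as much as an extension, a horizontal gap never
profits from re-opening out of a cell that itself ends in a horizontal gap,
so an ``accumulate`` over ``row - extend*j`` yields the exact gap term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

NEG_INF = -(10**9)


def _encode(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("ascii"), dtype=np.uint8)


def _strip_common(a: str, b: str) -> tuple[str, str]:
    """Drop shared prefix and suffix (cannot change the edit distance)."""
    i = 0
    while i < len(a) and i < len(b) and a[i] == b[i]:
        i += 1
    j = 0
    while j < len(a) - i and j < len(b) - i and a[-1 - j] == b[-1 - j]:
        j += 1
    return a[i : len(a) - j], b[i : len(b) - j]


def edit_distance(a: str, b: str) -> int:
    """Unit-cost Levenshtein distance."""
    a, b = _strip_common(a, b)
    if not a:
        return len(b)
    if not b:
        return len(a)
    bv = _encode(b)
    jcol = np.arange(len(b) + 1)
    prev = jcol.copy()
    for i, ca in enumerate(a.encode("ascii"), start=1):
        cur = np.empty_like(prev)
        cur[0] = i
        np.minimum(prev[:-1] + (bv != ca), prev[1:] + 1, out=cur[1:])
        # insertions (within-row): cur[j] = min_{k<=j} cur[k] + (j - k)
        cur = np.minimum.accumulate(cur - jcol) + jcol
        prev = cur
    return int(prev[-1])


def _edit_row_final(a: str, b: str) -> np.ndarray:
    """Final DP row: ``row[j] == edit_distance(a, b[:j])`` for every j."""
    bv = _encode(b)
    jcol = np.arange(len(b) + 1)
    prev = jcol.copy()
    for i, ca in enumerate(a.encode("ascii"), start=1):
        cur = np.empty_like(prev)
        cur[0] = i
        np.minimum(prev[:-1] + (bv != ca), prev[1:] + 1, out=cur[1:])
        cur = np.minimum.accumulate(cur - jcol) + jcol
        prev = cur
    return prev


@dataclass
class GlobalAlignment:
    score: int
    aligned_a: str
    aligned_b: str


def global_align(a: str, b: str, match: int = 1, mismatch: int = -1,
                 gap: int = -2) -> GlobalAlignment:
    """Needleman-Wunsch with linear gap cost; deterministic traceback
    preferring diagonal, then gap-in-b, then gap-in-a."""
    m, n = len(a), len(b)
    if a == b:
        return GlobalAlignment(match * m, a, b)
    av, bv = _encode(a), _encode(b)
    H = np.empty((m + 1, n + 1), dtype=np.int64)
    jcol = np.arange(n + 1)
    H[0] = gap * jcol
    for i in range(1, m + 1):
        subst = np.where(bv == av[i - 1], match, mismatch)
        row = np.empty(n + 1, dtype=np.int64)
        row[0] = gap * i
        np.maximum(H[i - 1, :-1] + subst, H[i - 1, 1:] + gap, out=row[1:])
        # horizontal gaps: row[j] = max_{k<=j} row[k] + gap*(j-k), exact scan
        row = np.maximum.accumulate(row - gap * jcol) + gap * jcol
        H[i] = row
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = m, n
    while i > 0 or j > 0:
        if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + (
            match if a[i - 1] == b[j - 1] else mismatch
        ):
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif i > 0 and H[i, j] == H[i - 1, j] + gap:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
    return GlobalAlignment(int(H[m, n]), "".join(reversed(out_a)),
                           "".join(reversed(out_b)))


@dataclass
class LocalAlignment:
    """Best local alignment of ``b`` (segment) within ``a`` (read).

    Intervals are 0-based half-open on the ungapped inputs.
    """

    score: int
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    n_matches: int
    n_mismatches: int
    n_indels: int
    aligned_a: str
    aligned_b: str


def local_align(a: str, b: str, match: int = 2, mismatch: int = -3,
                gap_open: int = -5, gap_extend: int = -2) -> LocalAlignment:
    """Smith-Waterman with affine gaps (first gapped base costs ``gap_open``,
    each further base ``gap_extend``; ``gap_open <= gap_extend <= 0``).

    Ties are broken deterministically: the maximum-scoring cell is the
    row-major first (earliest end in ``a``, then in ``b``); traceback prefers
    substitution over gap-in-``b`` over gap-in-``a``, and extends gap blocks
    maximally leftward.
    """
    m, n = len(a), len(b)
    if m == 0 or n == 0:
        return LocalAlignment(0, 0, 0, 0, 0, 0, 0, 0, "", "")
    av, bv = _encode(a), _encode(b)
    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    E = np.full((m + 1, n + 1), NEG_INF, dtype=np.int64)  # gap in b (vertical)
    F = np.full((m + 1, n + 1), NEG_INF, dtype=np.int64)  # gap in a (horizontal)
    jcol = np.arange(n + 1)
    ext = gap_extend
    for i in range(1, m + 1):
        E[i] = np.maximum(E[i - 1] + ext, H[i - 1] + gap_open)
        subst = np.where(bv == av[i - 1], match, mismatch)
        base = np.zeros(n + 1, dtype=np.int64)
        base[1:] = np.maximum(H[i - 1, :-1] + subst, E[i, 1:])
        np.maximum(base, 0, out=base)
        # F[i][j] = max_{k<j} base[k] + gap_open + (j-k-1)*ext
        g = base - ext * jcol
        acc = np.maximum.accumulate(g)
        f = np.full(n + 1, NEG_INF, dtype=np.int64)
        f[1:] = gap_open + ext * (jcol[1:] - 1) + acc[:-1]
        F[i] = f
        H[i] = np.maximum(base, f)
    flat = int(np.argmax(H))
    end_i, end_j = divmod(flat, n + 1)
    score = int(H[end_i, end_j])
    if score <= 0:
        return LocalAlignment(0, 0, 0, 0, 0, 0, 0, 0, "", "")

    out_a: list[str] = []
    out_b: list[str] = []
    i, j = end_i, end_j
    n_match = n_mm = n_indel = 0
    state = "H"
    while i > 0 or j > 0:
        if state == "H":
            if H[i, j] == 0:
                break
            diag = NEG_INF
            if i > 0 and j > 0:
                diag = H[i - 1, j - 1] + (
                    match if a[i - 1] == b[j - 1] else mismatch
                )
            if i > 0 and j > 0 and H[i, j] == diag:
                out_a.append(a[i - 1])
                out_b.append(b[j - 1])
                if a[i - 1] == b[j - 1]:
                    n_match += 1
                else:
                    n_mm += 1
                i -= 1
                j -= 1
            elif i > 0 and H[i, j] == E[i, j]:
                state = "E"
                n_indel += 1
            else:
                state = "F"
                n_indel += 1
        elif state == "E":
            out_a.append(a[i - 1])
            out_b.append("-")
            if i > 1 and E[i, j] == E[i - 1, j] + ext:
                i -= 1
            else:
                i -= 1
                state = "H"
        else:  # state == "F"
            out_a.append("-")
            out_b.append(b[j - 1])
            if j > 1 and F[i, j] == F[i, j - 1] + ext:
                j -= 1
            else:
                j -= 1
                state = "H"
    return LocalAlignment(
        score, i, end_i, j, end_j, n_match, n_mm, n_indel,
        "".join(reversed(out_a)), "".join(reversed(out_b)),
    )
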