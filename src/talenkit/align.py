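"""Global affine-gap read alignment with deterministic indel coordinates.

Amplicon reads are aligned end-to-end against the reference locus with a
Gotoh three-state dynamic program (match +2, mismatch -4, gap open -10,
gap extend -1; a gap of length L costs open + (L-1)*extend).  Ties are
broken in a fixed order -- diagonal, then deletion (gap in the read),
then insertion -- and every indel is subsequently shifted to its leftmost
equivalent placement, so identical biology always yields identical
reference coordinates regardless of read orientation of the surrounding
repeat structure.

Because an indel inside a repeat is positionally ambiguous (the classic
micro-homology ambiguity), :func:`deletion_equivalence_range` reports the
full range of equivalent placements; downstream deletion-center
statistics use its midpoint, which is unbiased where the leftmost
placement is not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "Scoring",
    "Alignment",
    "align_read",
    "deletion_equivalence_range",
    "left_shift_deletion",
    "left_shift_insertion",
]


@dataclass(frozen=True)
class Scoring:
    match: int = 2
    mismatch: int = -4
    gap_open: int = -10  # cost of the first gapped base
    gap_extend: int = -1  # each additional gapped base


@njit(cache=True)
def _gotoh_kernel(a, b, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    """Three-state global DP over ref ``a`` / read ``b``.

    Returns (score, ops) with ops codes 0 = diagonal, 1 = deletion
    (consumes ref), 2 = insertion (consumes read), in alignment order.
    Tie preference everywhere: M > D > I.
    """
    n = a.shape[0]
    m = b.shape[0]
    NEG = np.int32(-(2 ** 30))
    M = np.full((n + 1, m + 1), NEG, np.int32)
    D = np.full((n + 1, m + 1), NEG, np.int32)
    I = np.full((n + 1, m + 1), NEG, np.int32)
    tM = np.zeros((n + 1, m + 1), np.int8)
    tD = np.zeros((n + 1, m + 1), np.int8)
    tI = np.zeros((n + 1, m + 1), np.int8)
    M[0, 0] = 0
    for i in range(1, n + 1):
        D[i, 0] = gap_open + (i - 1) * gap_extend
        tD[i, 0] = 0 if i == 1 else 1
    for j in range(1, m + 1):
        I[0, j] = gap_open + (j - 1) * gap_extend
        tI[0, j] = 0 if j == 1 else 2
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = match if ai == b[j - 1] else mismatch
            best = M[i - 1, j - 1]
            p = 0
            if D[i - 1, j - 1] > best:
                best = D[i - 1, j - 1]
                p = 1
            if I[i - 1, j - 1] > best:
                best = I[i - 1, j - 1]
                p = 2
            M[i, j] = best + s
            tM[i, j] = p

            c0 = M[i - 1, j] + gap_open
            c1 = D[i - 1, j] + gap_extend
            c2 = I[i - 1, j] + gap_open
            best = c0
            p = 0
            if c1 > best:
                best = c1
                p = 1
            if c2 > best:
                best = c2
                p = 2
            D[i, j] = best
            tD[i, j] = p

            c0 = M[i, j - 1] + gap_open
            c1 = D[i, j - 1] + gap_open
            c2 = I[i, j - 1] + gap_extend
            best = c0
            p = 0
            if c1 > best:
                best = c1
                p = 1
            if c2 > best:
                best = c2
                p = 2
            I[i, j] = best
            tI[i, j] = p

    k = 0
    score = M[n, m]
    if D[n, m] > score:
        score = D[n, m]
        k = 1
    if I[n, m] > score:
        score = I[n, m]
        k = 2
    ops = np.empty(n + m, np.int8)
    t = 0
    i = n
    j = m
    while i > 0 or j > 0:
        ops[t] = k
        t += 1
        if k == 0:
            k = tM[i, j]
            i -= 1
            j -= 1
        elif k == 1:
            k = tD[i, j]
            i -= 1
        else:
            k = tI[i, j]
            j -= 1
    return score, ops[:t][::-1].copy()


@dataclass(frozen=True)
class Alignment:
    """Indel-level view of one global read alignment.

    ``deletions`` are reference half-open intervals, ``insertions`` are
    ``(ref position, inserted sequence)``; both are gap-left normalised.
    """

    score: int
    deletions: tuple[tuple[int, int], ...]
    insertions: tuple[tuple[int, str], ...]
    n_subs: int


def left_shift_deletion(ref: str, start: int, end: int, bound: int = 0
                        ) -> tuple[int, int]:
    """Leftmost equivalent placement of deleting ref[start:end]."""
    while start > bound and ref[start - 1] == ref[end - 1]:
        start -= 1
        end -= 1
    return start, end


def left_shift_insertion(ref: str, pos: int, ins: str, bound: int = 0
                         ) -> tuple[int, str]:
    """Leftmost equivalent placement of inserting ``ins`` before ref[pos]."""
    while pos > bound and ref[pos - 1] == ins[-1]:
        ins = ref[pos - 1] + ins[:-1]
        pos -= 1
    return pos, ins


def deletion_equivalence_range(ref: str, start: int, end: int
                               ) -> tuple[int, int]:
    """Range ``(min_start, max_start)`` of equivalent deletion placements.

    Deleting ``ref[start:end]`` yields the same sequence as deleting the
    same-length window at any start in the returned inclusive range.
    """
    length = end - start
    a = start
    while a > 0 and ref[a - 1] == ref[a - 1 + length]:
        a -= 1
    b = start
    while b + length < len(ref) and ref[b + length] == ref[b]:
        b += 1
    return a, b


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def align_read(read: str, ref: str, scoring: Scoring = Scoring()) -> Alignment:
    """Globally align ``read`` to ``ref`` and extract normalised indels."""
    if not read or not ref:
        raise ValueError("read and reference must be non-empty")
    read_u = read.upper()
    ref_u = ref.upper()
    if read_u == ref_u:
        return Alignment(scoring.match * len(ref_u), (), (), 0)
    score, ops = _gotoh_kernel(
        _encode(ref_u), _encode(read_u),
        scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend,
    )
    raw: list[tuple[str, int, int, int]] = []  # (kind, ref_start, ref_end, read_start)
    n_subs = 0
    i = j = 0
    for op in ops:
        if op == 0:
            if ref_u[i] != read_u[j]:
                n_subs += 1
            i += 1
            j += 1
        elif op == 1:
            if raw and raw[-1][0] == "D" and raw[-1][2] == i:
                raw[-1] = ("D", raw[-1][1], i + 1, raw[-1][3])
            else:
                raw.append(("D", i, i + 1, j))
            i += 1
        else:
            if raw and raw[-1][0] == "I" and raw[-1][1] == i and \
                    raw[-1][3] + (raw[-1][2] - raw[-1][1]) == j:
                raw[-1] = ("I", i, i + (j + 1 - raw[-1][3]), raw[-1][3])
            else:
                raw.append(("I", i, i + 1, j))
            j += 1
    dels: list[tuple[int, int]] = []
    inss: list[tuple[int, str]] = []
    bound = 0  # left-shifting never crosses an earlier indel
    for kind, a, b, jstart in raw:
        if kind == "D":
            a2, b2 = left_shift_deletion(ref_u, a, b, bound)
            dels.append((a2, b2))
            bound = b2
        else:
            ins_seq = read_u[jstart : jstart + (b - a)]
            p2, s2 = left_shift_insertion(ref_u, a, ins_seq, bound)
            inss.append((p2, s2))
            bound = max(bound, p2)
    return Alignment(int(score), tuple(dels), tuple(inss), n_subs)
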