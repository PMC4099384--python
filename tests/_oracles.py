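"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately written with plain Python loops and
string operations, separate from the vectorised/compiled code paths in
the package.
"""

from __future__ import annotations

import math

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def rc(seq: str) -> str:
    return "".join(COMP.get(b, b) for b in reversed(seq))


def brute_sites(seq: str, strand: str, L: int) -> list[tuple[int, int, int]]:
    """(start, end, t0) footprints of single sites by positional scan."""
    seq = seq.upper()
    n = len(seq)
    out = []
    if strand == "+":
        for i in range(n - L):
            if seq[i] == "T" and all(b in "ACGT" for b in seq[i + 1 : i + 1 + L]):
                out.append((i, i + L + 1, i))
    else:
        for q in range(L, n):
            if seq[q] == "A" and all(b in "ACGT" for b in seq[q - L : q]):
                out.append((q - L, q + 1, q))
    return out


def brute_pairs(seq: str, arch_name: str, L: int, windows) -> set:
    """All valid paired targets by pairing independently enumerated sites.

    Returns a set of (footprint_start, footprint_end, spacer, bound_strand).
    """
    lengths = set(windows.lengths())
    plus = brute_sites(seq, "+", L)
    minus = brute_sites(seq, "-", L)
    pairs = set()
    if arch_name == "TtT":
        # + site left (T0 distal-left), - site right (T0 distal-right)
        for (a0, a1, _) in plus:
            for (b0, b1, _) in minus:
                s = b0 - a1
                if s in lengths:
                    pairs.add((a0, b1, s, "+"))
    elif arch_name == "HtH":
        # - site left (T0 proximal), + site right (T0 proximal)
        for (a0, a1, _) in minus:
            for (b0, b1, _) in plus:
                s = b0 - a1
                if s in lengths:
                    pairs.add((a0, b1, s, "+"))
    else:  # TtH: tandem same-strand pairs, both orientations
        for (a0, a1, _) in plus:
            for (b0, b1, _) in plus:
                s = b0 - a1
                if s in lengths:
                    pairs.add((a0, b1, s, "+"))
        for (a0, a1, _) in minus:
            for (b0, b1, _) in minus:
                # bound-strand left site is the forward-rightmost one
                s = b0 - a1
                if s in lengths:
                    pairs.add((a0, b1, s, "-"))
    return pairs


def brute_union_coverage(pairs: set, n: int) -> int:
    """Covered base count by explicit per-base marking."""
    covered = [False] * n
    for (a, b, _s, _o) in pairs:
        for i in range(a, b):
            covered[i] = True
    return sum(covered)


def oracle_align(read: str, ref: str, match=2, mismatch=-4,
                 gap_open=-10, gap_extend=-1):
    """Plain-Python Gotoh global aligner; same scoring and tie rules
    (diagonal > deletion > insertion; gap of length L costs
    open + (L-1)*extend), with indels shifted to their leftmost
    equivalent placement.

    Returns (score, deletions, insertions, n_subs) with deletions as
    ref half-open intervals and insertions as (ref_pos, seq).
    """
    read = read.upper()
    ref = ref.upper()
    n, m = len(ref), len(read)
    NEG = -(10 ** 9)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    D = [[NEG] * (m + 1) for _ in range(n + 1)]
    I = [[NEG] * (m + 1) for _ in range(n + 1)]
    PM = [[0] * (m + 1) for _ in range(n + 1)]
    PD = [[0] * (m + 1) for _ in range(n + 1)]
    PI = [[0] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0
    for i in range(1, n + 1):
        D[i][0] = gap_open + (i - 1) * gap_extend
        PD[i][0] = 0 if i == 1 else 1
    for j in range(1, m + 1):
        I[0][j] = gap_open + (j - 1) * gap_extend
        PI[0][j] = 0 if j == 1 else 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if ref[i - 1] == read[j - 1] else mismatch
            cands = (M[i - 1][j - 1], D[i - 1][j - 1], I[i - 1][j - 1])
            p = max(range(3), key=lambda k: (cands[k], -k))
            M[i][j] = cands[p] + s
            PM[i][j] = p
            cands = (M[i - 1][j] + gap_open, D[i - 1][j] + gap_extend,
                     I[i - 1][j] + gap_open)
            p = max(range(3), key=lambda k: (cands[k], -k))
            D[i][j] = cands[p]
            PD[i][j] = p
            cands = (M[i][j - 1] + gap_open, D[i][j - 1] + gap_open,
                     I[i][j - 1] + gap_extend)
            p = max(range(3), key=lambda k: (cands[k], -k))
            I[i][j] = cands[p]
            PI[i][j] = p
    finals = (M[n][m], D[n][m], I[n][m])
    k = max(range(3), key=lambda x: (finals[x], -x))
    score = finals[k]
    i, j = n, m
    ops = []
    while i > 0 or j > 0:
        ops.append(k)
        if k == 0:
            k = PM[i][j]
            i, j = i - 1, j - 1
        elif k == 1:
            k = PD[i][j]
            i -= 1
        else:
            k = PI[i][j]
            j -= 1
    ops.reverse()
    dels, inss = [], []
    n_subs = 0
    i = j = 0
    for op in ops:
        if op == 0:
            if ref[i] != read[j]:
                n_subs += 1
            i += 1
            j += 1
        elif op == 1:
            if dels and dels[-1][1] == i:
                dels[-1][1] = i + 1
            else:
                dels.append([i, i + 1])
            i += 1
        else:
            if inss and inss[-1][0] == i and inss[-1][2]:
                inss[-1][1] += read[j]
            else:
                inss.append([i, read[j], True])
            j += 1
    bound = 0
    norm_dels = []
    norm_inss = []
    events = sorted(
        [("D", a, b, None) for a, b in dels]
        + [("I", p, None, s) for p, s, _ in inss],
        key=lambda e: e[1],
    )
    for kind, a, b, s in events:
        if kind == "D":
            while a > bound and ref[a - 1] == ref[b - 1]:
                a, b = a - 1, b - 1
            norm_dels.append((a, b))
            bound = b
        else:
            while a > bound and ref[a - 1] == s[-1]:
                s = ref[a - 1] + s[:-1]
                a -= 1
            norm_inss.append((a, s))
            bound = max(bound, a)
    return score, tuple(norm_dels), tuple(norm_inss), n_subs


def pooled_t(xs, ys):
    """Closed-form pooled-variance two-sample t statistic and df."""
    nx, ny = len(xs), len(ys)
    mx = sum(xs) / nx
    my = sum(ys) / ny
    ssx = sum((x - mx) ** 2 for x in xs)
    ssy = sum((y - my) ** 2 for y in ys)
    sp2 = (ssx + ssy) / (nx + ny - 2)
    t = (mx - my) / math.sqrt(sp2 * (1 / nx + 1 / ny))
    return t, nx + ny - 2
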