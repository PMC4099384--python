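"""Architecture-aware target-site discovery and genome targetability.

Enumerates every valid paired target of an architecture over arbitrary
sequences and derives base-resolution coverage: a position is *targetable*
iff it lies within at least one paired-target footprint, and maximal
uncovered runs are reported as target-devoid regions (the quantity behind
chromosome-scale targetability estimates such as "99.8% of chromosome 1").

Scanning is case-insensitive by default; with ``respect_mask=True``
soft-masked (lowercase) bases are excluded.  Ambiguous bases never
satisfy T0 and never match a recognised position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .core import (
    Architecture,
    ArrayGeometry,
    BindingSite,
    PairedTarget,
    reverse_complement,
)

__all__ = [
    "DevoidRegion",
    "CoverageReport",
    "find_sites",
    "find_paired_targets",
    "coverage_scan",
    "targets_to_bed",
]

_T, _A = 84, 65  # ASCII 'T', 'A'


def _prep(seq: str, respect_mask: bool) -> tuple[np.ndarray, np.ndarray]:
    """Uppercase byte array plus per-base validity mask."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    lower = (raw >= 97) & (raw <= 122)
    up = np.where(lower, raw - 32, raw)
    valid = (up == 65) | (up == 67) | (up == 71) | (up == 84)
    if respect_mask:
        valid &= ~lower
    return up, valid


def _site_masks(up: np.ndarray, valid: np.ndarray, l_rec: int
                ) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks over T0 positions of valid +/- strand sites.

    ``plus[i]`` -- forward-strand site with T0 at i (footprint [i, i+L+1)).
    ``minus[q]`` -- reverse-strand site with T0 at q (footprint [q-L, q+1));
    the reference base at q is A, i.e. T on the bound strand.
    """
    n = len(up)
    L = l_rec
    plus = np.zeros(n, dtype=bool)
    minus = np.zeros(n, dtype=bool)
    if n < L + 1:
        return plus, minus
    cum = np.concatenate(([0], np.cumsum(valid)))
    i = np.arange(0, n - L)
    full = (cum[i + 1 + L] - cum[i + 1]) == L
    plus[i] = (up[i] == _T) & valid[i] & full
    q = np.arange(L, n)
    full = (cum[q] - cum[q - L]) == L
    minus[q] = (up[q] == _A) & valid[q] & full
    return plus, minus


def find_sites(
    seq: str,
    strand: str,
    geom: ArrayGeometry,
    chrom: str = "seq",
    respect_mask: bool = False,
) -> list[BindingSite]:
    """All single binding sites on one strand, in forward coordinates."""
    if strand not in "+-":
        raise ValueError("strand must be '+' or '-'")
    up, valid = _prep(seq, respect_mask)
    plus, minus = _site_masks(up, valid, geom.l_rec)
    L = geom.l_rec
    su = seq.upper()
    sites = []
    if strand == "+":
        for i in np.flatnonzero(plus):
            i = int(i)
            sites.append(
                BindingSite(chrom, i, i + L + 1, "+", i, su[i + 1 : i + 1 + L])
            )
    else:
        for q in np.flatnonzero(minus):
            q = int(q)
            sites.append(
                BindingSite(
                    chrom, q - L, q + 1, "-", q,
                    reverse_complement(su[q - L : q]),
                )
            )
    return sites


def _pair_start_arrays(
    plus: np.ndarray, minus: np.ndarray, arch: Architecture, l_rec: int
) -> list[tuple[str, int, np.ndarray]]:
    """Footprint-start positions of valid pairs, per (bound strand, spacer).

    Returns tuples ``(bound_strand, s, starts)`` where each start ``p`` is
    the leftmost reference coordinate of the full footprint of span
    ``2*(l_rec+1) + s``.
    """
    L = l_rec
    site = L + 1
    n = len(plus)
    out: list[tuple[str, int, np.ndarray]] = []
    for s in arch.spacer_windows.lengths():
        span = 2 * site + s
        if span > n:
            continue
        p = np.arange(0, n - span + 1)
        if arch.name == "TtT":
            # + site T0 at p; - site T0 at p + span - 1 (distal)
            keep = plus[p] & minus[p + span - 1]
            out.append(("+", s, p[keep]))
        elif arch.name == "HtH":
            # - site T0 at p + L (spacer-proximal); + site T0 at p + site + s
            keep = minus[p + L] & plus[p + site + s]
            out.append(("+", s, p[keep]))
        else:  # TtH: tandem sites, either strand
            keep = plus[p] & plus[p + site + s]
            out.append(("+", s, p[keep]))
            # reverse strand: head site first in forward coords
            keep = minus[p + L] & minus[p + span - 1]
            out.append(("-", s, p[keep]))
    return out


def _materialize(
    su: str, chrom: str, arch: Architecture, l_rec: int,
    bound: str, s: int, p: int,
) -> PairedTarget:
    L = l_rec
    site = L + 1
    span = 2 * site + s
    rc = reverse_complement
    if arch.name == "TtT":
        left = BindingSite(chrom, p, p + site, "+", p, su[p + 1 : p + site])
        q = p + span - 1
        right = BindingSite(chrom, q - L, q + 1, "-", q, rc(su[q - L : q]))
    elif arch.name == "HtH":
        q = p + L
        left = BindingSite(chrom, p, p + site, "-", q, rc(su[p : p + L]))
        r0 = p + site + s
        right = BindingSite(chrom, r0, r0 + site, "+", r0, su[r0 + 1 : r0 + site])
    elif bound == "+":  # TtH forward
        left = BindingSite(chrom, p, p + site, "+", p, su[p + 1 : p + site])
        r0 = p + site + s
        right = BindingSite(chrom, r0, r0 + site, "+", r0, su[r0 + 1 : r0 + site])
    else:  # TtH on the reverse strand: tail site at higher coordinates
        q1 = p + span - 1
        left = BindingSite(chrom, q1 - L, q1 + 1, "-", q1, rc(su[q1 - L : q1]))
        q2 = p + L
        right = BindingSite(chrom, p, p + site, "-", q2, rc(su[p : p + L]))
    return PairedTarget(arch, left, right, s, bound)


def find_paired_targets(
    seq: str,
    arch: Architecture,
    geom: ArrayGeometry,
    chrom: str = "seq",
    respect_mask: bool = False,
    require_distinct_sites: bool = False,
) -> list[PairedTarget]:
    """Exhaustively enumerate valid paired targets for one architecture.

    Overlapping and nested targets are all reported; order is by footprint
    start, then spacer length, then bound strand.  With
    ``require_distinct_sites`` pairs whose two bound-strand site sequences
    are identical (palindromic self-pairs) are dropped.
    """
    up, valid = _prep(seq, respect_mask)
    plus, minus = _site_masks(up, valid, geom.l_rec)
    su = seq.upper()
    found = []
    for bound, s, starts in _pair_start_arrays(plus, minus, arch, geom.l_rec):
        for p in starts:
            found.append(_materialize(su, chrom, arch, geom.l_rec, bound, s, int(p)))
    if require_distinct_sites:
        found = [
            t for t in found
            if t.left_site.bound_seq != t.right_site.bound_seq
        ]
    found.sort(key=lambda t: (t.start, t.spacer_len, t.bound_strand))
    return found


@dataclass(frozen=True)
class DevoidRegion:
    """Maximal interval intersecting no paired-target footprint."""

    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CoverageReport:
    """Base-resolution targetability of a sequence set."""

    total_bp: int
    covered_bp: int
    devoid_regions: list[DevoidRegion] = field(default_factory=list)
    per_architecture: dict[str, int] = field(default_factory=dict)

    @property
    def coverage_fraction(self) -> float:
        return self.covered_bp / self.total_bp if self.total_bp else 0.0

    def to_dict(self) -> dict:
        return {
            "total_bp": self.total_bp,
            "covered_bp": self.covered_bp,
            "coverage_fraction": self.coverage_fraction,
            "n_devoid_regions": len(self.devoid_regions),
            "devoid_bp": sum(r.length for r in self.devoid_regions),
            "per_architecture": dict(self.per_architecture),
        }


def _mark_covered(
    covered: np.ndarray, seq: str, arch: Architecture, l_rec: int,
    offset: int, lo: int, hi: int, respect_mask: bool,
) -> None:
    """Mark footprint coverage of ``seq`` into ``covered[offset + ...]``.

    Only marks within the chunk [lo, hi) of the global sequence to keep
    windowed scans equal to whole-sequence scans.
    """
    up, valid = _prep(seq, respect_mask)
    plus, minus = _site_masks(up, valid, l_rec)
    site = l_rec + 1
    diff = np.zeros(len(covered) + 1, dtype=np.int32)
    for _, s, starts in _pair_start_arrays(plus, minus, arch, l_rec):
        if len(starts) == 0:
            continue
        span = 2 * site + s
        a = np.clip(starts + offset, lo, hi)
        b = np.clip(starts + offset + span, lo, hi)
        np.add.at(diff, a, 1)
        np.add.at(diff, b, -1)
    covered |= np.cumsum(diff[:-1]) > 0


def coverage_scan(
    sequences: Iterable[tuple[str, str]],
    archs: Sequence[Architecture] | Architecture,
    geom: ArrayGeometry,
    chunk: int | None = None,
    respect_mask: bool = False,
) -> CoverageReport:
    """Targetable coverage and devoid regions over multi-record input.

    ``sequences`` yields ``(name, sequence)`` pairs.  A base is covered iff
    it lies inside the footprint of at least one paired target of any
    requested architecture.  With ``chunk`` the scan is windowed (overlap
    equal to the maximal footprint span minus one), which gives results
    identical to the whole-sequence scan while bounding memory for the
    per-window site tables.
    """
    if isinstance(archs, Architecture):
        archs = [archs]
    total = 0
    covered_total = 0
    per_arch: dict[str, int] = {a.name: 0 for a in archs}
    devoid: list[DevoidRegion] = []
    for name, seq in sequences:
        n = len(seq)
        total += n
        union = np.zeros(n, dtype=bool)
        for arch in archs:
            cov = np.zeros(n, dtype=bool)
            span = 2 * geom.site_len + arch.spacer_windows.max_len
            if chunk is None or chunk >= n:
                _mark_covered(cov, seq, arch, geom.l_rec, 0, 0, n, respect_mask)
            else:
                pad = span - 1
                for lo in range(0, n, chunk):
                    hi = min(lo + chunk, n)
                    a = max(0, lo - pad)
                    b = min(n, hi + pad)
                    _mark_covered(
                        cov, seq[a:b], arch, geom.l_rec, a, lo, hi, respect_mask
                    )
            per_arch[arch.name] += int(cov.sum())
            union |= cov
        covered_total += int(union.sum())
        # maximal uncovered runs
        edges = np.diff(np.concatenate(([0], (~union).astype(np.int8), [0])))
        starts = np.flatnonzero(edges == 1)
        ends = np.flatnonzero(edges == -1)
        devoid.extend(
            DevoidRegion(name, int(a), int(b)) for a, b in zip(starts, ends)
        )
    return CoverageReport(total, covered_total, devoid, per_arch)


def targets_to_bed(targets: Iterable[PairedTarget]) -> str:
    """BED6+ rendering: name = architecture, score = spacer length,
    strand = left-site strand, extra columns = site coordinates."""
    lines = []
    for t in targets:
        lines.append(
            "\t".join(
                str(x)
                for x in (
                    t.chrom, t.start, t.end, t.architecture.name,
                    t.spacer_len, t.left_site.strand,
                    t.left_site.start, t.left_site.end,
                    t.right_site.start, t.right_site.end, t.bound_strand,
                )
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")
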