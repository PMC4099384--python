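"""Off-site target enumeration for a designed nuclease pair.

A genomic off-site target is any combination of near-matches of the two
designed half-sites -- left + right, left + left, or right + right --
separated by a spacer compatible with nuclease activity.  Half-site
matching is plain Hamming distance over the recognised bases with a hard
requirement for the T0 anchor (a non-T at T0 disqualifies the site, it is
not a countable mismatch).  Because FokI dimerisation constrains geometry
through the scaffold kinds, two tail fusions always pair in the TtT
layout, two head fusions in HtH, and a mixed pair in TtH -- regardless of
which architecture the pair was designed for.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import (
    PairedTarget,
    ScaffoldKind,
    SpacerWindows,
    reverse_complement,
)
from .scan import _prep

__all__ = [
    "MonomerHit",
    "DesignedPair",
    "OfftargetHit",
    "match_monomer",
    "enumerate_offtargets",
    "offtarget_summary",
    "offtarget_ratio",
    "geometry_for_kinds",
]

PAIR_TYPES = ("L+R", "L+L", "R+R")


@dataclass(frozen=True)
class MonomerHit:
    """One half-site match: forward footprint start, strand, mismatches."""

    start: int
    strand: str
    mismatches: int


@dataclass(frozen=True)
class DesignedPair:
    """The two half-sites of a designed nuclease (bound-strand sequences,
    T0 included) plus their scaffold kinds."""

    left_seq: str
    right_seq: str
    left_kind: ScaffoldKind = ScaffoldKind.TALE_FOKI
    right_kind: ScaffoldKind = ScaffoldKind.FOKI_TALE

    def __post_init__(self) -> None:
        object.__setattr__(self, "left_kind", ScaffoldKind.parse(self.left_kind))
        object.__setattr__(self, "right_kind", ScaffoldKind.parse(self.right_kind))
        for seq in (self.left_seq, self.right_seq):
            if not seq or seq[0].upper() != "T":
                raise ValueError("half-site sequences must start with T0")

    @classmethod
    def from_target(cls, target: PairedTarget) -> "DesignedPair":
        return cls(
            target.left_site.bound_seq,
            target.right_site.bound_seq,
            target.architecture.left.kind,
            target.architecture.right.kind,
        )


@dataclass(frozen=True)
class OfftargetHit:
    """A candidate off-site target.

    ``left_*``/``right_*`` are in architecture-role order (the left role
    is the scaffold whose 3' side faces the spacer in TtT/TtH, or the
    reverse-strand head site in HtH); starts are forward footprint starts.
    """

    pair_type: str
    geometry: str
    bound_strand: str
    left_start: int
    left_strand: str
    right_start: int
    right_strand: str
    mm_left: int
    mm_right: int
    spacer_len: int


def geometry_for_kinds(kind_a: ScaffoldKind, kind_b: ScaffoldKind) -> str:
    """Pair layout forced by two scaffold kinds."""
    kinds = {kind_a, kind_b}
    if kinds == {ScaffoldKind.TALE_FOKI}:
        return "TtT"
    if kinds == {ScaffoldKind.FOKI_TALE}:
        return "HtH"
    return "TtH"


def match_monomer(
    genome: str, site_seq: str, k_max: int, respect_mask: bool = False
) -> list[MonomerHit]:
    """All half-site matches on both strands.

    ``site_seq`` is T0 plus recognised bases, 5'->3' on the bound strand.
    A hit requires an exact T at T0 and at most ``k_max`` mismatches over
    the recognised bases; ambiguous or masked bases never match.
    """
    if k_max < 0:
        raise ValueError("k_max must be >= 0")
    site = site_seq.upper()
    if not site or site[0] != "T":
        raise ValueError("site_seq must start with T0")
    L = len(site) - 1
    up, valid = _prep(genome, respect_mask)
    n = len(up)
    hits: list[MonomerHit] = []
    if n < L + 1:
        return hits
    w = n - L  # number of footprint start positions
    site_b = np.frombuffer(site.encode("ascii"), dtype=np.uint8)
    # forward strand: footprint [i, i+L+1), T0 at i
    mm = np.zeros(w, dtype=np.int32)
    for j in range(1, L + 1):
        mm += ((up[j : j + w] != site_b[j]) | ~valid[j : j + w]).astype(np.int32)
    ok = (up[:w] == ord("T")) & valid[:w] & (mm <= k_max)
    for i in np.flatnonzero(ok):
        hits.append(MonomerHit(int(i), "+", int(mm[i])))
    # reverse strand: forward footprint equals revcomp(site); T0 maps to the
    # final forward base, which must be A
    rc = np.frombuffer(
        reverse_complement(site).encode("ascii"), dtype=np.uint8
    )
    mm = np.zeros(w, dtype=np.int32)
    for j in range(L):
        mm += ((up[j : j + w] != rc[j]) | ~valid[j : j + w]).astype(np.int32)
    ok = (up[L : L + w] == ord("A")) & valid[L : L + w] & (mm <= k_max)
    for i in np.flatnonzero(ok):
        hits.append(MonomerHit(int(i), "-", int(mm[i])))
    return hits


def _index(hits: Iterable[MonomerHit], strand: str) -> dict[int, MonomerHit]:
    return {h.start: h for h in hits if h.strand == strand}


def _combine(
    hits_first: Mapping[int, MonomerHit],
    hits_second: Mapping[int, MonomerHit],
    len_first: int,
    windows: SpacerWindows,
) -> list[tuple[MonomerHit, MonomerHit, int]]:
    """Ordered (forward-left, forward-right) pairs at admissible spacers."""
    out = []
    for s in windows.lengths():
        delta = len_first + 1 + s
        for start, h1 in hits_first.items():
            h2 = hits_second.get(start + delta)
            if h2 is not None:
                out.append((h1, h2, s))
    return out


def enumerate_offtargets(
    genome: str,
    pair: DesignedPair,
    k_max: int,
    windows_by_geometry: Mapping[str, SpacerWindows],
    pair_types: Sequence[str] = PAIR_TYPES,
    exclude: tuple[int, int] | None = None,
    respect_mask: bool = False,
) -> list[OfftargetHit]:
    """Enumerate candidate off-site targets of a designed pair.

    ``windows_by_geometry`` maps layout name (TtT/HtH/TtH) to its
    admissible spacer windows.  ``exclude`` drops the on-target itself,
    given as the (left footprint start, right footprint start) of the
    designed target.
    """
    monomers = {"L": pair.left_seq, "R": pair.right_seq}
    kinds = {"L": pair.left_kind, "R": pair.right_kind}
    lens = {k: len(v) - 1 for k, v in monomers.items()}
    hit_cache = {
        key: match_monomer(genome, seq, k_max, respect_mask)
        for key, seq in monomers.items()
    }
    results: list[OfftargetHit] = []
    for pt in pair_types:
        if pt not in PAIR_TYPES:
            raise ValueError(f"unknown pair type {pt!r}")
        a, b = pt.split("+")
        geometry = geometry_for_kinds(kinds[a], kinds[b])
        windows = windows_by_geometry.get(geometry)
        if windows is None:
            continue
        if geometry == "TtH":
            tail, head = (a, b) if kinds[a] is ScaffoldKind.TALE_FOKI else (b, a)
            # forward bound strand: tail then head left-to-right
            for h1, h2, s in _combine(
                _index(hit_cache[tail], "+"), _index(hit_cache[head], "+"),
                lens[tail], windows,
            ):
                results.append(OfftargetHit(
                    pt, geometry, "+", h1.start, "+", h2.start, "+",
                    h1.mismatches, h2.mismatches, s,
                ))
            # reverse bound strand: head then tail left-to-right
            for h1, h2, s in _combine(
                _index(hit_cache[head], "-"), _index(hit_cache[tail], "-"),
                lens[head], windows,
            ):
                results.append(OfftargetHit(
                    pt, geometry, "-", h2.start, "-", h1.start, "-",
                    h2.mismatches, h1.mismatches, s,
                ))
        else:
            # opposite-strand layouts; forward-left role strand differs
            left_strand = "+" if geometry == "TtT" else "-"
            right_strand = "-" if geometry == "TtT" else "+"
            arrangements = [(a, b)]
            if a != b:
                arrangements.append((b, a))
            for first, second in arrangements:
                for h1, h2, s in _combine(
                    _index(hit_cache[first], left_strand),
                    _index(hit_cache[second], right_strand),
                    lens[first], windows,
                ):
                    results.append(OfftargetHit(
                        pt, geometry, "+", h1.start, left_strand,
                        h2.start, right_strand,
                        h1.mismatches, h2.mismatches, s,
                    ))
    if exclude is not None:
        results = [
            h for h in results
            if not (
                h.mm_left == 0 and h.mm_right == 0
                and {h.left_start, h.right_start} == set(exclude)
            )
        ]
    results.sort(key=lambda h: (min(h.left_start, h.right_start),
                                h.spacer_len, h.pair_type))
    return results


def offtarget_summary(hits: Sequence[OfftargetHit]) -> dict:
    """Counts per pair type and spacer-length histogram."""
    per_type: dict[str, int] = {pt: 0 for pt in PAIR_TYPES}
    per_spacer: dict[int, int] = {}
    for h in hits:
        per_type[h.pair_type] = per_type.get(h.pair_type, 0) + 1
        per_spacer[h.spacer_len] = per_spacer.get(h.spacer_len, 0) + 1
    return {
        "total": len(hits),
        "per_pair_type": per_type,
        "per_spacer_length": {str(k): per_spacer[k] for k in sorted(per_spacer)},
    }


def offtarget_ratio(count_a: float, count_b: float) -> float:
    """Fold difference between two off-site target counts."""
    if count_b == 0:
        raise ValueError("undefined fold ratio: zero denominator")
    return count_a / count_b
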