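"""Geometric model of paired TALE-FokI nucleases.

A TALE DNA-binding domain reads its target 5'->3' starting from an
invariant thymine (T0) that is contacted by the TALE N-terminal domain.
Fusing the FokI catalytic domain to either terminus of the TALE yields
two scaffolds:

* ``TALE_FOKI`` -- the "tail" fusion, FokI at the C-terminus, so the cut
  is delivered beyond the 3' end of the binding site;
* ``FOKI_TALE`` -- the "head" fusion, FokI at the N-terminus, so the cut
  is delivered upstream of the 5' T0.

FokI must dimerise to cleave, so nucleases act as pairs of scaffolds
flanking a spacer.  Three pair layouts exist:

* ``TtT`` (tail-to-tail, the classical TALEN): two TALE_FOKI scaffolds
  on opposite strands, T0s distal to the spacer;
* ``HtH`` (head-to-head): two FOKI_TALE scaffolds on opposite strands,
  T0s immediately flanking the spacer;
* ``TtH`` (tail-to-head): one TALE_FOKI followed by one FOKI_TALE in
  tandem on the *same* strand -- only one strand of the locus needs to
  carry thymines.

Each scaffold contributes a characteristic cleavage offset, measured in
bp from the spacer-proximal edge of its binding site to the expected cut
center.  The spacer length at which a pair is most active is modelled as
the sum of the two offsets; with the default offsets of 7.5 bp
(TALE_FOKI) and 12.5 bp (FOKI_TALE) this reproduces optima of 15, 20 and
25 bp for TtT, TtH and HtH.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ScaffoldKind",
    "Scaffold",
    "SpacerWindows",
    "Architecture",
    "RvdCode",
    "CANONICAL_RVD_CODE",
    "ArrayGeometry",
    "BindingSite",
    "PairedTarget",
    "reverse_complement",
    "rvd_for_sequence",
    "sequence_for_rvds",
    "predicted_optimal_spacer",
    "predicted_cut_center",
    "DEFAULT_CLEAVAGE_OFFSETS",
]

_RC_TABLE = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    """Reverse complement; non-ACGT characters (e.g. N) pass through unchanged."""
    return seq.translate(_RC_TABLE)[::-1]


class ScaffoldKind(str, Enum):
    """Which terminus of the TALE carries the FokI catalytic domain."""

    TALE_FOKI = "TALE::FokI"  # tail fusion, FokI C-terminal
    FOKI_TALE = "FokI::TALE"  # head fusion, FokI N-terminal

    @classmethod
    def parse(cls, value: "str | ScaffoldKind") -> "ScaffoldKind":
        if isinstance(value, cls):
            return value
        key = str(value).strip()
        for member in cls:
            if key in (member.name, member.value):
                return member
        raise ValueError(f"unknown scaffold kind: {value!r}")


#: Default per-scaffold cleavage offsets (bp from the spacer-proximal edge
#: of the binding site to the expected cut center).  The unique half-integer
#: pair whose pairwise sums give the observed 15/20/25 bp spacer optima.
DEFAULT_CLEAVAGE_OFFSETS: Mapping[ScaffoldKind, float] = {
    ScaffoldKind.TALE_FOKI: 7.5,
    ScaffoldKind.FOKI_TALE: 12.5,
}


@dataclass(frozen=True)
class Scaffold:
    """A TALE-FokI fusion variant with its cleavage-offset parameter."""

    kind: ScaffoldKind
    cleavage_offset: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", ScaffoldKind.parse(self.kind))
        if not self.cleavage_offset:
            object.__setattr__(
                self, "cleavage_offset", DEFAULT_CLEAVAGE_OFFSETS[self.kind]
            )
        if self.cleavage_offset <= 0:
            raise ValueError("cleavage_offset must be positive")


@dataclass(frozen=True)
class SpacerWindows:
    """Ordered, non-overlapping inclusive ranges of active spacer lengths."""

    windows: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        wins = tuple(sorted((int(lo), int(hi)) for lo, hi in self.windows))
        if not wins:
            raise ValueError("at least one spacer window is required")
        prev_hi = 0
        for lo, hi in wins:
            if lo < 1:
                raise ValueError("spacer lengths start at 1 bp")
            if hi < lo:
                raise ValueError(f"inverted window ({lo}, {hi})")
            if lo <= prev_hi:
                raise ValueError("spacer windows overlap")
            prev_hi = hi
        object.__setattr__(self, "windows", wins)

    def __contains__(self, s: int) -> bool:
        return any(lo <= s <= hi for lo, hi in self.windows)

    def lengths(self) -> list[int]:
        """All admissible spacer lengths, ascending."""
        return [s for lo, hi in self.windows for s in range(lo, hi + 1)]

    @property
    def min_len(self) -> int:
        return self.windows[0][0]

    @property
    def max_len(self) -> int:
        return self.windows[-1][1]

    @classmethod
    def parse(cls, spec: "str | Iterable[Sequence[int]] | SpacerWindows") -> "SpacerWindows":
        """Accept ``"18-22,27-33"``, ``[[18, 22], [27, 33]]`` or an instance."""
        if isinstance(spec, cls):
            return spec
        if isinstance(spec, str):
            parts = []
            for chunk in spec.split(","):
                lo, _, hi = chunk.strip().partition("-")
                parts.append((int(lo), int(hi or lo)))
            return cls(tuple(parts))
        return cls(tuple((int(a), int(b)) for a, b in spec))


_VALID_LAYOUTS = {
    "TtT": (ScaffoldKind.TALE_FOKI, ScaffoldKind.TALE_FOKI),
    "HtH": (ScaffoldKind.FOKI_TALE, ScaffoldKind.FOKI_TALE),
    "TtH": (ScaffoldKind.TALE_FOKI, ScaffoldKind.FOKI_TALE),
}


@dataclass(frozen=True)
class Architecture:
    """A paired-scaffold geometry with its strand layout and spacer windows.

    The strand layout is implied by the name: TtT places the left site on
    the forward strand and the right site on the reverse strand with both
    T0s distal to the spacer; HtH places the left site on the reverse
    strand and the right site on the forward strand with both T0s adjacent
    to the spacer; TtH places both sites in tandem on one strand.
    """

    name: str
    left: Scaffold
    right: Scaffold
    spacer_windows: SpacerWindows

    def __post_init__(self) -> None:
        if self.name not in _VALID_LAYOUTS:
            raise ValueError(f"unknown architecture {self.name!r}")
        expected = _VALID_LAYOUTS[self.name]
        if (self.left.kind, self.right.kind) != expected:
            raise ValueError(
                f"{self.name} requires scaffolds {expected[0].value} + "
                f"{expected[1].value}, got {self.left.kind.value} + "
                f"{self.right.kind.value}"
            )


class RvdCode:
    """Bijective nucleotide -> repeat-variable-di-residue map."""

    def __init__(self, mapping: Mapping[str, str] | None = None) -> None:
        mapping = dict(mapping or {"A": "NI", "C": "HD", "G": "NN", "T": "NG"})
        if set(mapping) != set("ACGT"):
            raise ValueError("RVD code must cover exactly A, C, G, T")
        if len(set(mapping.values())) != 4:
            raise ValueError("RVD code must be bijective")
        self.forward = mapping
        self.inverse = {v: k for k, v in mapping.items()}

    def encode(self, seq: str) -> list[str]:
        out = []
        for i, base in enumerate(seq.upper()):
            rvd = self.forward.get(base)
            if rvd is None:
                raise ValueError(f"unmappable base {base!r} at position {i}")
            out.append(rvd)
        return out

    def decode(self, rvds: Iterable[str]) -> str:
        out = []
        for i, rvd in enumerate(rvds):
            base = self.inverse.get(rvd)
            if base is None:
                raise ValueError(f"unknown RVD {rvd!r} at index {i}")
            out.append(base)
        return "".join(out)


#: The canonical association code (NI:A, HD:C, NN:G, NG:T).
CANONICAL_RVD_CODE = RvdCode()


def rvd_for_sequence(seq: str, code: RvdCode = CANONICAL_RVD_CODE) -> list[str]:
    """RVD array recognising ``seq`` (one di-residue per nucleotide)."""
    return code.encode(seq)


def sequence_for_rvds(rvds: Iterable[str], code: RvdCode = CANONICAL_RVD_CODE) -> str:
    """Inverse of :func:`rvd_for_sequence`."""
    return code.decode(rvds)


@dataclass(frozen=True)
class ArrayGeometry:
    """Repeat-array geometry.

    A TALE array of ``n + 0.5`` repeats reads ``n + 1`` nucleotides (the
    half-repeat reads one base), so the standard 15.5-repeat array
    recognises 16 nt and its footprint including T0 spans 17 bp.
    """

    repeats: float = 15.5

    def __post_init__(self) -> None:
        frac = self.repeats - int(self.repeats)
        if frac not in (0.0, 0.5):
            raise ValueError("repeats must be an integer or end in .5")
        if self.l_rec < 1:
            raise ValueError("array must recognise at least one nucleotide")

    @property
    def l_rec(self) -> int:
        """Number of recognised nucleotides (excluding T0)."""
        n = int(self.repeats)
        return n + 1 if self.repeats - n else n

    @property
    def site_len(self) -> int:
        """Footprint of one binding site including T0."""
        return self.l_rec + 1


@dataclass(frozen=True)
class BindingSite:
    """A single TALE binding site in forward reference coordinates.

    ``start``/``end`` are 0-based half-open and span the full footprint
    including T0; ``recognized_seq`` is read 5'->3' on the bound strand
    and excludes T0.  For a ``-`` strand site the T0 sits at ``end - 1``
    (reference base A).
    """

    chrom: str
    start: int
    end: int
    strand: str
    t0_pos: int
    recognized_seq: str
    rvds: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if self.end - self.start != len(self.recognized_seq) + 1:
            raise ValueError("footprint must span recognized_seq plus T0")
        expected_t0 = self.start if self.strand == "+" else self.end - 1
        if self.t0_pos != expected_t0:
            raise ValueError("t0_pos inconsistent with strand/footprint")
        if not self.rvds:
            object.__setattr__(
                self, "rvds", tuple(rvd_for_sequence(self.recognized_seq))
            )

    @property
    def bound_seq(self) -> str:
        """T0 plus recognised sequence, 5'->3' on the bound strand."""
        return "T" + self.recognized_seq


@dataclass(frozen=True)
class PairedTarget:
    """Two binding sites plus spacer on a reference sequence.

    ``bound_strand`` is the strand read 5'->3' by the architecture's left
    scaffold: always ``+`` for TtT and HtH (whose target sets are
    strand-symmetric) and either strand for TtH, whose tandem layout can
    sit entirely on the reverse strand (left site then at higher
    reference coordinates).
    """

    architecture: Architecture
    left_site: BindingSite
    right_site: BindingSite
    spacer_len: int
    bound_strand: str = "+"

    def __post_init__(self) -> None:
        first, second = sorted(
            (self.left_site, self.right_site), key=lambda s: s.start
        )
        gap = second.start - first.end
        if gap != self.spacer_len:
            raise ValueError(
                f"spacer_len {self.spacer_len} != site gap {gap}"
            )

    @property
    def chrom(self) -> str:
        return self.left_site.chrom

    @property
    def start(self) -> int:
        return min(self.left_site.start, self.right_site.start)

    @property
    def end(self) -> int:
        return max(self.left_site.end, self.right_site.end)

    @property
    def footprint(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def spacer_interval(self) -> tuple[int, int]:
        """Reference interval (0-based half-open) of the spacer."""
        first, second = sorted(
            (self.left_site, self.right_site), key=lambda s: s.start
        )
        return (first.end, second.start)


def predicted_optimal_spacer(arch: Architecture) -> float:
    """Spacer length of peak activity: the sum of the two cleavage offsets."""
    total = arch.left.cleavage_offset + arch.right.cleavage_offset
    return int(total) if float(total).is_integer() else total


def predicted_cut_center(target: PairedTarget) -> tuple[float, float]:
    """Expected cut center of a paired target.

    Returns ``(ref_coord, spacer_offset)``.  ``ref_coord`` is in forward
    reference base-index coordinates (half-integers land between bases).
    ``spacer_offset`` is relative to the spacer-center convention used
    for deletion centers: spacer bases are numbered 1..s from the left
    scaffold, coordinate 0 sits at base (s+1)/2, and the cut center lies
    ``o_left`` bp past the spacer-proximal edge of the left site, i.e. at
    spacer coordinate ``o_left``, giving an offset of
    ``o_left - (s + 1)/2`` (equivalently ``(o_left - o_right)/2 - 1/2``
    at the architecture's optimal spacer).
    """
    o_left = target.architecture.left.cleavage_offset
    s = target.spacer_len
    sp_start, sp_end = target.spacer_interval
    if target.bound_strand == "+":
        ref = (sp_start - 1) + o_left
    else:
        ref = sp_end - o_left
    return ref, o_left - (s + 1) / 2
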