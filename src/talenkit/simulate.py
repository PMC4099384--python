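"""Synthetic genomes and amplicon read sets with a parametric NHEJ model.

The genome generator produces i.i.d. sequence with a controllable base
composition and verbatim planted features such as trinucleotide /
tetranucleotide repeat expansions (CAG, CTG, GAA, CCTG) whose forward
strand carries thymines on only one strand -- the sequence class that
motivates the single-strand tail-to-head architecture.

The read simulator emulates deep-sequenced amplicons over a nuclease
locus: each read is wild type with probability ``1 - event_rate``;
otherwise it carries a single NHEJ event, an insertion with probability
``p_ins`` or a deletion otherwise.  Deletion lengths are geometric (or an
empirical table), deletion centers are normal around the locus' predicted
cut position in spacer-relative coordinates, and a deletion is laid out
symmetrically about its sampled center with the fractional part resolved
by stochastic rounding, so the planted midpoint is unbiased for the
sampled center.  A uniform per-base substitution error is applied last.
Every event is recorded in a truth table, with indel coordinates
left-normalised exactly as the analysis pipeline reports them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .align import left_shift_deletion, left_shift_insertion
from .core import Architecture, ArrayGeometry
from .indels import LocusSpec, spacer_center

__all__ = [
    "GenomeSpec",
    "IndelModel",
    "SimulatedRead",
    "TruthRecord",
    "make_genome",
    "make_locus",
    "simulate_reads",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class GenomeSpec:
    """Length, base composition and planted features of a synthetic genome."""

    length: int
    composition: Mapping[str, float] = field(
        default_factory=lambda: {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}
    )
    features: tuple[tuple[str, int, int], ...] = ()  # (motif, copies, start)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("genome length must be positive")
        if set(self.composition) - set("ACGT"):
            raise ValueError("composition keys must be A/C/G/T")
        if not math.isclose(sum(self.composition.values()), 1.0, abs_tol=1e-9):
            raise ValueError("composition probabilities must sum to 1")
        intervals = []
        for motif, copies, start in self.features:
            end = start + len(motif) * copies
            if start < 0 or end > self.length:
                raise ValueError(f"feature {motif}x{copies} out of bounds")
            intervals.append((start, end))
        intervals.sort()
        for (a0, b0), (a1, b1) in zip(intervals, intervals[1:]):
            if a1 < b0:
                raise ValueError("planted features overlap")


def make_genome(spec: GenomeSpec) -> str:
    """Reproducible random genome with planted motifs present verbatim."""
    rng = np.random.default_rng(spec.seed)
    probs = [self_p for self_p in (spec.composition.get(b, 0.0) for b in "ACGT")]
    seq = rng.choice(_BASES, size=spec.length, p=probs)
    for motif, copies, start in spec.features:
        block = np.array(list(motif.upper() * copies))
        seq[start : start + len(block)] = block
    return "".join(seq)


def make_locus(
    arch: Architecture,
    geom: ArrayGeometry,
    spacer_len: int,
    amplicon_len: int = 450,
    seed: int = 0,
    name: str = "locus",
) -> LocusSpec:
    """Random amplicon with one valid paired target planted at its center.

    T0 bases are forced at the positions the architecture's forward-bound
    layout requires; the rest of the amplicon is uniform random sequence.
    """
    L = geom.l_rec
    site = L + 1
    span = 2 * site + spacer_len
    if span + 2 > amplicon_len:
        raise ValueError("amplicon too short for the target footprint")
    rng = np.random.default_rng(seed)
    seq = rng.choice(_BASES, size=amplicon_len)
    start = (amplicon_len - span) // 2
    if arch.name == "TtT":
        seq[start] = "T"
        seq[start + span - 1] = "A"
    elif arch.name == "HtH":
        seq[start + L] = "A"
        seq[start + site + spacer_len] = "T"
    else:  # TtH, forward strand
        seq[start] = "T"
        seq[start + site + spacer_len] = "T"
    reference = "".join(seq)
    cut_offset = arch.left.cleavage_offset - (spacer_len + 1) / 2
    return LocusSpec(
        name=name,
        reference=reference,
        footprint_start=start,
        footprint_end=start + span,
        spacer_start=start + site,
        spacer_end=start + site + spacer_len,
        orientation="+",
        architecture=arch.name,
        cut_offset=cut_offset,
    )


@dataclass(frozen=True)
class IndelModel:
    """Parametric NHEJ indel model for amplicon read simulation.

    ``event_rate`` is the probability that a read carries an event;
    ``center_mean`` defaults to the locus' predicted cut offset in
    spacer-relative coordinates.  Deletion and insertion lengths are
    geometric with the stated means unless ``del_len_table`` (length,
    weight) pairs are given.
    """

    event_rate: float = 0.087
    p_ins: float = 0.3
    del_len_mean: float = 8.0
    del_len_table: tuple[tuple[int, float], ...] | None = None
    center_mean: float | None = None
    center_sd: float = 3.0
    ins_len_mean: float = 3.0
    sub_rate: float = 0.001

    def __post_init__(self) -> None:
        for p in (self.event_rate, self.p_ins, self.sub_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.del_len_mean < 1 or self.ins_len_mean < 1:
            raise ValueError("mean indel lengths must be >= 1")
        if self.center_sd < 0:
            raise ValueError("center_sd must be non-negative")
        if self.del_len_table is not None:
            if any(l < 1 for l, _ in self.del_len_table):
                raise ValueError("deletion lengths must be positive integers")
            if any(w < 0 for _, w in self.del_len_table):
                raise ValueError("deletion-length weights must be >= 0")


@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    sequence: str


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated read (indels left-normalised)."""

    read_id: str
    klass: str  # WT | INS | DEL
    del_start: int | None = None
    del_end: int | None = None
    ins_pos: int | None = None
    ins_seq: str | None = None
    center_true: float | None = None


def _sample_length(rng: np.random.Generator, mean: float,
                   table: tuple[tuple[int, float], ...] | None) -> int:
    if table is not None:
        lengths = np.array([l for l, _ in table])
        weights = np.array([w for _, w in table], dtype=float)
        return int(rng.choice(lengths, p=weights / weights.sum()))
    return int(rng.geometric(1.0 / mean))


def simulate_reads(
    locus: LocusSpec,
    model: IndelModel,
    n: int,
    seed: int = 0,
) -> tuple[list[SimulatedRead], list[TruthRecord], dict]:
    """Simulate ``n`` amplicon reads plus their truth table.

    Returns ``(reads, truth, stats)`` where ``stats['resampled']`` counts
    events re-drawn because a deletion would have crossed the amplicon
    boundary.  The single global seed fans out to independent per-
    component streams, so e.g. the event pattern is unchanged when only
    the substitution rate changes.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mu = model.center_mean
    if mu is None:
        if locus.cut_offset is None:
            raise ValueError(
                "model.center_mean is unset and the locus has no cut_offset"
            )
        mu = locus.cut_offset
    ref = locus.reference
    ref0 = locus.ref_zero
    sign = 1.0 if locus.orientation == "+" else -1.0
    streams = np.random.SeedSequence(seed).spawn(5)
    rng_event = np.random.default_rng(streams[0])
    rng_center = np.random.default_rng(streams[1])
    rng_len = np.random.default_rng(streams[2])
    rng_seq = np.random.default_rng(streams[3])
    rng_sub = np.random.default_rng(streams[4])

    reads: list[SimulatedRead] = []
    truth: list[TruthRecord] = []
    resampled = 0
    width = len(str(n))
    for idx in range(n):
        read_id = f"read{idx:0{width}d}"
        has_event = rng_event.random() < model.event_rate
        if not has_event:
            seq = ref
            rec = TruthRecord(read_id, "WT")
        elif rng_event.random() < model.p_ins:
            c = rng_center.normal(mu, model.center_sd)
            pos = int(round(ref0 + sign * c))
            pos = min(max(pos, 1), len(ref) - 1)
            length = _sample_length(rng_len, model.ins_len_mean, None)
            ins = "".join(rng_seq.choice(_BASES, size=length))
            seq = ref[:pos] + ins + ref[pos:]
            pos_c, ins_c = left_shift_insertion(ref, pos, ins)
            rec = TruthRecord(
                read_id, "INS", ins_pos=pos_c, ins_seq=ins_c,
                center_true=locus.to_spacer_coord(pos - 0.5),
            )
        else:
            for _ in range(100):
                c = rng_center.normal(mu, model.center_sd)
                length = _sample_length(
                    rng_len, model.del_len_mean, model.del_len_table
                )
                mid = ref0 + sign * c
                start_f = mid - (length - 1) / 2
                base = math.floor(start_f)
                start = base + (rng_len.random() < (start_f - base))
                end = start + length
                if 1 <= start and end <= len(ref) - 1:
                    break
                resampled += 1
            else:
                raise ValueError("deletion cannot fit inside the amplicon")
            seq = ref[:start] + ref[end:]
            a, b = left_shift_deletion(ref, start, end)
            rec = TruthRecord(
                read_id, "DEL", del_start=a, del_end=b,
                center_true=locus.to_spacer_coord((start + end - 1) / 2),
            )
        if model.sub_rate > 0:
            arr = np.array(list(seq))
            flips = np.flatnonzero(rng_sub.random(len(arr)) < model.sub_rate)
            for i in flips:
                choices = [b for b in "ACGT" if b != arr[i]]
                arr[i] = choices[rng_sub.integers(3)]
            seq = "".join(arr)
        reads.append(SimulatedRead(read_id, seq))
        truth.append(rec)
    return reads, truth, {"resampled": resampled}
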