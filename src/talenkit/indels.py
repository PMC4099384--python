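"""Amplicon-read indel classification and mutagenesis summaries.

Deep-sequenced amplicon reads spanning a nuclease target are aligned
globally to the reference locus; insertions and deletions intersecting an
analysis window around the paired-target footprint are called as NHEJ
events.  Reads are classed WT (no indel in the window -- substitutions
alone do not count), INS, DEL, or MIXED (at least one of each); a MIXED
read contributes once to the total event count and once to each of the
insertion and deletion tallies, the accounting convention under which
insertion + deletion counts may exceed total events.

Deletion positions are summarised in spacer-centered coordinates: spacer
bases are numbered 1..s from the left scaffold and coordinate 0 is placed
at base (s+1)/2 -- base 8 of a 15-bp spacer, base 13 of a 25-bp spacer.
A deletion's center is the midpoint of its deleted interval in these
coordinates, by default taken over the micro-homology equivalence range
of the deletion so that repeat-internal placement ambiguity does not bias
the estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .align import Alignment, Scoring, align_read, deletion_equivalence_range
from .core import PairedTarget, predicted_cut_center

__all__ = [
    "LocusSpec",
    "ReadClassification",
    "MutagenesisSummary",
    "DeletionCenterStats",
    "DeletionSizeDistribution",
    "classify_read",
    "classify_reads",
    "summarize",
    "summarize_counts",
    "format_percent",
    "spacer_center",
    "deletion_center",
    "deletion_size_distribution",
    "center_stats",
    "compare_centers",
]


def spacer_center(s: int) -> float:
    """Spacer base (1-based) chosen as coordinate 0: the (s+1)/2-th base.

    Odd spacers have a unique central base (8 for s = 15, 13 for s = 25);
    even spacers center between two bases (10.5 for s = 20).
    """
    if s < 1:
        raise ValueError("spacer length must be >= 1")
    c = (s + 1) / 2
    return int(c) if c.is_integer() else c


@dataclass(frozen=True)
class LocusSpec:
    """Reference amplicon plus its paired-target annotation.

    Coordinates are 0-based half-open on the amplicon.  ``orientation``
    is the bound strand of the target: ``-`` means the left scaffold
    binds at higher reference coordinates (reverse-strand TtH targets),
    flipping the sign convention of spacer-relative coordinates.
    ``cut_offset`` is the predicted cut center in spacer-relative
    coordinates, used as the default deletion-center mean by the read
    simulator.
    """

    name: str
    reference: str
    footprint_start: int
    footprint_end: int
    spacer_start: int
    spacer_end: int
    orientation: str = "+"
    architecture: str = "TtH"
    cut_offset: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.footprint_start <= self.spacer_start
                <= self.spacer_end <= self.footprint_end
                <= len(self.reference)):
            raise ValueError("locus intervals must nest within the amplicon")
        if self.orientation not in "+-":
            raise ValueError("orientation must be '+' or '-'")

    @property
    def spacer_len(self) -> int:
        return self.spacer_end - self.spacer_start

    @property
    def ref_zero(self) -> float:
        """Reference base-index coordinate of spacer-relative 0."""
        c = spacer_center(self.spacer_len)
        if self.orientation == "+":
            return self.spacer_start + c - 1
        return self.spacer_end - c

    def to_spacer_coord(self, ref_pos: float) -> float:
        """Map a reference base-index position to spacer-relative c."""
        if self.orientation == "+":
            return ref_pos - self.ref_zero
        return self.ref_zero - ref_pos

    @classmethod
    def from_target(cls, name: str, reference: str, target: PairedTarget
                    ) -> "LocusSpec":
        sp_start, sp_end = target.spacer_interval
        _, offset = predicted_cut_center(target)
        return cls(
            name=name,
            reference=reference,
            footprint_start=target.start,
            footprint_end=target.end,
            spacer_start=sp_start,
            spacer_end=sp_end,
            orientation=target.bound_strand,
            architecture=target.architecture.name,
            cut_offset=offset,
        )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "footprint_start": self.footprint_start,
            "footprint_end": self.footprint_end,
            "spacer_start": self.spacer_start,
            "spacer_end": self.spacer_end,
            "orientation": self.orientation,
            "architecture": self.architecture,
            "cut_offset": self.cut_offset,
        }


@dataclass(frozen=True)
class ReadClassification:
    """Per-read indel call within the locus analysis window."""

    read_id: str
    klass: str  # WT | INS | DEL | MIXED
    deletions: tuple[tuple[int, int], ...] = ()
    insertions: tuple[tuple[int, int], ...] = ()  # (ref pos, length)
    deletion_centers: tuple[float, ...] = ()

    @property
    def deletion_center(self) -> float | None:
        """Center of the first deletion event, if any."""
        return self.deletion_centers[0] if self.deletion_centers else None


def deletion_center(
    interval: tuple[int, int],
    locus: LocusSpec,
    homology_aware: bool = True,
) -> float:
    """Spacer-relative center c of a deleted reference interval.

    c is the midpoint of the deleted bases minus the spacer-center
    coordinate.  With ``homology_aware`` (default) the midpoint is taken
    over the full micro-homology equivalence range of the deletion, which
    is invariant to how the aligner placed the gap; with
    ``homology_aware=False`` the literal interval midpoint is used.
    """
    a, b = interval
    if homology_aware:
        lo, hi = deletion_equivalence_range(locus.reference, a, b)
        start_mid = (lo + hi) / 2
    else:
        start_mid = a
    midpoint = start_mid + (b - a - 1) / 2
    return locus.to_spacer_coord(midpoint)


def classify_read(
    alignment: Alignment,
    locus: LocusSpec,
    read_id: str = "read",
    margin: int = 30,
    homology_aware: bool = True,
) -> ReadClassification:
    """Call indels intersecting the analysis window (footprint +/- margin)."""
    lo = max(0, locus.footprint_start - margin)
    hi = min(len(locus.reference), locus.footprint_end + margin)
    dels = tuple(
        (a, b) for a, b in alignment.deletions if a < hi and b > lo
    )
    inss = tuple(
        (p, len(s)) for p, s in alignment.insertions if lo <= p <= hi
    )
    if dels and inss:
        klass = "MIXED"
    elif dels:
        klass = "DEL"
    elif inss:
        klass = "INS"
    else:
        klass = "WT"
    centers = tuple(
        deletion_center(d, locus, homology_aware) for d in dels
    )
    return ReadClassification(read_id, klass, dels, inss, centers)


def classify_reads(
    reads: Iterable[tuple[str, str]],
    locus: LocusSpec,
    scoring: Scoring = Scoring(),
    margin: int = 30,
    min_len_frac: float = 0.5,
    homology_aware: bool = True,
) -> tuple[list[ReadClassification], int]:
    """Align and classify a read set; short reads are discarded and counted.

    Returns ``(classifications, n_discarded)``.
    """
    out = []
    discarded = 0
    min_len = min_len_frac * len(locus.reference)
    for read_id, seq in reads:
        if len(seq) < min_len:
            discarded += 1
            continue
        aln = align_read(seq, locus.reference, scoring)
        out.append(classify_read(aln, locus, read_id, margin, homology_aware))
    return out, discarded


@dataclass(frozen=True)
class MutagenesisSummary:
    """Locus-level event accounting (deep-sequencing table schema)."""

    reads: int
    wt: int
    total_events: int
    n_ins: int
    n_del: int
    percent_events: float

    def formatted_percent(self) -> str:
        return format_percent(self.percent_events)

    def to_dict(self) -> dict:
        return {
            "reads": self.reads,
            "wt": self.wt,
            "total_events": self.total_events,
            "n_ins": self.n_ins,
            "n_del": self.n_del,
            "percent_events": self.percent_events,
            "percent_events_printed": self.formatted_percent(),
        }


def format_percent(pct: float) -> str:
    """Printed-style percentage: one decimal at >= 1%, two significant
    digits below 1%, bare "0" for exactly zero."""
    if pct == 0:
        return "0"
    if pct >= 1:
        return f"{pct:.1f}"
    return f"{pct:.2g}"


def summarize_counts(reads: int, wt: int, n_ins: int = 0, n_del: int = 0
                     ) -> MutagenesisSummary:
    """Summary from raw per-locus counts (reads, WT reads, per-class tallies)."""
    if reads <= 0:
        raise ValueError("cannot summarise a locus with zero reads")
    if wt > reads:
        raise ValueError("WT count exceeds read count")
    total = reads - wt
    return MutagenesisSummary(reads, wt, total, n_ins, n_del,
                              100.0 * total / reads)


def summarize(classifications: Sequence[ReadClassification]
              ) -> MutagenesisSummary:
    """Event accounting over classified reads.

    total events = reads - WT; a MIXED read counts once in the total and
    once in each of the insertion and deletion tallies.
    """
    reads = len(classifications)
    wt = sum(1 for c in classifications if c.klass == "WT")
    n_ins = sum(1 for c in classifications if c.insertions)
    n_del = sum(1 for c in classifications if c.deletions)
    return summarize_counts(reads, wt, n_ins, n_del)


@dataclass
class DeletionSizeDistribution:
    """Per-size relative frequencies of deletion lengths, across loci."""

    sizes: np.ndarray  # deletion sizes (or bin left edges)
    per_locus: dict[str, np.ndarray]
    mean: np.ndarray  # mean relative frequency across included loci
    sd: np.ndarray  # s.d. across loci (0 with a single locus)


def deletion_size_distribution(
    classifications: "Mapping[str, Sequence[ReadClassification]] | Sequence[ReadClassification]",
    bins: Sequence[int] | None = None,
    min_events: int = 20,
) -> DeletionSizeDistribution:
    """Relative deletion-size spectra, averaged across loci.

    ``classifications`` is either one locus' read list or a mapping of
    locus name to read list; loci with fewer than ``min_events`` deletion
    events are excluded.  Each locus' spectrum is normalised to unit sum;
    the cross-locus mean and s.d. are computed per size (or per bin when
    ``bins`` edges are given).
    """
    if not isinstance(classifications, Mapping):
        classifications = {"locus": classifications}
    sizes_by_locus: dict[str, list[int]] = {}
    for name, cls_list in classifications.items():
        lens = [b - a for c in cls_list for a, b in c.deletions]
        if len(lens) >= min_events:
            sizes_by_locus[name] = lens
    if not sizes_by_locus:
        raise ValueError(
            f"no locus reaches the {min_events}-event inclusion threshold"
        )
    if bins is None:
        max_size = max(max(v) for v in sizes_by_locus.values())
        sizes = np.arange(1, max_size + 1)
        edges = np.arange(0.5, max_size + 1.5)
    else:
        edges = np.asarray(bins, dtype=float)
        sizes = edges[:-1]
    per_locus = {}
    for name, lens in sizes_by_locus.items():
        hist, _ = np.histogram(lens, bins=edges)
        per_locus[name] = hist / hist.sum()
    table = np.vstack(list(per_locus.values()))
    sd = table.std(axis=0, ddof=1) if len(per_locus) > 1 else np.zeros(table.shape[1])
    return DeletionSizeDistribution(sizes, per_locus, table.mean(axis=0), sd)


@dataclass
class DeletionCenterStats:
    """Sample moments of deletion centers plus a unit-area Gaussian summary."""

    n: int
    mean: float
    variance: float  # sample variance (ddof = 1)

    def gaussian(self, x):
        """Unit-area normal density with the sample mean and variance."""
        return stats.norm.pdf(x, loc=self.mean, scale=math.sqrt(self.variance))


def _collect_centers(source) -> np.ndarray:
    vals = []
    for item in source:
        if isinstance(item, ReadClassification):
            vals.extend(item.deletion_centers)
        else:
            vals.append(float(item))
    return np.asarray(vals, dtype=float)


def center_stats(classifications_or_centers: Iterable) -> DeletionCenterStats:
    """Mean/variance of deletion centers (>= 2 centers required)."""
    centers = _collect_centers(classifications_or_centers)
    if centers.size < 2:
        raise ValueError("variance of deletion centers needs >= 2 events")
    return DeletionCenterStats(
        int(centers.size), float(centers.mean()), float(centers.var(ddof=1))
    )


def compare_centers(
    group_a: Iterable, group_b: Iterable, method: str = "student"
) -> tuple[float, float]:
    """Two-sided two-sample t-test of deletion-center location.

    ``student`` pools the variances (classical two-sample t); ``welch``
    drops the equal-variance assumption.
    """
    a = _collect_centers(group_a)
    b = _collect_centers(group_b)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 deletion centers")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("degenerate comparison: zero variance in both groups")
    res = stats.ttest_ind(a, b, equal_var=(method == "student"))
    return float(res.statistic), float(res.pvalue)
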