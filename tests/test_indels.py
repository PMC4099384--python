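"""Read alignment, indel classification and mutagenesis statistics."""

import math

import numpy as np
import pytest
from scipy import stats

from talenkit.align import (
    Scoring,
    align_read,
    deletion_equivalence_range,
    left_shift_deletion,
)
from talenkit.indels import (
    LocusSpec,
    ReadClassification,
    center_stats,
    classify_read,
    classify_reads,
    compare_centers,
    deletion_center,
    deletion_size_distribution,
    format_percent,
    spacer_center,
    summarize,
    summarize_counts,
)

from _oracles import oracle_align, pooled_t
from conftest import random_dna


# ---------------------------------------------------------------- alignment


def test_identity_alignment():
    ref = random_dna(np.random.default_rng(0), 80)
    aln = align_read(ref, ref)
    assert aln.score == 2 * len(ref)
    assert aln.deletions == () and aln.insertions == () and aln.n_subs == 0


def test_single_excision_recovered():
    rng = np.random.default_rng(1)
    ref = random_dna(rng, 120)
    read = ref[:50] + ref[55:]
    aln = align_read(read, ref)
    assert len(aln.deletions) == 1
    a, b = aln.deletions[0]
    assert b - a == 5
    # equivalent up to micro-homology shifts of the planted interval
    assert left_shift_deletion(ref, 50, 55) == (a, b)


def test_gap_left_normalisation_in_repeat():
    ref = "ACGTGGGGGACGT"
    read = "ACGTGGGGACGT"  # one G of the homopolymer removed
    aln = align_read(read, ref)
    assert aln.deletions == ((4, 5),)  # leftmost placement
    ref2 = "ACGCAGCAGCAGTTA"
    read2 = "ACGCAGCAGTTA"  # one CAG unit removed
    aln2 = align_read(read2, ref2)
    # leftmost equivalent placement shifts one base past the repeat frame
    assert aln2.deletions == ((2, 5),)


def test_substitutions_do_not_create_indels():
    rng = np.random.default_rng(2)
    ref = random_dna(rng, 100)
    read = ref[:40] + ("A" if ref[40] != "A" else "C") + ref[41:]
    aln = align_read(read, ref)
    assert aln.deletions == () and aln.insertions == ()
    assert aln.n_subs == 1
    assert aln.score == 2 * 99 - 4


def test_alignment_rejects_empty():
    with pytest.raises(ValueError):
        align_read("", "ACGT")


def test_alignment_matches_independent_dp_oracle():
    """Compiled aligner agrees with a plain-Python Gotoh on mutated reads."""
    rng = np.random.default_rng(3)
    for _ in range(25):
        ref = random_dna(rng, int(rng.integers(60, 160)))
        read = _mutate(ref, rng)
        aln = align_read(read, ref)
        score, dels, inss, subs = oracle_align(read, ref)
        assert aln.score == score
        assert aln.deletions == dels
        assert aln.insertions == inss
        assert aln.n_subs == subs


def _mutate(ref, rng, max_events=3):
    """Random reads with a few well-separated indels and substitutions."""
    read = ref
    offset = 0
    cuts = sorted(rng.choice(len(ref) - 20, size=rng.integers(1, max_events + 1),
                             replace=False))
    prev_end = -15
    for pos in cuts:
        if pos - prev_end < 12:
            continue
        kind = rng.integers(3)
        p = pos + offset
        if kind == 0:  # deletion
            ln = int(rng.integers(1, 9))
            read = read[: p] + read[p + ln :]
            offset -= ln
        elif kind == 1:  # insertion
            ins = random_dna(rng, int(rng.integers(1, 6)))
            read = read[: p] + ins + read[p:]
            offset += len(ins)
        else:  # substitution
            new = "ACGT"[(("ACGT".index(read[p])) + 1) % 4]
            read = read[: p] + new + read[p + 1 :]
        prev_end = pos + 10
    return read


def test_equivalence_range():
    ref = "ATAAAAGC"
    assert deletion_equivalence_range(ref, 2, 3) == (2, 5)  # any single A
    ref2 = "ACGTACGT"
    assert deletion_equivalence_range(ref2, 2, 4) == (2, 2)


# ------------------------------------------------------------ classification


def _locus(s=15, seed=4, flank=60):
    """Synthetic locus with spacer of length s, footprint of 2*17+s bp."""
    rng = np.random.default_rng(seed)
    site = 17
    span = 2 * site + s
    ref = random_dna(rng, 2 * flank + span)
    return LocusSpec(
        name="L",
        reference=ref,
        footprint_start=flank,
        footprint_end=flank + span,
        spacer_start=flank + site,
        spacer_end=flank + site + s,
        architecture="TtT",
        cut_offset=-0.5,
    )


def test_classify_wt_ins_del_mixed():
    locus = _locus()
    ref = locus.reference
    mid = locus.spacer_start + 7
    assert classify_read(align_read(ref, ref), locus).klass == "WT"
    ins_read = ref[:mid] + "TTT" + ref[mid:]
    assert classify_read(align_read(ins_read, ref), locus).klass == "INS"
    del_read = ref[:mid] + ref[mid + 4 :]
    assert classify_read(align_read(del_read, ref), locus).klass == "DEL"
    both = del_read[:40] + "GGCCA" + del_read[40:]
    c = classify_read(align_read(both, ref), locus)
    assert c.klass == "MIXED"
    assert len(c.deletions) == 1 and len(c.insertions) == 1


def test_mixed_reads_counted_in_both_tallies():
    cls = [
        ReadClassification("a", "WT"),
        ReadClassification("b", "INS", insertions=((5, 3),)),
        ReadClassification("c", "DEL", deletions=((5, 8),),
                           deletion_centers=(0.0,)),
        ReadClassification("d", "MIXED", deletions=((5, 8),),
                           insertions=((9, 1),), deletion_centers=(0.0,)),
    ]
    s = summarize(cls)
    assert (s.reads, s.wt, s.total_events) == (4, 1, 3)
    assert (s.n_ins, s.n_del) == (2, 2)
    assert s.n_ins + s.n_del > s.total_events
    assert s.percent_events == 75.0


def test_indels_outside_analysis_window_ignored():
    locus = _locus(flank=80)
    ref = locus.reference
    read = ref[:5] + ref[9:]  # 4-bp deletion far upstream of the footprint
    c = classify_read(align_read(read, ref), locus, margin=30)
    assert c.klass == "WT"
    c2 = classify_read(align_read(read, ref), locus, margin=100)
    assert c2.klass == "DEL"


def test_substitution_only_read_is_wt():
    locus = _locus()
    ref = locus.reference
    mid = locus.spacer_start + 7
    read = ref[:mid] + ("G" if ref[mid] != "G" else "T") + ref[mid + 1 :]
    assert classify_read(align_read(read, ref), locus).klass == "WT"


def test_short_reads_discarded_and_counted():
    locus = _locus()
    reads = [("ok", locus.reference), ("short", locus.reference[:30])]
    cls, discarded = classify_reads(reads, locus)
    assert len(cls) == 1 and discarded == 1


# ----------------------------------------------------------------- summaries


@pytest.mark.parametrize(
    "reads,wt,total,printed",
    [
        (10731, 10538, 193, "1.8"),
        (2280, 2221, 59, "2.6"),
        (5276, 4817, 459, "8.7"),
        (5879, 4088, 1791, "30.5"),
        (6131, 6129, 2, "0.033"),
        (100, 100, 0, "0"),
    ],
)
def test_summary_accounting_and_printed_precision(reads, wt, total, printed):
    s = summarize_counts(reads, wt)
    assert s.total_events == total == reads - wt
    assert 0.0 <= s.percent_events <= 100.0
    assert s.formatted_percent() == printed


def test_summarize_zero_reads_flagged():
    with pytest.raises(ValueError):
        summarize_counts(0, 0)


def test_format_percent_regimes():
    assert format_percent(8.7004) == "8.7"
    assert format_percent(0.0511) == "0.051"
    assert format_percent(1.0) == "1.0"


# -------------------------------------------------------- spacer coordinates


@pytest.mark.parametrize("s,expected", [(15, 8), (25, 13), (20, 10.5), (1, 1)])
def test_spacer_center_convention(s, expected):
    assert spacer_center(s) == expected


def test_deletion_center_examples():
    locus = _locus(s=15)
    sp = locus.spacer_start
    # spacer bases 4..11 (1-based) -> reference [sp+3, sp+11)
    c = deletion_center((sp + 3, sp + 11), locus, homology_aware=False)
    assert c == -0.5
    # symmetric deletion about the center base 8 -> c = 0
    assert deletion_center((sp + 5, sp + 10), locus, homology_aware=False) == 0
    # single-base deletion at spacer base 8
    assert deletion_center((sp + 7, sp + 8), locus, homology_aware=False) == 0


def test_deletion_center_orientation_flip():
    base = _locus(s=15)
    flipped = LocusSpec(
        name="L", reference=base.reference,
        footprint_start=base.footprint_start,
        footprint_end=base.footprint_end,
        spacer_start=base.spacer_start, spacer_end=base.spacer_end,
        orientation="-", architecture="TtH",
    )
    sp = base.spacer_start
    c_fwd = deletion_center((sp + 3, sp + 11), base, homology_aware=False)
    c_rev = deletion_center((sp + 3, sp + 11), flipped, homology_aware=False)
    # odd spacer: coordinate 0 is the same physical base on both strands
    assert c_rev == -c_fwd


def test_homology_aware_center_is_shift_invariant():
    """All equivalent placements of a deletion get the same center."""
    locus = _locus(s=15, seed=9)
    ref = locus.reference
    sp = locus.spacer_start
    a, b = sp + 4, sp + 9
    lo, hi = deletion_equivalence_range(ref, a, b)
    centers = {
        deletion_center((x, x + (b - a)), locus) for x in range(lo, hi + 1)
    }
    assert len(centers) == 1


# -------------------------------------------------------------- distributions


def _del_read(klass="DEL", length=5, start=100):
    return ReadClassification(
        "r", klass, deletions=((start, start + length),),
        deletion_centers=(0.0,),
    )


def test_size_distribution_point_mass():
    cls = [_del_read(length=5) for _ in range(25)]
    d = deletion_size_distribution(cls, min_events=20)
    assert d.mean[d.sizes == 5] == 1.0
    assert d.mean.sum() == pytest.approx(1.0)


def test_size_distribution_small_deletion_fraction():
    cls = [_del_read(length=4) for _ in range(80)]
    cls += [_del_read(length=30) for _ in range(20)]
    d = deletion_size_distribution(cls)
    assert d.mean[d.sizes < 20].sum() == pytest.approx(0.8)


def test_size_distribution_inclusion_threshold():
    few = [_del_read() for _ in range(5)]
    many = [_del_read(length=7) for _ in range(30)]
    d = deletion_size_distribution({"A": few, "B": many}, min_events=20)
    assert list(d.per_locus) == ["B"]
    with pytest.raises(ValueError):
        deletion_size_distribution({"A": few}, min_events=20)


def test_size_distribution_recovers_geometric_lengths():
    rng = np.random.default_rng(12)
    lengths = rng.geometric(1 / 8, size=4000)
    cls = [_del_read(length=int(l)) for l in lengths]
    d = deletion_size_distribution(cls)
    expected = stats.geom.pmf(d.sizes, 1 / 8)
    assert np.abs(d.mean - expected).max() < 0.02


# ------------------------------------------------------------- center stats


def test_center_stats_moments_and_unit_area():
    s = center_stats([-1.0, 1.0])
    assert (s.n, s.mean, s.variance) == (2, 0.0, 2.0)
    from scipy.integrate import quad
    area, _ = quad(s.gaussian, -30, 30)
    assert area == pytest.approx(1.0, abs=1e-8)


def test_center_stats_needs_two_events():
    with pytest.raises(ValueError):
        center_stats([0.5])


def test_center_stats_accepts_classifications():
    cls = [_del_read(), _del_read()]
    assert center_stats(cls).n == 2


def test_compare_centers_identical_groups():
    g = [-1.0, 0.0, 1.0, 2.0]
    t, p = compare_centers(g, list(g))
    assert t == 0.0 and p == pytest.approx(1.0)


def test_compare_centers_matches_pooled_oracle():
    a = [1.1, 2.3, 3.2, 4.8, 5.0, 2.2]
    b = [2.0, 4.1, 6.3, 8.8, 10.1]
    t, p = compare_centers(a, b)
    t_oracle, df = pooled_t(a, b)
    assert t == pytest.approx(t_oracle, rel=1e-12)
    assert p == pytest.approx(2 * stats.t.sf(abs(t_oracle), df), rel=1e-12)


def test_compare_centers_welch_differs_under_unequal_variance():
    rng = np.random.default_rng(13)
    a = rng.normal(0, 1, 30)
    b = rng.normal(0.5, 6, 10)
    t_s, p_s = compare_centers(a, b, method="student")
    t_w, p_w = compare_centers(a, b, method="welch")
    assert p_s != p_w


def test_compare_centers_degenerate_flagged():
    with pytest.raises(ValueError):
        compare_centers([1.0, 1.0], [1.0, 1.0])


def test_shift_detection_power():
    """A -2.5 bp center shift (sd 5, n=200/group) is detected at the 1%
    level in the vast majority of replicates."""
    rng = np.random.default_rng(14)
    hits = 0
    for _ in range(100):
        a = rng.normal(-2.5, 5, 200)
        b = rng.normal(0.0, 5, 200)
        _, p = compare_centers(a, b)
        hits += p < 0.01
    assert hits > 90
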