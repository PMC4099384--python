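# Methods

## Geometric model of paired TALE–FokI nucleases

A binding site is modelled as a T0 thymine plus `L` recognised bases
read 5′→3′ on the bound strand; an array of `n + 0.5` repeats reads
`n + 1` bases (the half-repeat reads one), so the default 15.5-repeat
array has `L = 16` and a 17-bp footprint. Coordinates are 0-based
half-open on the forward reference strand throughout; reverse-strand
sites are stored in forward coordinates with a strand flag (T0 is then
the reference `A` at the footprint's right edge). This interoperates
directly with BED.

The three pair layouts are encoded as forward-strand footprint patterns:

* **TtT** — `T·seqL · spacer · revcomp(T·seqR)`: sites on opposite
  strands, T0s distal to the spacer.
* **HtH** — `revcomp(T·seqL) · spacer · T·seqR`: sites on opposite
  strands, T0s immediately flanking the spacer.
* **TtH** — `T·seqL · spacer · T·seqR` on one strand (scanned on both
  orientations; on the reverse strand the tail site sits at higher
  reference coordinates).

Each scaffold carries a cleavage offset, the distance in bp from the
spacer-proximal edge of its site to the expected cut center. The
defaults, 7.5 bp (TALE::FokI) and 12.5 bp (FokI::TALE), are the unique
half-integer pair whose pairwise sums reproduce all three observed
spacer optima (15, 20, 25 bp); they are configuration values
(`data/presets.yaml`), not hard-coded constants. The predicted optimal
spacer of a pair is the sum of its two offsets, which makes the TtH
optimum exactly the mean of the TtT and HtH optima.

**Cut-center convention.** Spacer bases are numbered 1..s from the left
scaffold and spacer-relative coordinate 0 is placed at base `(s+1)/2`
(a half-integer between the two central bases when s is even). The cut
center sits at spacer coordinate `o_left`, i.e. at offset
`o_left − (s+1)/2` from the center: −0.5 for symmetric layouts at odd
s, and `(o_left − o_right)/2 − 0.5` at any layout's optimal spacer
(−3.0 for TtH at s = 20).

**Spacer windows.** Two window presets ship: `results` (TtT 10–27, HtH
22–27, TtH 18–22 ∪ 27–33), the activity windows observed in a
surrogate-reporter assay, and `chr1-scan` (TtT 10–16 ∪ 20–25, TtH 17–23
∪ 26–33, HtH unchanged), an alternative set quoted for chromosome-scale
targetability scanning. Neither is privileged; `results` is the
default. Note the admissible spacer-length counts of these windows
(18/6/12 for TtT/HtH/TtH) do not equal the 25/8/16 counts quoted in the
off-site-target fold argument, which were read off activity-profile
figures at an unstated threshold; `offtarget_ratio` works on whatever
counts it is given, and the discrepancy is left documented rather than
resolved.

## Target scanning and coverage

Enumeration is exhaustive: every (position, spacer) combination whose
T0s, site validity and window membership fit the layout is reported,
including overlapping, nested and palindromic self-pairs (a
`require_distinct_sites` flag drops the latter). "Targetable" is defined
at base resolution by footprint membership, not cut-site position, so
target-devoid regions are maximal runs of bases intersecting no
footprint, and per-architecture coverage breakdowns allow set queries
such as "TtT-devoid but TtH-covered". Scanning is vectorised (numpy
boolean masks plus cumulative-sum validity windows) and can run windowed
with an overlap of one maximal footprint span minus one, which is
provably equivalent to the whole-sequence scan. Lowercase (soft-masked)
bases are treated as ordinary bases unless `respect_mask` is set;
ambiguous bases never satisfy T0 and never match.

## Off-site enumeration

Half-site matching is Hamming distance over the recognised bases with an
exact-T0 requirement (the T0 anchor is a specificity feature, so a non-T
there disqualifies a site rather than costing one mismatch). No
position-dependent weighting is applied — nothing in the underlying data
supports one. Candidate off-sites combine half-site hits in all three
monomer combinations (L+R, L+L, R+R); the pair layout is forced by the
two scaffold kinds (two tails → TtT, two heads → HtH, mixed → TtH)
because FokI dimerisation constrains geometry, not sequence identity,
and each combination is screened against that layout's spacer windows.
With uniform admissibility the expected hit count is proportional to the
number of admissible spacer lengths, which is the basis of the
architecture fold-difference argument and is verified on random
synthetic genomes in the test suite.

## Read alignment and indel calling

Reads are aligned globally (Gotoh three-state affine DP, numba-compiled)
with match +2, mismatch −4, gap open −10, gap extend −1; a gap of length
ℓ costs `open + (ℓ−1)·extend`. Ties are broken deterministically
(diagonal > deletion > insertion, applied uniformly in every state and
at the final cell) and every indel is then shifted to its leftmost
equivalent placement without crossing a neighbouring indel, so identical
molecules always produce identical coordinates. A global — not local —
alignment is used because simulated and real amplicon reads span the
whole PCR product. Reads shorter than half the amplicon (configurable)
are discarded and counted.

Indels are called inside an analysis window of the target footprint
± 30 bp (configurable); indels entirely outside it are ignored as a
sequencing-noise guard, and substitutions never affect the class. Read
classes are WT / INS / DEL / MIXED; a MIXED read contributes once to
total events and once to each of the insertion and deletion tallies —
the only convention under which per-class counts may exceed total
events, as they do in the published locus table. Percentages are kept
at full precision internally; the printed-style formatter uses one
decimal at ≥ 1% and two significant digits below 1%.

**Deletion centers.** A deletion's center is its midpoint in
spacer-relative coordinates. Because an indel inside a repeat is
positionally ambiguous, the midpoint is taken by default over the full
micro-homology equivalence range of the deletion: the leftmost
placement alone is biased left by the expected flank-homology run
(≈ 0.33 bp in uniform random sequence), whereas the range midpoint is
unbiased and invariant to how the aligner placed the gap.
`homology_aware=False` restores the literal interval midpoint.
Multi-deletion reads contribute one center per deletion event.

Deletion-size spectra are per-locus relative frequencies (unit sum) with
a ≥ 20-event inclusion threshold by default, averaged across loci with a
cross-locus s.d. Center summaries report sample mean and variance
(ddof 1) plus a unit-area Gaussian with those moments; group comparisons
use the two-sided pooled-variance Student t by default, Welch optionally
(scipy implementations, validated in-tree against the closed form).
Degenerate inputs — zero reads, fewer than two centers, zero variance in
both groups — raise instead of returning silent NaNs.

## Synthetic data

The genome generator draws i.i.d. bases from a configurable composition
and plants motifs (e.g. `(CAG, 50, pos)`) verbatim, rejecting
out-of-bounds or overlapping features. The read simulator emulates
deep-sequenced amplicons over one locus: a read carries an event with
probability `event_rate` (default 0.087, the scale of a
mid-activity locus in the published table), an insertion with
probability `p_ins = 0.3` given an event (the approximate insertion
share of the published event counts), else a deletion. Deletion lengths
are geometric with mean 8 bp by default (consistent with the observed
predominance of deletions < 20 bp; an empirical length table can be
substituted), insertion lengths geometric with mean 3 bp, and the
substitution error rate defaults to 0.001/bp. Deletion centers are
normal around the locus's predicted cut offset (sd 3 bp by default); the
deletion is laid out symmetrically about the sampled center with the
fractional start resolved by stochastic rounding, so the planted
midpoint is unbiased for the sampled center under the analyzer's
midpoint definition. Deletions that would cross the amplicon boundary
are resampled and counted. A single seed fans out (`SeedSequence.spawn`)
to independent event/center/length/sequence/error streams, so
e.g. changing only the substitution rate leaves the event pattern
untouched. The default amplicon is 450 bp, inside the 370–630 bp range
of the real locus PCRs.

What the simulator does **not** model: platform-specific error profiles
(e.g. pyrosequencing homopolymer errors), PCR chimeras or UMI structure,
micro-homology-directed deletion preferences, and translocations or
large structural variants. Passing recovery tests therefore demonstrate
that the analysis is correct and unbiased under a clean NHEJ indel
model, not that it is robust to every artefact of real sequencing data.

## Problem sizes and numerical choices

The shipped test suite runs the scanners against brute-force oracles on
200 random sequences ≤ 500 bp and 100 random 10-kb sequences, the
aligner against an independent pure-Python DP on 100 mutated reads
≤ 300 bp, and parameter recovery on 5000 simulated 450-bp reads (event
rate 0.087, center mean −3.0, sd 3.0) — recovering the rate within the
99% binomial interval and the center mean within three standard errors.
These sizes give stable, seed-robust checks while keeping the whole
suite around a minute on one CPU. All randomness is seeded; the
alignment kernel is integer-valued so scores are exact, and the only
floating-point comparisons are on sample moments with explicit
tolerances.

## Known limitations

* The cleavage-offset defaults are inferred from three printed optima;
  they are not fitted to activity profiles, and real optima vary with
  linker composition and scaffold truncation, which are outside scope.
* Chromosome-scale targetability figures (e.g. the 99.8%/2945-region
  chromosome-1 estimate) depend on genome build and masking choices that
  are not reproducible here; the scanner supports the computation but no
  specific published number is asserted.
* Off-site enumeration is combinatorial, not thermodynamic: no binding
  affinity, chromatin or RVD-composition effects.
* Protein-level modelling (linkers, FokI dimer interface,
  obligate-heterodimer variants) is explicitly out of scope.
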