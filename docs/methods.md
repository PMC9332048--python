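# Methods

## Scope and data model

`ppscan` discovers promoter classes from the fixed windows around annotated
gene starts and scans genomes for further statistically significant matches
(potential promoter sequences, PPSs). The annotated gene start is used as a
proxy for the transcription start site throughout; the promoter window is
500 nt upstream plus 100 nt downstream, stored renumbered 1..600 reading
5'→3' toward the gene, so window column 501 is the annotated +1. Windows
that would leave the chromosome are dropped, not clipped, because every
downstream matrix requires the fixed length. Internally all coordinates are
0-based half-open; everything user-facing (TSV, GFF3, truth tables) is
1-based inclusive, with BED output converted at the boundary.

The window is nominally −499..+100 (599 positions); we resolve the
off-by-one by taking exactly 500 + 100 = 600 columns with the annotated
start at column 501, which puts the observed conservation peak where it is
expected, a few columns upstream of the start.

## Filters

Four per-window rules clean the raw promoter set: each base ≤ 60% of the
window; at most one N; no homopolymer run longer than m0 = {A: 13, T: 12,
C: 5, G: 5}; GC fraction within [0.29, 0.37] (the band observed in
reference plant promoter sets). Base and GC fractions use the full window
length as denominator — with ≤ 1 N the difference from an N-excluded
denominator is negligible — and N runs never count toward any base's m0.
`derive_run_thresholds` re-derives m0 from any reference promoter set given
per-base probability cutoffs: m0(u) is the smallest m such that the
fraction of reference sequences containing a run of u longer than m falls
below the cutoff. The cutoffs are treated as inputs; whether the historical
values (4.24%, 3.65%, 1.11%, 0.76%) were targets or outcomes cannot be
reconstructed, and nothing downstream depends on that choice.

## Dinucleotide PWMs

Base codes are {A:1, T:2, C:3, G:4}; the ordered pair at columns (j−1, j)
has index s = v(j−1) + 4(v(j) − 1) ∈ 1..16, so a length-L1 alignment has
L1 − 1 informative columns (j = 2..L1). Pairs containing a gap or N are
skipped. The raw weight standardizes each count against its binomial
expectation under the pooled dinucleotide background p(i) = Y(i)/K. A
dinucleotide that never occurs would make the weight undefined; in that
case add-one smoothing is applied to the marginals Y(i) (and only in that
case, so exact-expectation inputs keep weight exactly 0). Empty columns
(no counts) get weight 0 and are flagged.

The normalization transform is center-then-scale: W = α(PWM' − κ) with
κ = K_d(PWM') and α chosen so that R² = Σ W² = 75·L1. K_d uses p1 = the
matrix's background distribution and p2 = uniform over informative columns;
both sum to 1, which is exactly what makes the centering zero K_d, and any
transform satisfying the two constraints would be equivalent for scoring.
The constant 75 is adopted as given — it only fixes the common scale. The
transform is scale-invariant and idempotent; exactly constant matrices are
rejected (no spread to rescale), detected with a relative floor so that
round-off cannot masquerade as signal.

The conservation profile is X(j) = sqrt(2 Σᵢ PWM'(i,j)²) − sqrt(2n − 1)
with n = 9 degrees of freedom (adopted as a fixed constant). For background
columns X is approximately standard normal, so |X| > 3–4 marks non-random
dinucleotide usage.

## Alignment

Sequence-vs-PWM alignment pairs the sequence's dinucleotide positions
t = 2..len (the pair ending at base t) with matrix columns l = 2..L1,
scoring pwm(s(t), l). The dinucleotide of a position is computed from the
actual sequence — after a gap, the first matched position still uses its
real left neighbor — so scores are a pure function of the sequence, not of
the gap pattern. Gaps are linear; the default penalty d_seq = 20 mirrors
the only penalty the procedure specifies elsewhere (the matrix–matrix
alignment) and is configurable, since the sequence-vs-PWM penalty is
otherwise unconstrained. Global alignment consumes both the sequence and
the matrix end-to-end (F_max at the terminal cell); local alignment is
Smith–Waterman-style with a zero floor (E_max), with window positions
containing N scoring 0. The kernels are numba-compiled; a start-propagating
variant returns local endpoints without a full traceback for the scan's
inner loop, and tracebacks (CIGAR M/I/D strings) are recomputed only for
reported records.

## Null models and Z scores

Every score is studentized against a Monte-Carlo shuffle null. Class
membership shuffles the scored window itself (mononucleotide permutation,
n = 1000 by default) and uses Z = (F_max − mean)/sd with threshold 5.0.
The genome scan estimates one null per (class, chromosome): the chromosome
is mono-shuffled once and E_max is sampled on non-overlapping windows
(independence of samples); the threshold is Z ≥ 6.0. Pair- and
triplet-token shuffles (window 600, stride 300, tokens permuted within each
window) preserve short-range composition and serve as harder controls, not
as the null. All randomness flows from one master seed; derived seeds are
recorded in the null-model cache.

A property worth knowing: scoring a sequence against a PWM whose counts
include that sequence inflates Z by roughly 5 at a fully-sampled pool of
200 sequences, 1.6 at 1000 (measured on iid pools). At realistic pool
sizes (thousands of windows, 1000 sampled) this bias is what produces the
small but nonzero random-control class volumes (~tens), and the
minimum-class-volume threshold of 100 is calibrated against exactly that
noise floor. At very small desk-scale pools the bias can push a leftover
homogeneous pool over the membership threshold wholesale, so the final
iteration of class building may emit one trailing background-only class;
see "Synthetic benchmark" below.

## Class building

Each round samples min(1000, remaining) windows and aligns them with a
small genetic algorithm over alignment layouts: an individual is a set of
per-sequence match traces (initially the gapless 600-column stack, which is
already column-consistent because all windows are anchored on the annotated
start); operators are all-gap column insertion/deletion (L1 may grow to
650, matching the scan window slack), an EM-like re-alignment of every
sequence to the PWM rebuilt from the mutated layout, and elitist selection;
fitness is the summed global score of the sample against the layout's PWM,
which is non-decreasing across accepted generations. The GA stops when the
fitness gain stays below 1e-3 for `patience` generations or at the
generation cap. Defaults are population 20 / 200 generations; the test
suite and examples run reduced settings (population 3–4, 4–6 generations),
which suffices because the gapless initial layout is already near-optimal
for anchored windows — the GA's role there is refinement, and fitness
plateaus within a few generations.

Every remaining window (sampled or not) is then scored against the
candidate PWM; windows with Z > 5 form the class and leave the pool, and
the loop stops when a candidate has fewer than 100 members. Classes are
disjoint by construction and numbered in creation order.

## Genome scan

Windows of L1 + 50 nt slide with a configurable stride (default 1; the
benchmark uses 100 — see problem sizes). Windows with more than 10% N are
skipped. Per class, the per-window best local alignments are reduced to
non-intersecting local maxima by greedy selection in descending E_max;
survivors with Z ≥ 6 become candidates carrying their chromosome interval,
matrix interval, and trace. Cross-class conflicts are resolved iteratively:
any pair overlapping by more than 10% of the shorter record keeps the
larger Z (ties: lower class id, then leftmost — the procedure is silent on
ties and this makes it deterministic). Strand handling is explicit: forward
and reverse-complement scans cover the two biological strands, and
complement-only / reverse-only transforms are mirror controls; all
coordinates map back to the forward frame.

Feature intersection reports overlap length, fraction, and a strand-pair
label (++, −−, +−, −+). The fraction's denominator is a mode switch:
`of_feature` (the SINE-style rule: fraction of the feature covered),
`of_record`, or `of_min` (the annotated-promoter-style rule; default).

## Class clustering

Classes are compared through their frequency matrices by Needleman–Wunsch
over columns with match weight w(i,j) = (1/4) Σₖ (S − |mⁿᵢₖ − mᵠⱼₖ|)/σ,
where S and σ are the mean and sd of the element-wise absolute difference
under random column pairing, estimated by Monte Carlo (1000 pairings). The
estimator is content-addressed — seeded by the unordered pair of matrix
digests plus the configured seed — so distances are exactly symmetric and
exactly zero for duplicated matrices. The published recurrence contains an
obvious typo (the same cell on both sides); the standard three-way
recurrence max(F(i,j−1)−d, F(i−1,j)−d, F(i−1,j−1)+w) is used. The distance
D = (min(Fnn, Fqq) − Fnq)/min(Fnn, Fqq) adopts the linear reading of the
published formula (whose trailing exponent is ambiguous): it maps D into
[0,1] for non-negative cross-similarity and reproduces the >0.9 control
distances; the squared-denominator reading remains available behind a
flag. Complete linkage uses scipy; groups are read at association level
0.8, calibrated by row-shuffled controls, and the dendrogram is exported
as Newick.

## Transcript support

The pooled two-proportion statistic U (no continuity correction, two-sided
decision at z₁₋α/₂) compares supported fractions between predicted PPSs and
random positions. For the reference counts (31/1000 vs 17/1000) the formula
evaluates to U = 2.0454; note that the historically quoted 2.07 for these
counts is only reproducible by pooling over the wrong total (48/1000
instead of 48/2000 inside the variance factor), so this package reports
2.05. The decision (reject at α = 0.05, critical 1.96) is unaffected.

## Synthetic benchmark

The generator emulates the structure the pipeline assumes: an iid
background genome (A/T 0.335, C/G 0.165 each, GC ≈ 0.33 — inside the
filter band), genes with annotated starts on both strands, and planted
promoter classes, each defined by a consensus plus per-column emission
sharpness, with a strongly conserved core at columns 491–515 to mimic the
real conservation peak, 15% per-member substitution noise, and intergenic
decoy instances that are planted but never annotated. Members are
composition-controlled (resampled until they pass all four filters), so
clean planted promoters are never rejected downstream. The background is
order-0 by default: a uniformly autocorrelated background is itself a
genome-wide shared dinucleotide signal relative to the mono-shuffle null
and would make every window weakly significant; an order-1 copy probability
remains available (`markov_rho`) for studying exactly that effect.

Class sharpness defaults are graded (0.55 / 0.30 / 0.19 for the 600 / 300 /
150-member classes): real promoter classes differ in conservation, with the
largest class the most conserved, and the grading keeps each class dominant
in the round in which it is discovered. This matters because membership Z
against a *blended* first-round matrix scales with a class's share of the
sample: with equal sharpness, a 24%-share class sits almost exactly at the
Z = 5 membership threshold, and discovery degenerates into merged or
fragmented classes for any single sharpness value.

What passing benchmark tests shows: the procedure separates classes whose
conservation hierarchy matches their abundance hierarchy, in an iid
background, with composition-matched members. What it does not show:
robustness to repeat families, autocorrelated background, overlapping or
nested classes, or classes whose conservation is uncorrelated with
abundance — real genomes contain all four. The trailing background-only
class discussed under "Null models" appears in the benchmark because the
leftover pool (200 background windows) is small and fully sampled; at
realistic pool sizes the same bias yields control volumes well under the
acceptance threshold and the loop terminates cleanly.

## Problem sizes and numerical choices

The benchmark genome is ~1.2 Mb (1250 genes plus 60 decoys); class
discovery uses sample size 1000, 40 shuffles per membership Z, and reduced
GA settings; scans use stride 100 and 150 null windows per class, sizes at
which the planted-recovery and calibration checks are comfortably resolved.
Tolerances: the normalization contract is asserted at 1e-9 relative; exact
DP equivalence is asserted against enumeration oracles at float tolerance;
degenerate inputs (all-N chromosomes, constant matrices, zero-variance
nulls) raise errors rather than returning silently. Determinism: every
stochastic component takes a seed or Generator; the CLI derives per-stage
seeds from the master seed by hashing the stage name.

## Known limitations

- The GA explores layouts only through column indels plus EM re-alignment;
  it cannot discover alignments far from the anchored initialization (for
  anchored promoter windows this is by design, not a restriction that
  matters).
- Null means and variances are estimated, not analytic; extreme-value
  (Gumbel) calibration of local scores is out of scope.
- The scan is O(genome × classes × L1² / stride); stride 1 on gigabase
  genomes requires either patience or banding, neither of which is
  included.
- Class membership scoring includes the scored sequence's own contribution
  to the sample matrix (faithful to the reference procedure); the resulting
  small-pool bias is documented above rather than corrected.
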