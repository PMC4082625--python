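# Methods

This note records the models, conventions and numerical choices behind
`synrec`, and what the synthetic-data tests do and do not establish about
real data.

## Coordinates and containers

All genomic intervals are 0-based half-open internally (BED convention);
1-based inclusive coordinates appear only in human-readable report tables,
converted in one place (`io.to_report_coords`). Ortholog tables and gene
tables are pandas DataFrames with fixed column sets; assemblies are
chromosome-length dictionaries plus N-run (assembly gap) intervals, which
the synthetic genomes use to mark centromeres (default N-run 500 Kbp).

## Synteny-block chaining

Blocks are maximal runs of reference-sorted markers satisfying, pairwise in
sequence: same chromosome pair; same strand relation as the block's first
marker; target order strictly ascending when strands agree and strictly
descending when they are flipped (so a block's orientation is fixed by its
first two markers and any later contradiction closes it); and a reference
inter-marker distance of at most `max_marker_gap_bp`.

* `min_markers` defaults to 2: a single out-of-order marker cannot found a
  block, which keeps isolated noise markers from fragmenting detection.
* `max_marker_gap_bp` defaults to 4 Mbp, the same constant as the gap rule
  for breakpoint candidates — one knob, one semantics.
* The gap rule is applied to the **reference** distance only. A deleted or
  inserted segment leaves a gap on exactly one genome; applying the rule to
  both genomes would break the chain in both reference directions and
  produce a phantom breakpoint on the genome that has no rearrangement.
  With the reference-side rule an indel surfaces as an EBR only in the
  direction whose reference carries the extra sequence, which is how such
  events present in real pairwise comparisons. Consequence: an indel
  smaller than `max_marker_gap_bp` is invisible; detecting sub-megabase
  indels requires lowering the gap parameter.
* Block intervals are marker hulls (first marker start to last marker end).
  In pathological nested transpositions two blocks' target hulls can
  overlap; detection does not attempt to arbitrate these (documented
  limitation — the classification stage types them `complex`).

EBRs are the inter-block intervals per chromosome; intervals over 4 Mbp are
labelled `gap` and excluded downstream. Terminal intervals (chromosome end
to first/last block) are not EBRs. Narrowing tightens an EBR to the
innermost coordinates of its flanking blocks' markers and never widens; an
EBR with a missing flank is returned unchanged and flagged.

## Merging, masks, classification

Two detectors' EBR sets are reconciled by **intersection** of overlapping
calls (≥ 1 bp), the narrower consensus; union is available as an option.
Masks are the 2 Mbp at each chromosome end (telomeric) and 2 Mbp on each
side of every N-run, N-run included (centromeric); any overlap with a mask
excludes an EBR — deliberately conservative, trading sensitivity near
heterochromatin for a low false-positive rate. Chromosomes shorter than
4 Mbp are entirely telomeric.

Classification reads the flanking-block geometry of each retained EBR:
an inverted block bracketed by two same-chromosome EBRs is an inversion
(rearranged region = the inverted span between the inner EBR edges); a
chromosome-pair change across the EBR is a fission, fusion or translocation
according to whether the target genome has more, fewer or equally many
chromosomes; collinear flanks (same pair, same orientation) mean the EBR
spans sequence present in one genome only — an indel; anything else,
including missing flanks, is complex. Size classes follow the 1.4-Mbp rule
(macro strictly above; the equality case is micro). For fusion / fission /
translocation the rearranged region is taken as the span of the moved
(distal) block, since those events relocate a whole block rather than a
bounded interval.

## Tandem repeats and windows

The repeat finder calls **exact** tandem repeats: for each period k in
[2, 100], maximal runs of positions matching k positions back, trimmed to
whole copies, reported when ≥ 2 complete copies. `N` never matches and
terminates runs. Overlapping calls across periods are resolved
deterministically — longest span wins, ties to the smallest period, then
leftmost — so homopolymers surface at the smallest admissible period
(motif `AA` under the default minimum of 2) and every call carries the
lexicographically least rotation of its unit as canonical motif. Mismatch
tolerance (as in score-thresholded repeat finders) is not implemented; this
undercounts diverged repeats and is a known limitation.

Windows are non-overlapping 100-Kbp bins per chromosome, the last one
short but retained. Repeat base pairs are clipped to the window (a repeat
spanning a boundary is split, so per-chromosome sums are conserved); genes
are counted by any-overlap (presence/absence), so a boundary-spanning gene
counts in each window it touches. Window labels follow the precedence
telomere > centromere > EBR > HSB by any-overlap; unlabelled windows are
excluded from comparisons. Kruskal–Wallis is used for more than two region
classes, Mann–Whitney U for two.

## EASE and annotation clustering

For a term with k foreground hits out of n foreground genes, against K term
genes in a background of N, the EASE score is the one-sided upper tail
after removing one gene from the overlap: `P[X ≥ k−1]` with
`X ~ Hypergeom(N, K, n−1)`; k = 0 is defined as p = 1. This is always ≥ the
unpenalized Fisher p and deflates single-gene hits (k = 1 gives p = 1).
Terms with EASE ≤ 0.05 enter clustering. Similarity between terms is
Cohen's kappa on their gene-membership indicators over the foreground
universe (degenerate all-agree tables give κ = 1, an empty universe 0);
clusters grow greedily from the most significant unassigned term, admitting
a term when κ ≥ 0.35 with at least half the current members (standard
annotation-clustering defaults; the underlying studies do not state
theirs). Clusters keep between 10 and 3000 member genes and are ranked by
`ES = −log10` geometric mean of member EASE p-values; the ES ≥ 1.5
significance convention is only coherent on this log scale, which is why
the "geometric mean of p-values" is reported as its negative log. No
further multiple-testing correction is applied, matching the analysis
this package re-implements.

## Meiotic recombination model

Each synaptonemal complex is a segment of configurable length (μm) with an
interior centromere. Crossover counts and positions are generated in two
stages:

1. **Count.** Per SC, the count is Poisson; under the obligate-crossover
   rule it is zero-truncated Poisson sampled by inverse CDF, with the rate
   solved numerically (Brent) so the post-truncation mean equals the
   configured per-SC expectation. Calibration is therefore exact in
   expectation; expectations below 1 are infeasible under obligate CO and
   degenerate to exactly one crossover.
2. **Position.** A hard-core configuration with pairwise gaps ≥ the
   interference spacing (default 20% of SC length, a deliberately simple
   stand-in for gamma-renewal interference that reproduces the ≤ 3
   crossovers-per-bivalent regime) is drawn directly: uniform order
   statistics on the free length plus fixed gaps. Counts above the packing
   bound `⌊1/spacing⌋ + 1` are clamped to it (negligible at the default
   regime). Each focus inside a suppression interval then survives with
   probability `suppression_factor` — genuine intensity thinning, so factor
   0 guarantees an empty interval and the inside/outside density ratio
   estimates the factor consistently. If thinning empties an obligate SC,
   the whole SC is resampled.

Two emergent properties matter for interpretation. First, hard-core
placement plus the obligate rule produce a mild, genuine excess of
crossovers towards the SC ends — the centro-distal gradient seen in real
pachytene data — so a central interval has slightly lower density even
with no suppression. Specificity of the suppression analysis is therefore
judged on effect size (the collinear control's inside/outside ratio stays
near 1, an order of magnitude from the 0.1 suppression regime), not on
non-rejection of a rank test. Second, suppression thinning reduces realized
counts below the configured expectation on suppressed SCs; calibration
regimes and suppression regimes are distinct configurations.

Relative focus positions are signed percentages of total SC length from the
centromere (p-arm negative, q-arm positive; a focus exactly at the
centromere belongs to the q-arm), binned at 10%. Densities are pooled
(Σ foci / Σ length in μm) for the headline tables, with per-cell densities
retained for the rank tests; a focus on an interval boundary counts inside
(closed-left, with the SC end closed). Cells missing a required BAC signal
are excluded listwise from inversion estimates only. One MLH1 focus is one
crossover and 50 cM throughout.

## Synthetic genome pairs

Genome A has equal-length chromosomes, a central N-run centromere and
non-overlapping genes placed by a stars-and-bars construction (uniform, or
`clustered` via a Beta(0.3, 0.3) profile). The rearrangement script is
interpreted in ancestral coordinates; intra-chromosomal events must not
overlap and at most one inter-chromosomal event may touch a chromosome
(events are applied inversions → indels → structural, with recorded
breakpoints transformed through later coordinate shifts). A gene cut by a
breakpoint is treated as disrupted and dropped from the ortholog set, which
is a bijection over retained genes. Truth breakpoint regions are
marker-bounded — the interval between the flanking retained genes on each
side — in both genomes' coordinates; a fission's derived-genome breakpoint
is a chromosome end and yields no truth EBR there, and symmetrically for a
fusion's ancestral side.

What the generator does **not** emulate: nucleotide substitution and
annotation error, assembly fragmentation, segmental duplications, repeat
divergence, clustered breakpoint reuse, and the image-analysis noise of
real MLH1 measurements. Passing tests establish that the detectors and
statistics recover what the models plant at marker / window / cell
resolution — not that real genomes satisfy those models.

## Test design and problem sizes

Oracle equivalences run against independently written brute-force checks:
maximal-run enumeration for the chaining rules (random tables up to 10
markers), an O(n³) substring scanner for tandem repeats (exhaustive over
2-letter strings to length 12, random 4/5-letter strings to length 30), and
a `math.comb` hypergeometric tail sum for EASE (exhaustive to N = 25,
random margins to N = 200). Stochastic guarantees are asserted as
rate bounds over many seeds (power ≥ 90% at the 85-cell regime with
suppression 0.1; null rejection ≤ 9% at α = 0.05, an upper bound because
tied ranks make the exact Mann–Whitney conservative) rather than on single
seeds, whose own null would fail 5% of the time. Consistency of the
suppression-factor estimate is checked at 4000 cells, where Monte-Carlo
error (~5%) sits safely inside the 10% assertion band, and with
interference disabled, since hard-core crowding adds a small positive bias
to the naive density-ratio estimator. Simulation sizes throughout (2–3
chromosomes of 20 Mbp, 200–600 genes, 85–4000 cells) are chosen so each
check's sampling error is small against the effect it asserts.
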