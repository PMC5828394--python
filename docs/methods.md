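# Methods

This note documents the models and procedures `ernascope` implements, the
parameters that matter, the conventions chosen where several were
defensible, and what the synthetic-data generator does and does not
emulate.

## Coordinates and signal semantics

All internal coordinates are 0-based, half-open (BED convention); GTF input
(1-based, inclusive) is converted on read. A `SignalTrack` stores sparse
non-negative integer counts of RNA 5′ ends per (chromosome, strand,
position). A minus-strand count at position *p* means a 5′ end at *p* read
leftward; no positional shifting is applied, matching the semantics of
5′-end assays (PRO-cap, CAGE). bedGraph intervals wider than one base are
expanded to per-base counts on read; overlapping intervals within one
strand file are rejected as ambiguous.

The TSS of a plus-strand gene is its start coordinate; of a minus-strand
gene, `end − 1` (the last base). For *distance* rules (below) gene ends are
treated as interval boundaries (5′ end of a minus-strand gene = `end`),
which is what makes an element at 100–200 sit exactly 800 bp from a 5′
boundary at 1000. TSS *overlap* always tests the TSS base itself.

## Element curation

Elements are partitioned into three genomic classes, in priority order:

1. **promoter** — the element interval contains an annotated TSS base
   (promoter beats intragenic for TSSs nested inside other genes, being
   the more specific label);
2. **intragenic** — the interval overlaps a gene body;
3. **intergenic** — otherwise. An intergenic element is *clean* only if
   its closest edge clears every gene 5′ end by ≥ `min_dist_5prime`
   (default 500 bp) and every gene 3′ end by ≥ `min_dist_3prime` (default
   1500 bp); the 3′ clearance is larger because transcriptional
   read-through past gene ends contaminates nearby windows more than
   upstream regions do. Elements failing the clearances are kept in the
   table, flagged, and excluded from downstream intergenic sets.

A second filter removes likely unannotated promoters: any
intergenic/intragenic element whose interval, expanded by
`tss_exclusion_radius` (default 500 bp) on both sides, contains an
auxiliary TSS (RAMPAGE-like or lncRNA TSS sets) is dropped. The radius is
measured edge-to-point; a center-to-point reading would be stricter for
wide elements, but edge-to-point is the conservative reading of "within
500 bp of the element" and is the one implemented.

Enhancer regions that are long or composite are refined against a DHS peak
set: an enhancer overlapping exactly one peak is replaced by that peak
(carrying the enhancer's identity and its summit); enhancers overlapping
zero or several peaks are dropped with counts logged, since multi-peak
regions likely span several distinct elements.

## Orientation index and directionality

Strand counts are summed over `[summit − h, summit + h)` with
`h = halfwidth` (default 250 bp, i.e. a 500-base window around the element
center; the halfwidth is configurable because the window definition in
display legends is ambiguous between a 500-bp and a 1000-bp read). Then

    OI = max(P, M) / (P + M)

with OI undefined when `P + M = 0`. A tie (`P = M`) deterministically
assigns sense `+` and OI exactly 0.5. Class bands: OI ≤ 0.6 bidirectional,
OI ≥ 0.8 unidirectional, otherwise asymmetric; elements with total reads
≤ `min_reads` (default 30, strict "more than 30 reads") are undefined to
keep noisy ratios out of the class comparisons. OI is invariant under
strand swap and under scaling both counts by a common factor, and binomial
thinning with equal retention on both strands leaves its expectation
unchanged — both properties are enforced by tests.

## Depth matching by binomial thinning

To compare datasets of different depth, the deeper track is thinned: each
read kept independently with retention probability *p* (binomial per
position), which preserves Poisson structure and relative strand ratios.
*p* is fitted by bisection on the realised median of both-strand promoter
window counts, warm-started at `target / current_median`, and accepted when
the realised median is within 5% of the target or the bracketing interval
is below 1e-4. Each bisection evaluation and the final thinning use RNG
streams derived deterministically from the user seed, so results are
reproducible. Upsampling (target above the current median) is refused.

## Motif analysis

PWMs are width ≥ 4 probability matrices over ACGT (rows sum to 1 within
1e-3) with a background model (uniform by default), scanned as log₂-odds;
an `N` contributes 0 at any motif position. Minus-strand scanning uses the
reverse complement with offsets mapped back to the original frame, so the
best score is strand-symmetric by construction.

Anchors are strand-specific initiation maxima: the leftmost position of
maximal count within the element window. For each element and strand role
(sense = more-transcribed strand, antisense = other), the window of
± `window_halfwidth` (default 250 bp) around the anchor is scanned (the
antisense window reverse complemented so offsets live in the transcription
frame), and the best-site offset recorded — one site per element.

Central enrichment is the binomial upper tail Pr[X ≥ k | n, p₀] for *k* of
*n* best sites within ± `central_halfwidth` (default 50 bp, a package
choice exposed as a flag) of the anchor. The null fraction p₀ counts valid
site-start offsets only (window length − width + 1), which matters at
motif width 6–8 in a 501-base window. This is deliberately a single fixed
central window with a single test — the full CentriMo machinery
(window-ladder maximisation, cross-motif E-values) is out of scope; a
window ladder with Bonferroni correction over windows is available for
sensitivity checks. The discrete binomial tail is conservative: under
uniform best-site placement the measured Pr[p ≤ 0.05] is about 4–5%
(checked over 1000 simulated element sets).

The package ships a synthetic INR-like PWM (`default_inr_pwm`,
TCAGT-core, consensus TCAGTY, dominant probability 0.85) as a documented
stand-in because no numeric initiator matrix is bundled; real analyses
should supply their own MEME-minimal PWM file. The consensus's initiation
base (the A at motif position 2) is the anchoring convention used both for
planting in simulation and for interpretation.

Positional occurrence profiles (e.g. AATAAA polyadenylation signal, U1-like
patterns) count exact IUPAC matches (or PWM hits above a cutoff) per
offset, strand-aware, normalised per element — used to ask whether such
motifs show positional structure around element centers.

## Metaprofiles and smoothing

Metaprofiles are per-offset **sums** of counts over elements aligned at
their summits, offsets −h…+h inclusive; when oriented by sense strand each
element is flipped so its more-transcribed strand reads rightward. Sums
(not means) are the display convention; a `mean` option divides by the
element count. Profile additivity over element sets is exact and tested.

Smoothing is loess of degree 1: at each offset, a linear fit over the
nearest ⌈span·n⌉ points weighted by tricube `(1 − (d/dmax)³)³`, no
robustness iterations, span default 0.1. Degree 1 makes the smoother exact
on linear data for any span (a test oracle); points at the neighbourhood
boundary get weight 0, which makes the output independent of how distance
ties are broken. If fewer than two points carry positive weight the fit
falls back to an unweighted fit over the neighbourhood. The smoother is
implemented in-package (rather than delegating to an external lowess) so
the neighbourhood and weighting conventions are exactly these documented
ones, verified against a per-point weighted-least-squares oracle at 1e-6.

## Activity comparisons

Activity labels are `(element, stage, tissue) → status` with status in
{active, inactive, nonenhancer}; conflicting duplicates are an error,
labels for unknown elements are logged and skipped. Levels are both-strand
window counts; displays use log₂(count + 1) since untranscribed elements
(zero counts) are real and must remain plottable.

The test is one-sided Wilcoxon rank-sum for "a exceeds b" with midranks.
For `n_a + n_b ≤ 20` the p-value is the exact permutation tail
Pr[W ≥ W_obs] computed by enumerating all label assignments over the pooled
midranks — ties included, which the usual exact tables do not cover; larger
samples use the normal approximation with tie-corrected variance and
continuity correction (scipy's Mann-Whitney asymptotic path). The exact
branch is verified against an independent full-permutation oracle for all
sample sizes up to 12. The three pairwise comparisons (active > inactive,
active > nonenhancer, inactive > nonenhancer) are reported unadjusted,
matching how such panels are usually presented; a Holm adjustment helper is
provided. The direction is fixed a priori (the biological claim direction),
not chosen post hoc.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
with ground truth for every quantity the pipeline estimates:

- **Genome**: i.i.d. uniform ACGT (GC-content knob), default ~1.2 Mb. This
  is sufficient for motif-test calibration but carries none of the
  composition, repeat, or chromatin structure of a real genome.
- **Genes**: non-overlapping, ≥ 2 kb flanks, random strands; a directional
  promoter element (q = 0.97, λ = 400) sits at each TSS.
- **Elements**: default 150 each of bidirectional (q = 0.5), asymmetric
  (q = 0.75) and unidirectional (q = 0.95) classes at λ = 200 expected
  reads, plus 50 nonenhancers (q = 0.5, λ = 20 — DHS-positive, weakly
  transcribed, never active), spaced 1.5 kb apart in a gene-free region so
  the distance rules classify them cleanly. q values were chosen to sit
  clearly inside the three OI bands at realistic depth; λ = 200 reflects a
  well-covered element in a deeply sequenced library, and λ = 20 a weak
  one near the read filter.
- **Counts**: total reads N ~ Poisson(λ) (or gamma-Poisson with dispersion
  0.2 for negative-binomial noise); sense reads ~ Binomial(N, q); 5′
  positions ~ round(Normal(anchor, σ)), σ default 15 bp — focused but not
  single-base initiation. The antisense anchor sits 110 bp upstream of the
  sense anchor, a typical divergent-initiation spacing.
- **Motifs**: the INR consensus is written into the genome at each planted
  anchor (reverse complemented on the minus strand) — on the sense anchor
  for all transcribed classes, on both anchors for the bidirectional
  class, nowhere for nonenhancers.
- **Activity**: transcribed-class elements are active with probability 0.5;
  inactive elements get λ divided by the activity effect (default 4-fold),
  encoding "same element, lower output at this stage".

Everything is drawn from one seeded generator; outputs (FASTA, GTF, BED,
bedGraph pair, label and truth TSVs) are byte-identical across runs with
the same seed and are valid inputs to every other module.

What passing tests on these data show: that the estimators recover known
strand biases, planted motifs and level effects under the stated noise
models. What they do not show: robustness to mappability artifacts,
transcriptional read-through from real gene 3′ ends, sequence-composition
biases in motif background, replicate variance structure, or peak-calling
uncertainty — none of which the generator simulates (read-through, in
particular, is the confounder the classifier's distance rules exist to
exclude upstream).

## Problem sizes and determinism

Default sizes (500 elements + 30 genes, ~70k reads; 500 per class in the
recovery analyses; 1000 replicate sets in the calibration analysis) were
chosen so each analysis yields stable estimates while the whole suite and
the acceptance script run in seconds. All randomness flows through
`numpy.random.default_rng` seeded from user-supplied integers; derived
stream seeds stay below 2³¹. Pipeline TSVs use fixed 6-significant-digit
float formatting and the run manifest contains no timestamps, so reports
are byte-stable.

## Known limitations

- The classifier tests TSS overlap against points, not promoter windows;
  broad promoters are represented only via the exclusion radius.
- The OI window and the central-enrichment window defaults are
  display-convention choices, not fitted quantities; conclusions should be
  checked at ±500 bp / ±100 bp as well (both are flags).
- The exact Wilcoxon branch enumerates combinations and is O(C(n, n_a));
  it is capped at n = 20 for that reason.
- `read_fasta` materialises sequences in memory; appropriate for the
  synthetic and per-region genomes used here, not for mammalian-scale
  genomes (use the indexed accessor directly for those).
- No multiple-testing correction is applied across directionality classes
  in the motif report; the per-class tests are reported as-is.
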