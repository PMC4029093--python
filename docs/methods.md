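# Methods

## Peak model and clustering

CTSS tables hold one record per (chromosome, position, strand) with the
number of CAGE reads whose alignment starts there: forward reads contribute
their leftmost aligned base, reverse reads their rightmost. Coordinates are
0-based; records are BED-style half-open single bases. Secondary and
supplementary alignments are excluded by default so one tag is one
transcript 5′ end; multi-mapped reads count once at their primary location.
TPM normalization divides by the per-sample total CTSS count.

For a density parameter *d* > 0, a segment of consecutive sites *i..j*
scores `T(i,j) − d·(pos_j − pos_i)`. The peak set at density *d* is defined
as the maximal-scoring-subsequence decomposition (Ruzzo–Tompa) of the
alternating sequence (+count at each site, −d·gap between neighbours),
trimmed to start and end on sites. The clusters reported by
`cluster_sites` are exactly the union of these decompositions over all
*d* > 0, each annotated with the infimum (`min_d`) and supremum (`max_d`)
of its density interval. The implementation is the recursive
split-at-weakest-break algorithm: a segment's break density is the minimum
over all prefix densities `T(i,k−1)/(pos_k − pos_i)` and suffix densities
`T(k,j)/(pos_j − pos_{k−1})`; the segment is emitted when its break density
exceeds the minimum density inherited from its parent, and the recursion
descends into the two halves. Equal prefix/suffix break densities split at
the leftmost minimizing break; this choice affects only the order of
recursion, not the emitted set. The test suite enforces exact equality —
coordinates and density interval endpoints — against an independent
brute-force oracle that evaluates the decomposition with exact rational
arithmetic at midpoints between all candidate critical densities.

Internally cluster coordinates are inclusive site positions (`start` =
first site, `end` = last site): the scoring extent is `end − start` while
length for per-base quantities is `end − start + 1`, so singletons have a
defined TPM per base. Exports and all downstream interval work (merging,
hierarchy, counting, annotation) use half-open `[start, end+1)` BED
convention. Strands and chromosomes are clustered fully independently.

### Density filter

`tpm_per_base = (tag_sum · 10⁶ / library_size) / length`; clusters strictly
below the threshold (default 0.1) are discarded and surviving parent links
are re-wired to the nearest surviving ancestor. A density threshold, unlike
a raw tag-count threshold, keeps narrow peaks of moderate expression — the
point of the multiscale analysis.

### Stability

`stability = max_d / min_d`. Root clusters (min_d = 0) and singletons
(max_d = ∞) have an unbounded ratio; these are reported at a configurable
ceiling (default 1000) so hierarchical sums stay finite and rank-usable by
the IDR step, which consumes only ranks. Finite ratios are reported exactly
by default (`clip_finite_stability` also clips them if set), preserving the
identity `stability = max_d/min_d` wherever the ratio is finite.
Hierarchical stability is the running sum of stabilities from the root down:
`hier(child) = hier(parent) + stability(child)`.

## Replicate merging and IDR

Peaks from two replicates match when the same-strand overlap is at least
90% of *both* lengths (inclusive reading of "90% reciprocal overlap");
the merged peak takes the intersection coordinates and both hierarchical
stabilities. Many-to-many conflicts are resolved greedily by best
reciprocal fraction (ties: larger overlap, then leftmost), so each input
peak joins at most one pair. With more than two replicates every pairwise
combination is merged and reported; the first pair defines the condition's
reproducible set.

The IDR model: each pair is reproducible with probability π₁, in which case
its latent scores are bivariate normal with mean (μ, μ), common variance σ²
and correlation ρ; otherwise the latents are independent standard normal.
Observed scores matter only through ranks: ranks (average ties) are scaled
by 1/(n+1), inverted through the current mixture marginal CDF to pseudo
normal scores (vectorized bisection), and the Gaussian mixture EM runs to a
pseudo-log-likelihood tolerance (default 1e-4) with the rank inversion
refreshed between EM passes. The refresh loop is capped (30 passes):
iterating the self-consistent transform to a fixed point drifts slowly
along a likelihood ridge that shrinks σ, so bounded refreshing is both the
convention of reference implementations and the better estimator. M-step
guards keep the fit identifiable: π₁ ∈ [1e-4, 1−1e-4], μ ≥ 0 (the
reproducible component is the higher-scoring one), σ ≥ 0.1, |ρ| ≤ 0.999.

**Null identifiability guard.** When replicates carry no rank concordance
the pseudo-likelihood is maximized on a degenerate ridge — an uncorrelated
"reproducible" component absorbing all pairs — which would label everything
reproducible. Since the reproducible component is *defined* by concordance,
a fit whose final ρ falls below `min_rho` (default 0.2) is declared
uninformative and every pair receives local IDR 1. On genuinely concordant
data fitted ρ sits far above the floor, so the guard only engages in the
no-signal regime.

Local IDR is the posterior probability of the irreproducible component;
global IDR at rank r is the mean of the r smallest local IDRs (the expected
irreproducibility of the selected set). Filtering keeps global IDR
strictly below 0.1 (configurable to local IDR), then drops peaks longer
than 200 bp. EM defaults (init 0.7/2.6/1.3/0.8, tol 1e-4, 200 iterations)
are exposed in the pipeline config.

## Hierarchy and peak classes

The containment forest links each reproducible peak to the smallest peak
strictly containing it; identical intervals are de-duplicated upstream
(keeping the higher mean stability), and partially overlapping peaks —
possible because merged peaks are intersections — share no edge. Bottom
peaks are roots, top peaks are leaves; a lone peak is both. The forest is
built after the IDR and length filters, following the pipeline's step
order. The size-vs-content histogram counts all transitive descendants per
peak ("clusters within clusters"), not only direct children.

## Differential expression

Counts per peak interval and sample are compared between exactly two
conditions, top and bottom classes tested separately. Counts are equalized
to the geometric-mean library size (continuous pseudo-counts); the common
NB dispersion φ (Var = μ + φμ²) maximizes the conditional likelihood of
within-group counts given group sums — a Dirichlet-multinomial likelihood
in φ — via bounded scalar optimization on log φ; an optimum at the lower
bound reports φ = 0 (Poisson), and one replicate per group falls back to a
configured default (0.1) with a warning. The exact test conditions the
(rounded) equalized group sums on their total: group sums are NB with size
n_g/φ and a shared success probability, so the conditional law is
Dirichlet-multinomial (binomial at φ = 0), and the p-value sums the
probabilities of all outcomes no more likely than the observed split (a
1+1e-10 relative tolerance absorbs floating-point ties). log₂FC uses a
prior count of 0.5 per group; logConc is the log₂ mean normalized
abundance. BH adjustment is applied within each peak class; calls require
|log₂FC| > 2 and adjusted p < 0.05, both strict.

Gene-level calls assign each tested peak to every gene whose TSS ± 500 bp
window it overlaps by ≥ 1 bp on the same strand (whole-peak overlap;
strand-agnostic mode available); unassigned peaks are "novel". A gene is
called when any assigned peak is significant, and the triggering classes
are recorded so top-only triggers (TSS shift under a stable promoter) are
visible.

## Legacy comparison mode

Replicate CTSS counts are pooled per condition, clustered once, and
filtered by tag_sum ≥ 30, stability ≥ 2 and length ≤ 200 bp, keeping only
outermost clusters. How the original single-scale treatment combined
replicates into one DE-ready peak set is not standardized; pooling is the
simplest defensible choice and is confined to this mode.

## Synthetic data

The simulator plants the structures the pipeline is built to find: 60
promoters on a 600 kb chromosome (uniform slots, random strand), each a
broad region of 50–200 bp containing 1–5 sub-peaks of 1–10 bp (placed in
disjoint sub-slots, strictly inside) plus sparse background sites every
5 bp carrying 20% of the promoter's intensity. Promoter intensities are
log-normal (scale 300 tags/library, σ = 0.7) and shared across all
samples — this shared factor, not shared noise, is what makes replicate
peak scores concordant — while counts are drawn independently per site and
replicate as Gamma–Poisson (NB, φ = 0.1). 15% of promoters are
replicate-specific: emitted in one replicate of each condition only, at
0.1× intensity, matching the empirical association between irreproducibility
and low expression; uniform background noise sites (rate 1e-4/bp,
count ≈ 1–2) are independent per replicate. Differential expression
(fold 8) is planted as whole-promoter scaling (15% of promoters, random
direction) or as a sub-peak shift (15%): two sub-peaks exchange intensity
shares t·f/(1+f) ↔ t/(1+f) between conditions, so each moves by the full
fold while the promoter total is exactly conserved. Truth tables expose
promoter/sub-peak intervals, per-condition site means, reproducibility
flags, true log₂ fold changes and a gene-TSS table.

What the simulator does *not* emulate: mapping error and multi-mapping,
sequence-dependent peak shapes, chromatin-driven broad/sharp promoter
classes, inter-promoter correlation, and library-preparation biases.
Passing tests therefore demonstrate the pipeline's statistical behaviour
under its own model assumptions, not performance on any real library.

All randomness flows from one seed: architecture from a master stream,
each (condition, replicate) sample from a spawned substream, so outputs
are byte-identical across runs. A `share_replicate_streams` flag reuses
one substream across replicates (with φ = 0, no noise and no
replicate-specific promoters this makes replicate tables identical — a
degenerate configuration used in tests).

## Problem sizes

Default test and acceptance runs use the simulator at its default scale
(60 promoters, ~2–3 thousand CTSS per library) with 10–20 seed
repetitions, 2000-pair IDR fits and 2000-row DE matrices — sizes chosen so
the full suite exercises every stage many times while an entire run stays
in the minutes range on one CPU.

## Known limitations

* The IDR guard is binary: data with genuine but weak concordance
  (true ρ barely above the floor) is conservatively declared
  irreproducible rather than partially credited.
* Common dispersion is a single shared φ; heavy contamination of a small
  peak set with all-or-nothing rows (e.g. spurious peaks surviving into a
  legacy-mode matrix) inflates it and costs power. Tag-wise or trended
  dispersion is out of scope.
* Hierarchical stability grows with depth, so broad root peaks carry
  systematically lower scores than deeply nested singletons; under tight
  IDR thresholds roots are the first to drop, which can fragment the
  bottom layer.
* Merging is strictly pairwise; with >2 replicates there is no consensus
  interval across all replicates, only per-pair results.
* DE supports exactly two conditions (the pipeline runs every stage for
  any number of conditions, but testing is pairwise).
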