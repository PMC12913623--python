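# Methods

This note documents the models and procedures the package implements,
the defaults it ships, and the choices made where the underlying method
leaves room for interpretation.

## Library design

Elements are 100-bp sequences. Motifs are substituted into a neutral
template at four fixed slot anchors starting at positions 8, 30, 52 and
74 (1-based; configurable), which keeps motifs of up to 12 bp evenly
spaced and disjoint and the fourth motif clear of the template end.
Slot 1 is the most distal from the minimal promoter, slot 4 the most
proximal. Partial homotypic arrangements use slot 2 (one copy) and
slots 2–3 (two copies); four copies fill all slots. The Class 2 scheme
— every ordered pair (A, B) as a 1:1 layout (A in slot 2, B in slot 3)
and a 2:2 block layout (A in slots 1–2, B in slots 3–4), on both
templates — is the arrangement under which nine motifs yield exactly
288 elements and the interaction term *k* of the synergy regression
equals the per-motif copy number (1 or 2).

The default motif set contains nine liver-TF consensus strings (CEBPA,
CTCF, FOXA1, HNF1A, NR2F2, ONECUT1, PPARA, REST, XBP1). They are
short JASPAR-core-like consensus sequences chosen so that four slots fit
the template; any motif set can be supplied as (name, IUPAC-consensus)
pairs or explicit PWMs. Motif instantiation takes the most probable
base per PWM column (alphabetical tie-break); sampling from the PWM is
deliberately not the default so designs are deterministic.

The default templates are seeded random 100-bp sequences standing in
for the two neutral genomic backbones (their hg19 coordinates are kept
as provenance strings); pilot/control sequences are likewise seeded
random stand-ins, with scrambled controls generated as per-element
shuffles of the active set so base composition is preserved.

**Window perturbation.** Each 6-bp window (step 1) is re-randomized
per replicate: every base is redrawn uniformly from the three
non-reference bases, so the mutant window differs from the wild type at
all six positions. To prevent randomization from creating a binding
site, the mutated window plus 6 bp of flank on each side (18 bp total,
clipped at the CRE ends) is scanned against the motif set; any hit
rejects the draw, with up to 100 retries before the window is reported
as a design error. The scanner is a log-odds PWM scan of both strands
against a uniform background with threshold 0.8 x the motif's maximum
score; for consensus-derived PWMs (consensus base probability 0.997)
this behaves as a near-exact consensus match, which is the conservative
behaviour wanted in a rejection filter. A p-value-calibrated scanner is
out of scope.

## Quantification and normalization

Counts are UMI counts per (element, sample, assay); deduplication
counts distinct UMI strings. CPM normalization is applied within each
(sample, assay). The TMM factor is computed over negative controls
(random-genomic sequences) with positive counts on both sides:
M = log2(enriched/inserted) and A = 0.5·log2(enriched·inserted) are
doubly trimmed — 30% per tail by M, 5% per tail by A, the conventional
TMM fractions — and f = 2^mean(M) over the kept set. The default mean
is unweighted: both the trim windows and the mean are then invariant
under a common shift of M, so dividing enriched counts by f zeroes the
negatives' trimmed mean log2 activity *exactly*, which is the anchoring
contract the rest of the package relies on. Inverse-variance weighting
(w = 1/(1/E + 1/I)) is available but makes the anchor exact only up to
weight recomputation.

For the reporter assay, DNA and RNA barcode counts are CPM-normalized
separately, per-barcode ratios averaged per element (mean by default,
median optionally), and the anchoring factor is computed on the same
statistic being anchored — the doubly trimmed mean of the negatives'
log2 aggregated ratios — rather than on summed counts, because the mean
of barcode ratios carries a Jensen inflation that ratio-of-sums does
not; anchoring a statistic with a factor derived from a different one
would leave that inflation in place.

Replicates are combined by summing TMM-anchored enriched CPM and
inserted CPM per element across replicates and taking the ratio of
totals (not the mean of per-replicate ratios); per-replicate activities
are retained for the regressions. TMM anchoring is applied per
replicate by default; a pooled-counts mode exists.

Zeros: when either side of a ratio is zero, a pseudocount of half a
UMI, expressed on the CPM scale of that library (0.5·10⁶/library size),
is added to both sides. A fixed 0.5-CPM pseudocount would place
zero-count elements a dozen log2 units below the data and, in the
variant-effect regression, inflate the residual variance enough to
destroy power; half a UMI puts them just below the smallest observable
count. Elements with fewer than 5 raw inserted UMIs (configurable) are
flagged `low_inserted` and excluded rather than erroring — this is the
poly-C-type dropout mode in which library members fail amplification.
Reporter elements need barcodes observed in both DNA and RNA and at
least 5 surviving barcodes.

## Grammar statistics

All families are per assay and BH-adjusted; every result row carries
its family and a flag for degenerate cases.

* **Copy-number trend**: two-sided Spearman correlation between motif
  copy number (1/2/4) and per-replicate log2 activity. For n ≤ 9
  observations the p-value is an exact permutation p over all rank
  permutations (mid-ranks for ties); larger samples use the asymptotic
  approximation. Constant activities are reported NA.
* **Pairwise synergy**: OLS with intercept of log2 activity on
  (count_tf1, count_tf2, k) over the pair's homotypic and heterotypic
  elements, replicates (templates x infections) entering as independent
  observations. k is 0 for homotypic elements and the per-motif copy
  number (1 or 2) for heterotypic ones; a binary k encoding is available
  behind a flag. Noise-free fits with zero residual get the limiting
  p-values (1 for a zero coefficient, 0 otherwise) instead of NaN.
  Rank-deficient designs (e.g. missing heterotypic rows) are flagged NA.
* **Order ANOVA**: one-way ANOVA over the up-to-24 slot-order groups of
  each 4-motif combination; combinations with fewer than 3 groups of ≥ 2
  observations, or all-constant values, are flagged NA. The effect size
  reported is the difference between the highest and lowest permutation
  group means.
* **Positional enrichment**: elements ranked by combined activity;
  the top and bottom n (default 200) form the draw sets, ties at the
  boundary broken deterministically by element id. For each (motif,
  slot, group) the one-sided hypergeometric tail in the direction of the
  observed odds ratio is reported along with that direction; infinite or
  zero odds ratios are flagged `boundary`.
* **Variant effects**: per CRE and assay, OLS of log2 enriched CPM on
  log2 inserted CPM plus one indicator per variant, wild type as
  baseline, replicates pooled. Significance is raw p < 0.01 (BH
  optional). Variants with no counts in any replicate are omitted and
  listed in the result's `omitted` attribute.

## Functional-site calling

For each position the positional effect is the median activity of the
window variants covering it (up to 6 per randomization replicate, 12
pooled — both replicates pool into one covering set by default;
positions near the ends have fewer). The reference is the wild-type
activity for reporter data; for enriched assays, where the wild type is
grossly over-represented, the median of the substitution-library
activities should be supplied instead. The MAD score is
(m_i − ref) / s with s the median of |m_j − ref| — a robust z-style
score centred at the reference; a mean-based scale is available behind
a flag. s = 0 yields all-zero scores with a `degenerate_scale` flag.

Scores are smoothed with a Gaussian filter (sigma 2 positions, kernel
truncated at 4 sigma, reflective boundary; the sigma default is ours)
and differentiated by central differences (one-sided at the ends).
Edges: the threshold is the median of |derivative| with strict
inequality, so a flat profile yields no edges; strong edges are 3-point
non-maximum-suppression survivors above threshold, weak edges all other
above-threshold positions, and weak edges adjacent (distance 1) to a
strong edge are promoted iteratively to a fixpoint. Peaks are strict
3-point local extrema of the smoothed score with |value| > 0.75
(plateaus report their leftmost position). Functional sites extend
each peak to the nearest *NMS-localized* strong edge on either side
(profile end if none) and merge overlapping intervals. Promoted
positions classify the edge map but do not bound sites: by
construction about half of all positions exceed the median threshold,
so promotion chains are too dense to delimit regions — inside a deep
perturbation plateau they would truncate the site at the inner slope,
and at low noise they can bridge the entire profile. Each site records
the extreme smoothed MAD value and its sign (gain vs loss). The module
contains no randomness; identical inputs give identical calls.

Because the MAD scale is set by the typical noise deviation, noise
positions score near ±1 regardless of the raw noise level, and
occasional spurious peaks above 0.75 (hence small spurious sites) are
an inherent property of the procedure, also at high signal-to-noise.
Downstream consumers should rank sites by |extreme_mad|.

## Synthetic data

True log2 activities are additive: per-copy motif effects + synergy x k
+ optional slot modifiers + template effect (0 by default — templates
act as replicates); control elements are exactly 0. Counts are
negative binomial parameterized by mean and dispersion (variance
mu + phi·mu²; phi = 0 is the Poisson limit), with inserted means equal
to depth x an element-specific log-normal integration frequency
(sd 0.5 in log space) and enriched means integration x 2^truth.
Replicates model independent library infections, so integration
frequencies are redrawn per replicate — this matters: with one
indicator per variant, the inserted-count covariate of the
variant-effect regression is identified only by within-element
variation, which independent infections provide and a single shared
integration draw would not. Barcode tables draw 40–120 barcodes per
element (emulating the ~80-barcode average of such libraries) with
per-barcode log-normal frequencies shared across replicates (one
plasmid pool) and RNA means equal to DNA means x 2^truth.

Default depths emulate the reported sequencing scales: ~400 inserted
and ~50 enriched UMIs per element (750/50 for perturbation libraries),
dispersion 0.1 — which reproduces the moderate replicate-to-replicate
activity correlations characteristic of direct UMI-counting readouts.
Perturbation datasets plant functional windows as additive effects on
any variant whose mutated span overlaps the window; activity-level
noise is Gaussian (default sd 0.15). Everything is reproducible from
(config, seed).

What the generator does *not* emulate: sequencing error and UMI
collisions, PCR chimeras, position-of-integration effects, fragment
length structure, and correlated noise between assays. Passing tests
therefore demonstrate correctness of the computations under the stated
noise model, not robustness to every artefact of real libraries.

## Validation problem sizes

The packaged checks use: 500 simulated elements with 200 negative
controls for the anchoring and recovery properties; 200 seeded runs for
planted-synergy detection and 500 for the all-null false-positive
calibration; 100 seeded runs each for variant-effect recovery
(4-fold drop over a 7-bp span at 750/50 UMI depths) and for
planted-window site recovery (10-bp loss window, activity noise 0.15).
These sizes give binomial standard errors of a few percent on the
reported rates while keeping the whole validation suite around a
minute of CPU.
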