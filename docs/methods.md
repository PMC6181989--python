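# Methods

## Problem and scope

CTCF-mediated loops are pairs of CTCF-bound anchors brought into contact by
cohesin-dependent extrusion.  `loopforest` treats loop calling as supervised
binary classification over candidate anchor pairs, with ChIA-PET loop calls
as the labelling oracle.  The package covers the downstream method only:
upstream peak calling, motif scanning (FIMO), read alignment, ChIA-PET
interaction calling and expression quantification are inputs, consumed as
standard text formats.

## Coordinates and quantification

All coordinates are 0-based half-open internally (BED convention); FIMO's
1-based inclusive coordinates are converted on read.  Overlap always means
"by at least 1 bp" — for read counting, anchor matching, site repertoire
comparison and network anchor merging alike.

RPKM over a window is `n / (kb × M)` where `n` counts reads overlapping the
window by ≥ 1 bp, `kb` is the window length in kilobases and `M` the
library's total mapped, de-duplicated read count in millions.  The
denominator is deliberately the *total* library size, not the count
surviving enriched-region masking: masking is a noise filter, and using the
masked count would re-scale every track by an arbitrary, track-specific
factor.  Masking itself retains reads overlapping ≥ 1 enriched region and is
idempotent.

Anchor-pair statistics (local features, motif strength, conservation) use
the population standard deviation, which for a pair is `|v1 − v2| / 2`.  The
same convention gives the relative fluctuation of a site's intensity across
two cell types the closed form `|v1 − v2| / (v1 + v2)`, a scale-free value
in [0, 1].

## Binding sites

A site is a CTCF peak summit ± 500 bp; intensity is the CTCF RPKM over
summit ± 2 kb; the site's motif is the highest-scoring occurrence within
summit ± 1 kb, score ties broken by distance to the summit and then by
leftmost coordinate (the caller's ranking is otherwise unstable under
input order).  Sites whose extents overlap within one cell type are kept
distinct — the peak caller already resolved them.  A site with no occurrence
contributes motif strength 0 and no orientation information.

## Loop geometry

Loop length is the distance between the two anchor summits.  Summits are
the stable reference points: anchor extents vary with the peak caller's
width conventions, summits do not.  The in-between and expression windows
are the inter-summit span for the same reason.  Flanking windows run from
the anchor summit to the nearest CTCF site summit outside the loop; at a
chromosome end, where no outside site exists, a 10 kb window is used so the
feature stays defined.

## Training sets

Positives: ChIA-PET loops with FDR ≤ 0.05 and PET ≥ 2, length within
10 kb–1 Mb.  Negatives: uniform rejection sampling over same-chromosome
site pairs in the length range, discarding any candidate whose two anchors
both overlap (≥ 1 bp each) a ChIA-PET call with PET ≥ 1 or a loop in the
supplied Hi-C list, until exactly 5× the positive count is reached;
sampling is seed-deterministic and fails loudly (reporting the achieved
count) if the feasible pool is exhausted, which genuinely happens on small
inputs.  Wiring negatives re-pair the positive loops' own anchors under the
same exclusions at 3×; because both anchors of a wiring negative are real
loop anchors, only pair-level features (orientation, length, in-between
signal, expression) can separate the classes, which is the point of the
protocol.

## Classifier and evaluation

The forest uses 500 trees, √p features per split, unlimited depth and
uniform class weights (the 5:1 design fixes the operating prevalence); all
hyperparameters are exposed, and the test suite runs smaller forests purely
for runtime.  Cross-validation is stratified 10-fold with out-of-fold
scoring, repeated 5 times with different partition seeds; the 95% CI is
mean ± 1.96 SE over the 5 repeat values.  Prediction refuses any feature
matrix whose column names or order differ from training — the feature order
is persisted with the model.

Recursive feature elimination refits the forest at each round, drops the
`step` lowest-importance features, and re-scores the reduced set with the
full repeated-CV protocol, so the first point of the curve is identical to
a direct cross-validation.

Anchor-level evaluation scores each labelled anchor (merged by ≥ 1 bp
overlap; positive if any positive-loop anchor contributed) with the highest
probability among predicted loops touching it, then sweeps the threshold;
zero-prediction thresholds have undefined precision and are skipped rather
than imputed.

## De novo prediction and validation

The genome scan enumerates all same-chromosome site pairs within the length
bounds and scores them in bounded-memory chunks.  Predictions are
categorised against the full (sub-threshold-inclusive) ChIA-PET call set:
*Significant* (matched call, FDR ≤ 0.05 and PET ≥ 2), *With evidence*
(matched but PET = 1 or FDR > 0.05), *No support* (no matching PET).  The
library down-sampling analysis is approximated desk-scale by binomial
thinning of PET counts (each count → Binomial(n, f), zero-count loops
dropped); users with the external ChIA-PET pipeline can instead supply
re-called loop files.

Hi-C validation takes each loop's KR-normalised contact value at its summit
bin pair (10 kb bins, value = raw / (kr_i · kr_j), missing if either factor
is NaN — never zero).  Controls reuse each loop's exact length at a uniform
random start, so the control length distribution matches the loop length
distribution exactly; the comparison is a one-sided Mann–Whitney U test.
No neighbourhood maximum is taken around the bin pair.

## Interaction network

Anchors overlapping ≥ 1 bp merge transitively into nodes — for intervals,
transitive overlap closure is exactly interval merging, so the
implementation uses a sweep and the tests verify it against a brute-force
union–find.  Loops become edges; parallel loops collapse with a recorded
multiplicity; within-node loops create no self-edge.  Hubs are the top 10%
of nodes by degree (distinct neighbours), ties broken by CTCF intensity
descending; the bottom 10% are non-hubs.  Fewer than 10 nodes makes the
deciles degenerate and raises.

## The synthetic world

The default `FixtureSpec` plants: two 10 Mb chromosomes; 1,600 sites on a
jittered grid (spacing ≈ 12 kb, so neighbouring anchors never overlap); 500
designated looping sites anchoring 600 true loops with uniform-feasible
lengths in 10 kb–1 Mb; PET counts 2 + Poisson(6) and FDR ~ U(0, 0.05) for
true loops plus 400 sub-threshold calls (PET = 1 or FDR > 0.05); 3× elevated
CTCF and RAD21 read density at loop anchors over a Poisson(40) per-site
base; an extra 85% convergent-motif rate at true loops over a 90%/random
background; 3.3× suppressed FPKM for genes inside loops; and 5× Hi-C
enrichment at loop bin pairs over a 1/(1+d) distance-decay background with
a lognormal KR vector (first two bins NaN).  Reads are only sampled on
enriched regions — masking would discard the rest anyway — with the library
size fixed at 10⁶ so RPKM values are realistic.  Where no external value
dictated a default, the choice reflects typical deep ChIP-seq of an
abundant factor and was made once, before any test was run against it.

`neutral()` switches every effect off.  Two subtleties make the neutral
world genuinely exchangeable rather than merely "effect-free": the
convergence parameter is defined as *forcing on top of chance* (so neutral
is 0, not the chance rate), and the looping-site designation is itself
released (every site may loop), because concentrating positives on a site
subset makes anchor identity informative across CV folds even with all
intensity folds at 1 — a real leakage channel, worth knowing about when
interpreting published cross-validated loop classifiers, since shared
anchors between training and test loops act as entity leakage there too.

A second cell type shares the site grid and all effect sizes; a stated
fraction of loops is rewired (never recreating a dropped pair) and the same
fraction of non-anchor sites is replaced.

What a green test on this world establishes: correctness of the feature
algebra, the sampling contracts, the evaluation protocols and the
statistical calibration of the tests.  What it does not establish:
performance on real chromatin, where signal-to-noise, mappability
artefacts, anchor-width variation, and correlated histone landscapes are
all absent from the toy.

## Numerical conventions and edge cases

Absent signal is 0, not missing: features are always finite.  Conservation
means treat uncovered bases as 0.  Windows are clipped at coordinate 0.
Undefined relative fluctuation (0, 0) raises.  Inter-chromosomal BEDPE rows
are dropped with a logged count, not fatal; malformed rows fail with the
line number.  Serialized models embed the feature order and refuse
mismatched matrices instead of silently re-indexing.

## Known limitations

No BAM or .hic/.cool binary input (text interchange only, by design at this
stage).  The naive baseline pairs every forward motif independently; a
blocking variant (innermost pairs only) is available behind a flag because
the method's one-line published descriptions do not resolve it.  The Oti
baseline's percentile rounds use peak-intensity rank with coordinate
tie-breaks.  Negative sampling is uniform over feasible pairs, not
distance-matched to positives; on genomes much smaller than the defaults
the feasible pool can exhaust, which raises rather than silently
under-filling the quota.
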