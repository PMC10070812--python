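# Methods

This note documents the models and procedures `sescape` implements, the
defaults that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely
open.

## Coordinate and overlap conventions

All coordinates are 0-based half-open (BED convention); formats with other
conventions are converted at the boundary. Overlap everywhere means ≥ 1 bp
in half-open coordinates — adjacent intervals do not overlap. Chromosome
names are compared by exact string match; no "chr" aliasing is attempted,
so mismatched naming surfaces as empty joins rather than silent errors.
Strand is ignored for peaks and signal (H3K27ac is unstranded) and kept
only in the TSS annotation. narrowPeak summits are read but unused: peak
"center" is the interval midpoint, which is defined for any BED input.

## Peak landscape

`classify_peaks` is a per-chromosome sweep equivalent to an all-pairs
overlap scan (the test suite checks this equivalence). One peak overlapping
two partners yields two common *pairs*, but every peak counts once in
category totals, so |common(A)| + |A-specific| = |A| always.

Composite profiles bin the window [center − w, center + w) (default
w = 2000 bp) into equal bins and average the piecewise-constant track
signal by length within each bin, then across peaks. The profile reports
mean signal, not a kernel density; rescaling to a density is left to the
caller, since no transform from signal to "probability density" is
canonical.

## MA normalization

Read density is the length-weighted mean track signal over the peak (or,
for a common pair, over the union interval of the pair — the pair defines
the comparable region). With pseudocount c = 0.5,
M = log₂((x+c)/(y+c)) and A = ½·log₂((x+c)(y+c)). The global trend
M = a + b·A is fitted on common peaks only, by Huber robust regression
(tuning constant 1.345, via statsmodels RLM): common peaks are assumed
unchanged *on average*, and the robust loss keeps a differential minority
from dragging the trend. Normalization subtracts the fitted line. The
per-peak differential P-value is a two-sided exact binomial test,
X ~ Binomial(x̂+ŷ, ½) with p = min(1, 2·min(P(X ≤ x̂), P(X ≥ x̂))), applied
to length-weighted pseudo-counts (density × peak length, rounded) with the
fitted rescaling applied to the second condition; a zero total gives
p = 1. For Poisson-distributed pairs this test is slightly conservative,
which the suite asserts as an upper bound on the false-positive rate.

Note that the binomial form and the count scaling are this package's
declared choices: published MA-normalization tools agree on the (M, A)
model and common-peak fitting but differ in test details.

## Super-enhancer calling

Stitching is a single left-to-right pass per chromosome: a peak joins the
open region iff its start minus the region end is ≤ gap (default
12,500 bp). Gap is measured end-to-start in half-open coordinates, so
book-ended peaks have gap 0 and merge at any threshold ≥ 0. Regions never
span chromosomes.

Region signal is Σ over member peaks of density × length; inter-peak gaps
contribute nothing, so sprawling regions are not rewarded for span. Whether
to rank by summed signal or mean density is a genuine fork; summed signal
(the ROSE convention) is used.

The SE/LE cutoff is the discrete tangent construction: sort signals
ascending as y₁…yₙ, set slope s = (max − min)/n, and for each index i
count the points on or below the line of slope s through (i, yᵢ); the
index minimizing the count is the tangent point, ties taking the smallest
index (the most-SEs reading). The count uses the difference form
yⱼ − yᵢ ≤ s·(j − i) so the diagonal j = i is exactly on the line in
floating point. SEs are regions with signal *strictly above* the cutoff
value, so a flat landscape yields zero SEs. The construction is scale
invariant: multiplying all signals by k > 0 preserves labels.

No TSS-exclusion of promoter-proximal peaks is applied before stitching
(the classic ROSE option) and no input/control subtraction is performed;
tracks are assumed pre-normalized. Both are deliberate simplifications of
scope, not oversights.

## Gene assignment

Nearest-TSS with bedtools-closest gap semantics: distance 0 if the TSS
falls inside the region (half-open), otherwise start − tss upstream and
tss − end downstream. Ties break to the lexicographically smallest gene
id, making assignment deterministic. The distance cap defaults to 500 kb —
published enhancer-gene maps rarely state theirs, so the cap is a
prominent, documented parameter rather than a hidden constant. Summary
bins are [0], (0, 5 kb], (5 kb, 50 kb], (50 kb, cap]; a region whose
chromosome is absent from the annotation is unassigned, not an error.

## Differential expression

A deliberately transparent NB pipeline (no dispersion shrinkage, no
outlier filtering, no fold-change moderation), so that every number is
reproducible from the formulas:

- **Size factors**: median-of-ratios over genes with nonzero counts in all
  samples.
- **Dispersion**: per gene, pooled within-group sample variance s²
  (df = n₁+n₂−2) and grand mean m̄ of normalized counts give the moment
  estimate α̂ = max(0, (s² − m̄)/m̄²). With 2–3 replicates this raw
  estimate is extremely noisy — it is exactly zero for roughly half of
  null genes, which would wildly overstate significance. It is therefore
  *moderated* by flooring each gene's estimate at the across-gene median
  of the raw estimates (then at 10⁻⁸). Genes with genuinely high
  dispersion keep their own estimate; genes whose estimate collapsed to
  zero borrow the typical dispersion of the dataset. Measured at the
  simulated null (α = 0.1, mean 100, 3 vs 3), the Wald test's type-I
  error at nominal 0.05 is ≈ 0.05; the unmoderated estimator gives
  ≈ 0.12 (the Wald z is then essentially t₄-distributed), and replacing
  the normal reference by t₄ instead would make q < 0.01 unreachable at
  realistic effect sizes. The median floor is the smallest intervention
  that yields a test both calibrated and powered at these replicate
  numbers.
- **Wald test**: log₂FC = log₂((m̄_B + c)/(m̄_A + c)) with c = 0.5;
  delta-method SE from Var = m + αm²; two-sided normal p; BH q.
- **Thresholds**: two named presets, "results" (q < 0.01, |log₂FC| ≥ 1)
  and "methods" (q < 0.05, |log₂FC| ≥ 1); q is compared strictly, the
  fold change inclusively. Neither preset is chosen silently — callers
  pick one (the pipeline default is "results").

## Integration

Category-level expression shifts use the two-sided Mann-Whitney rank-sum
test: full enumeration of all C(n+m, n) group assignments (with 0.5 tie
credit) when both groups have ≤ 8 members, the normal approximation with
tie correction otherwise; the two paths agree within 0.02 at the 8 vs 8
boundary. "Rescued" genes are the three-way intersection of
condition-specific-SE-driven genes (deduplicated: a gene with several SEs
counts once), up-regulated in disease vs normal, and down-regulated on
treatment vs disease. Over-representation uses the hypergeometric upper
tail P(X ≥ k) against user-supplied GMT sets, each intersected with the
universe first; the universe defaults to all genes in the DE table.

## Motif enrichment

PWMs (probabilities with a 0.5 pseudocount over counts) are scanned as
log₂-odds against the background base composition; a sequence has a motif
iff some window on either strand scores ≥ 80 % of the maximum attainable
score; N bases score 0 (background-neutral). Enrichment is a one-sided
Fisher exact test of hit counts in targets vs background, BH-corrected
across the library, reported with the percentage of sequences carrying
each motif. Background defaults to per-sequence dinucleotide shuffles
(Altschul-Erickson random-Eulerian-walk construction, seeded), preserving
length, base and dinucleotide composition exactly. Both the 80 % threshold
and the background model are parameters, since no single convention is
standard; de novo motif discovery is out of scope.

## Synthetic data

The generator emulates a normal (A/N) vs disease (B/D) H3K27ac landscape
with a treated (T) arm in expression, on a toy genome of 3 × 5 Mb:

- **Landscape**: elements (single-peak slots and SE clusters) are placed
  left to right in seeded shuffled order, with inter-element spacing drawn
  above the 12.5 kb stitch gap so single peaks remain single stitched
  regions and each planted cluster stitches into exactly one region.
  Defaults: 500 common, 150 + 150 condition-specific peaks, 20 B-specific
  SE clusters of 5–15 peaks (gaps 0.5–3 kb). Peak densities are
  LogNormal(ln 3, 0.5) per bp; realized densities are Poisson around
  density × width; condition-B signal carries a global 2¹ bias (the
  disease condition's higher overall signal); cross-condition signal of
  specific peaks is 5 % of their own. SE cluster peaks are ~10× the median
  density, putting cluster signals far above the LE tail. Common peak
  coordinates are jittered ±50 bp per condition. One gene TSS is planted
  inside each SE cluster; 980 decoy genes are placed ≥ 5 kb away from all
  clusters. A "big-landscape" preset (3 × 6 Mb, ~1000 LE regions) exists
  for cutoff stress tests.
- **Counts**: NB with dispersion 0.02, base means LogNormal(ln 100, 0.8),
  3 replicates per condition, per-sample depth wobble LogNormal(0, 0.1).
  SE-linked genes carry planted up-regulation in D (log₂FC 1.5 in the
  default "moderate" preset, 3 in "strong"); 80 % of them return to
  baseline in T (the planted rescued set). 50 extra non-SE up- and 50
  down-regulated genes (half of the ups also reversed) keep the treated
  contrast from trivially equalling the SE truth. 2000 genes total.
- **Sequences**: 100 targets of 500 bp, i.i.d. bases at GC 0.4; an AP-1
  style 8-mer consensus (TGACTCAG) is inserted in 80 % of targets with a
  5 % per-position mutation rate; the PWM library holds the planted motif
  plus 7 random sharp decoys.

Each output stream draws from its own substream of the master seed, so all
outputs are pure functions of (config, seed) and regenerating one file
never perturbs another.

**What passing tests show — and don't.** The generator plants clean,
well-separated structure: peaks never overlap across elements, tracks are
piecewise constant over peaks with zero elsewhere, dispersions are
homogeneous across genes, and SE clusters are far above the LE signal
range. Recovery of this structure validates the *logic* of the chain
(classification, stitching, cutoff, assignment, testing, intersection), not
performance on real data, where peak boundaries are fuzzy, signal is
autocorrelated, dispersions vary per gene, enhancer-gene links defy
nearest-TSS, and SE tails are continuous. Reported sensitivities are upper
bounds on what the same settings achieve on real landscapes.

## Problem sizes and determinism

The default study runs in seconds: ~1000 peaks, 670 stitched regions, 2000
genes, 100 + 100 sequences, 8 PWMs. Calibration checks use 12,000 null
gene-tests and 2000-peak normalization instances. All randomness flows
from explicit seeds; reruns are byte-identical, and the pipeline report
embeds the config hash and seed for exact reproduction.

## Known limitations

- The DE stage is not a DESeq2 replacement: no per-gene dispersion trend,
  no shrinkage, no outlier handling. It is calibrated under homogeneous
  dispersion; strongly heterogeneous dispersion profiles will be tested
  against a partially pooled α.
- The binomial differential-peak test treats scaled densities as counts;
  it is conservative for overdispersed signal.
- Nearest-TSS assignment is a heuristic; no chromatin-contact information
  is used.
- bigWig tracks are not parsed; convert to bedGraph first.
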