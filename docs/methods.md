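# Methods

## Coordinate scaffolding

All coordinates are 0-based half-open internally (BED convention); BAM's
1-based convention is converted at the reader boundary. Four tables fix
the feature space: a chromosome table, an arm table, a 1 Mb bin
manifest, and a set of Alu-like regions.

The bundled hg19 presets are autosome-only. The arm preset lists 44
arms with the five acrocentric short arms (13p, 14p, 15p, 21p, 22p)
flagged as excluded, leaving 39 feature-emitting arms. The bin preset
tiles the 22 autosomes into 2,897 bins of 1 Mb and drops 422 of them via
a frozen exclusion BED — acrocentric p-arms, centromere gaps padded
symmetrically by a fixed deterministic rule, and the first/terminal bin
of every chromosome — leaving 2,475 kept bins, the width of the CNV
feature block. The exclusion list is a versioned data file constructed
once and shipped with the package, so the feature-space size is
reproducible bit-exactly; it is a practical mask in the spirit of
standard shallow-WGS bin filtering, not a re-derivation of any
particular tool's mappability track. Per-bin GC and mappability in the
preset are neutral placeholders (0.5 / 1.0) because no hg19 reference or
wig tracks are vendored; when a user supplies a reference FASTA,
`build_bin_manifest` computes GC per bin (fraction of G/C among non-N
bases) and applies the keep rules: mappability ≥ 0.9 and GC within
[0.28, 0.68] by default, both exposed in config.

## Fragment model and I/O

A fragment is the template between the two 5′ ends of a read pair:
interval `[leftmost start, leftmost start + TLEN)`. The BAM reader keeps
properly-paired, primary, non-duplicate pairs with MAPQ ≥ 30 (field
convention; configurable) and 0 < TLEN ≤ 1000; the BED reader accepts
the simulator's interchange format and behaves identically downstream.
Both termini carry a 5′ end motif: the left end reads the reference at
`[start, start+3)`; the right end is the reverse complement of
`[end−3, end)`, i.e. both motifs are 5′→3′ on their own strand. Both
ends contribute end-motif events by default (`both`), matching the
end-motif literature and doubling usable signal; `left_only` is
available in config. Motifs containing N are excluded from motif
analysis but the fragment still counts for CNV/FSD.

Depth down-sampling is Bernoulli thinning of fragments at a target
fraction computed from observed mean coverage (Σ lengths / genome
size), seeded and order-preserving.

## CNV profile

Per sample: midpoint bin assignment (a boundary-straddling fragment is
counted once, in its midpoint's bin) → LOESS of count on GC over kept
bins (span 0.75), rescaled by `median/fit` → division by mappability →
scaling to sum 1 → division by the panel of normals → log2 → median
centering, so a copy-neutral genome sits at 0. The PoN is the per-bin
median of ≥ 3 healthy profiles processed the same way, with zero
medians floored to the smallest positive value. Where the LOESS fit is
non-positive, it is floored at 10⁻³ of the median count (with a
warning) rather than dropping bins, keeping the feature block at a
fixed width so cohort matrices stay aligned. The profile is left
unsegmented: the classifier consumes the per-bin log2 ratios directly,
and no absolute copy-number or tumor-fraction calling is attempted.
Closed form used in tests: a CN = 3 segment in a diploid background at
tumor fraction tf has expected ratio `1 + tf/2`, i.e. log2 ratio
`log2(1 + tf/2)`.

## Fragment size distribution

Lengths are histogrammed per included arm in 24 half-open 5 bp bins
starting at 110 bp. The nominal size range 110–220 bp does not divide
evenly into 24 five-bp bins; this package fixes 24 bins covering
[110, 230) so that the arm-major feature layout is exactly
arms × 24 (936 under hg19). Counts are GC-corrected per size bin by
LOESS across arms (arm GC computed from the reference, N excluded;
skipped with a warning below 10 arms or under degenerate GC), then
z-scored per feature. The z statistics (mean, sample SD with ddof = 1)
are fitted on the **training split only** and frozen into the model —
cohort-wide standardization is available as `normalization: all` for
replication, but leaks validation information and is not the default.
Zero-variance features are flagged and emit z = 0.

## End-motif (FRAGMA) features

Events are fragment 5′ ends whose terminal base lies inside an Alu
region. Nine Alu-wide features: the frequencies of the four CGN and
four NCG motifs among all events, plus ΣCGN/ΣNCG. Twelve CGCG-context
features: every CGCG occurrence inside a region defines four cleavage
registers per strand, identified by the motif each produces —
`p−1 → NCG` (split by the upstream base), `p → CGC`, `p+1 → GCG`,
`p+2 → CGN` (split by the base after the CGCG). CGCG is its own reverse
complement, so the minus-strand registers mirror these at `p+4…p+1`
with complemented N bases; an event matches a register only on the
matching strand. The ten register counts are divided by the total
number of register events, so they partition to 1; CGC/NCG and CGN/CGC
count ratios complete the 21. Design choices: the register denominator
is CGCG-context events (config allows all-Alu events); overlapping CGCG
occurrences resolve first-come left-to-right, so each (position,
strand) belongs to one register; zero denominators fall back to a
pseudo-count of 1 with a warning — the feature matrix never contains
NaN, at the cost that pure-ratio features lose scale invariance in the
degenerate all-numerator case.

## Ensemble

Six learner families per feature block: GLM = standardized L2 logistic
regression (C = 1); XRT = extremely randomized trees (200 trees, √p
features); DRF = random forest (200 trees); DeepLearning = standardized
MLP (32×16, α = 10⁻³); GBM = gradient boosting (100 trees, depth 3);
XGBoost (150 histogram trees, depth 4). These defaults are sized for
cohorts of order 10²; an optional random grid (config `grid_budget`)
draws per-family candidates and keeps the best by out-of-fold AUC.
Stratified 5-fold CV produces out-of-fold scores for every training
sample; each model is then refit on the full training split for
deployment. The stacked score is the unweighted mean of base scores
over the best of the 7 non-empty block subsets by out-of-fold AUC (ties
prefer more blocks); the mean rule is the default and a second-layer
logistic meta-learner (`meta_glm`) is available because the two are both
defensible stacking rules for this design. Scores are clipped to [0, 1].

The decision cutoff is the smallest observed-score threshold placing at
least ⌈0.95 · n_healthy⌉ training healthy samples strictly below it
(score ≥ cutoff ⇒ cancer); when no observed score suffices, the
smallest representable value above the maximum is used. The cutoff and
all normalizers (PoN, FSD statistics) derive from the training split
only; validation samples touch no fitted parameter.

## Evaluation

AUC is the Mann–Whitney statistic (ties ½), which equals the
trapezoidal area of the assembled ROC curve; the curve itself comes
from scikit-learn with no point thinning so the identity holds exactly.
Confusion metrics follow the standard definitions; confidence intervals
are exact Clopper–Pearson by default (beta quantiles), Wilson
optionally. Ties at the cutoff count as predicted positive. Stratified
reports give per-stratum sensitivity with strata under 5 positives
flagged.

## Synthetic cohorts

The generator emulates the three signal axes the extractors assume,
scaled to desk size:

* **Genome**: 4 chromosomes × 3 Mb by default (8 arms, 12 bins); a
  smooth GC field (clipped random walk over 10 kb windows, default
  [0.38, 0.52]); 30 planted 300 bp Alu-like repeats per Mb with CGCG
  blocks planted inside (≈ 10 per repeat at the default enrichment 5).
* **Healthy fragments**: lengths from a truncated normal mixture —
  mononucleosomal mode 167 bp (SD 10) with a 5% dinucleosomal mode at
  320 bp (SD 30), clipped to [60, 500]; origins uniform; a baseline 2%
  of left ends snap to the nearest CpG cytosine inside an Alu (within
  25 bp), giving healthy samples a nonzero CGN end-motif rate.
* **Tumor fragments** (a cancer sample draws each fragment from the
  tumor component with probability tf): origins weighted by planted
  segment dosage (copy numbers 0/1/3/4; default one CN 3 gain, one CN 1
  loss, one CN 4 gain), the mononucleosomal mode shifts to 145 bp
  (SD 12) while the dinucleosomal mode persists unchanged — so a
  CNV-only or motif-only configuration leaves the size distribution
  exactly healthy — and the CpG snap probability is multiplied by
  `motif_effect` (default 4).

A cancer sample at tf = 0 is distributionally identical to a healthy
sample, which is the basis of the null-calibration checks. Default
cohort shape is 119 + 112 training and 85 + 79 validation; the
simulator default depth is 5×, which on the toy genome gives per-bin
counts (~29 k) comparable to a real shallow-WGS study. Test and
acceptance cohorts run at 1× — one of the down-sampled depths the
method is meant to tolerate — with 60 + 60 / 30 + 30 samples, keeping a
full multi-seed pipeline evaluation to minutes on one CPU. "Stage" in
synthetic cohorts is the tumor-fraction tertile, used only to exercise
stratified reporting.

What the simulator does **not** model: nucleosome-ladder size
structure, sequence-composition bias of real cleavage, GC-coverage
coupling (coverage is uniform given dosage, so the LOESS corrections
are exercised as near-identities at toy scale), real Alu consensus
sequences, sequencing error, or inter-sample technical batch effects.
Passing tests therefore demonstrate correctness of the computational
pipeline and its sensitivity to the three planted signal axes — not
clinical performance on real plasma.

## Numerical conventions

LOESS is statsmodels `lowess` (span 0.75) interpolated to the observed
abscissae, with non-positive fits floored. Degenerate inputs (single
GC value, < 20 bins, < 10 arms, all-identical training features, zero
denominators) produce warnings and documented fallbacks, never NaN.
Every stochastic step — genome realization, fragment sampling, fold
assignment, learner seeds — derives from explicit integer seeds, and
cohort generation is deferred per sample (regenerated from per-sample
seed entropy), so cohorts of any size are reproducible without holding
fragments in memory.

## Known limitations

* The hg19 kept-bin mask reproduces a standard bin count by frozen
  construction; it is not a lift of any published mappability track.
* The per-bin log2 profile is unsegmented and unsmoothed; no HMM.
* The FSD z-scores encode arm-level dosage as well as size shape; this
  is inherent to count-based size histograms and mirrors the original
  design, but means the FSD and CNV blocks are correlated for CNV-rich
  samples.
* Hyperparameter search defaults to fixed per-family settings; the grid
  exists but is budget-capped and off by default.
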