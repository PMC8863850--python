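# Methods

## Problem and model

The package predicts a binary case-level endpoint — lymph-node metastasis
(LNM) of T1 colorectal cancer — from tile-level probabilities derived from
digitized H&E slides. The model is deliberately two-stage:

1. tile classifiers turn pixels into per-tile probabilities (cancer-class
   probability `p_c`; metastatic probability `p_m` on cancer tiles), and
2. a case-level random-forest ensemble turns the *distribution* of those
   probabilities within a case into a single score.

The intermediate tile probabilities are the interpretability device: group
membership (A–E) and the red/green slide maps show *which* tissue drove a
score.

## Tiling and tissue filtering

Slides are tessellated into non-overlapping squares (default 299 px =
273 µm at the assumed scan resolution; overridable). Edge remainders are
dropped — padding would fabricate tissue. A tile is kept iff the minimum
of its 8-bit luminance (BT.601 weights, round-half-up; fixed so results
are bit-stable) is ≤ 110. The keep-if-`min ≤ 110` direction and the
inclusive boundary are documented conventions: a sufficiently dark pixel
is taken as evidence of at least one nucleated cell. Raising the
threshold can only grow the kept set (tested as a monotonicity property).

## Tile classifiers

The reference implementation is a one-hidden-layer perceptron (64 units,
Adam, default 40 epochs at learning rate 0.01, batch 64) over a compact
tile representation: an 8×8 area-averaged downscale of the tile plus nine
translation-invariant statistics (mean, SD, five intensity quantiles,
mean and SD of the gradient magnitude), standardized on the training set.
Raw pixel positions are nearly pure noise for texture identity, which is
why the summary statistics — not the pixel grid — carry most of the
signal; the statistics head is what lets the model generalize instead of
memorizing blob positions. A convolutional backbone can be substituted
behind the same contract (probability-simplex outputs, per-epoch
accuracy/cross-entropy curves, single-seed reproducibility); nothing
downstream depends on the classifier's internals.

Classifier #2 is trained only on tiles with `p_c` strictly above 0.8 and
inherits each tile's *case* outcome as a weak label. Weak labels are
noisy by construction (negative-looking tiles occur in positive cases),
so tile-level accuracy well below 1 is expected even for a perfect
model. All train/validation splits are stratified by case, never by
tile: tiles within a case are correlated and splitting them leaks
outcome information.

## Probability groups and case features

Cancer tiles for scoring are those with `p_c > 0.5` (strict, matching the
documented cutoff wording; the training cutoff 0.8 is strict too). Groups
partition `p_m`: A `< 0.1`, B `[0.1, 0.2]`, C `(0.2, 0.8)`, D
`[0.8, 0.9]`, E `> 0.9`. Ties at the four boundaries are assigned to the
informative extreme groups (B/D); `boundary_to_extreme=False` flips them
into A/C/E for sensitivity analysis. The mirror symmetry
`group(p) = mirror(group(1−p))` (A↔E, B↔D, C fixed) is enforced by test.

The 18-feature case vector comprises: ordinal location code (1/2/3);
counts of cancer, metastasis-predicted (`p_m > 0.5`) and
negative-predicted tiles; the five group counts; the two percentage
splits; mean `p_c`; mean `p_m` over met-predicted tiles and mean
`1 − p_m` over negative-predicted tiles; the three matching sample SDs
(n−1; a single tile gives SD 0); and the probability score summary
`PSS = Σ p_c · p_m`. Three open choices are resolved as follows and kept
configurable: the 18th slot is the Group C count (completing the A–E
partition); the PSS "summary" is a sum, since a mean would duplicate
existing features; location is one ordinal feature, because one-hot
encoding would break the 18-parameter arithmetic. SDs are computed after
the 0.5 cancer cutoff, on the same tile set as every other feature. A
case with no cancer tile after the cutoff is excluded with an explicit
flag — scoring it would require inventing features.

## Ensemble scoring

Class imbalance (~10:1) is corrected by oversampling the minority class
with replacement to equality; only the count is guaranteed, not coverage
of every minority case. 500 candidate forests (depth 6, 60 trees — the
tuned defaults; a (depth, trees) sweep utility reports the full AUC
surface for both splits with ties broken toward the smaller model) are
trained on the balanced table, differing only by seed. Selection AUC is
computed on the **original unbalanced** cases: scoring on the oversampled
table would credit memorization of duplicated positives. The top 20 are
retained (stable sort, candidate order breaks ties) and a case's RF score
is the maximum member probability — a sensitivity-first aggregation that
raises scores, accepted because the clinical cost asymmetry is between a
missed metastasis and an unnecessary surgery. Feature importances are
impurity-decrease importances averaged over members (they sum to 1).

All 500 member seeds derive from one master seed via a seed sequence, so
the entire sweep is reproducible from a single integer.

## Evaluation

AUC is the tie-corrected Mann–Whitney concordance (identical to the
trapezoidal ROC area; both are cross-checked against brute-force pair
enumeration in tests). The decision cutoff is the balanced error point —
the candidate threshold minimizing |sensitivity − specificity|, ties to
the lower threshold; the published operating point 0.70 is exposed as the
package default for binary decisions. Risk tiers are half-open
[0, 0.7), [0.7, 0.8), [0.8, 0.9) with [0.9, 1.0] closed at the top; an
empty tier reports NA, never 0%. Group comparisons use the
pooled-variance Student t (raw samples or (mean, SD, n) summaries) and
the two-sided Fisher exact test (p sums hypergeometric tables with
probability ≤ observed — conventions differ, so this one is stated; the
odds ratio is the sample OR, reported as ∞/0 when a zero cell makes it
unbounded rather than silently continuity-corrected).

## Synthetic data: what it does and does not emulate

The generator produces the two inputs the pipeline needs, with the
statistical structure the method assumes — not histologic realism.

**Texture tiles.** Ten procedural classes (flat background gray with dark
elliptical blobs and Gaussian noise; per-class gray level, blob density
and radius). They are separable by construction; the `background` class
is pure white and therefore always rejected by the pixel threshold.
Passing classifier tests show the training harness works on separable
textures; they say nothing about performance on real H&E tiles.

**Cohorts.** Cases are LNM-positive with prevalence 0.078. Per-tile
metastatic probabilities follow a two-level truncated-normal hierarchy:
case means are drawn around the class-conditional mode (0.53 negative,
0.73 positive — the documented modal tile probabilities), then tiles
around the case mean. Truncation to [0, 1] uses the exact conditional
(equivalent to resampling). A truncated normal, not a beta, was chosen
because the observed tile-probability histograms are bell-shaped. The
within-case SD (0.12) reproduces a heavy Group C mass; the between-case
SD (0.06) is an additional knob the published work does not constrain —
both are free calibration parameters, stated as such. Tiles per case are
log-normal (median 400, log-SD 0.6 — a scale at which cohort generation
and scoring stay interactive while keeping several hundred tiles per
case). Cancer-class probabilities are Beta(6, 1.5), skewed toward 1 as
expected for tiles already routed through a cancer classifier. Locations
are drawn per class from the published training-set frequencies
(negatives 193/138/174 over groups 1/2/3; positives 10/9/24), giving the
rectal enrichment among positives.

Under these defaults the feature→ensemble pipeline recovers the outcome
signal with held-out AUC ≥ 0.8 (typically ≈ 0.95 at n = 600), and
label-shuffled nulls sit at chance. That demonstrates the machinery is
correctly wired, not that clinical slides would yield such AUCs: the
synthetic effect size is an assumption, real tile probabilities are not
i.i.d. within a case, and stain/scanner variability is absent entirely.

## Numerical and design notes

- Strict `>` for both cancer cutoffs; a tile exactly at a cutoff is
  excluded.
- Candidate thresholds for ROC/balanced-cutoff sweeps are the distinct
  scores plus one value below the minimum (all-positive calls included);
  predictions are positive at score ≥ threshold.
- `stratify` validates that the tier map partitions the score range and
  conserves the cohort count.
- Pipeline runs write a manifest with per-stage counts and SHA-256 hashes
  of every artifact; rerunning with the same config and seed reproduces
  the hashes exactly, and any stage can be resumed from existing
  artifacts.
- Problem sizes in the shipped tests and acceptance script (600-case
  cohorts, 100 tiles per texture class, 500-candidate ensembles) were
  chosen so the full pipeline exercises its defaults while remaining a
  few minutes of single-CPU compute.

## Known limitations

- The MLP tile classifier is a reference implementation for the contract;
  it is not expected to transfer to real histology without replacing the
  featurization with a learned (convolutional) one.
- The published clinical accuracies (tissue classifier 0.980, tile-level
  LNM 0.740, case AUC 0.971/0.760) depend on a non-public slide cohort
  and trained weights and are out of scope here; no synthetic setting can
  validate them.
- Oversampling duplicates cases; selection AUC on unbalanced cases
  mitigates but does not remove the optimism of training-set member
  selection. The selection set is injectable
  (`train_rf_ensemble(selection_features=..., selection_labels=...)`), so
  a held-out fold can be used instead when enough cases exist.
- The 18-parameter enumeration resolves a genuinely ambiguous published
  list; the schema is data-driven so alternatives are one-line changes.
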