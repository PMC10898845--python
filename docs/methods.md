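# Methods

## Data model

A body-sensation map (BSM) is a signed intensity field on the in-mask
pixels of a body silhouette: positive where the subject feels activity
increasing, negative where decreasing. The interchange format is a paint
-event table (`subject_id, stimulus, polarity ∈ {+1,−1}, row, col,
intensity ∈ (0,1]`, 0-based row-major coordinates, origin top-left) plus
a cohort table of questionnaire totals and a template (binary PNG mask +
JSON landmark sidecar). Raw exports of browser-based painting tools can
be converted to this schema; the package makes no claim about any
particular tool's native format.

## Reconstruction

Each event deposits its intensity on pixels within `brush_radius`
(Euclidean) of its coordinate; overlapping deposits take the **maximum**,
capped at 1 — a painting metaphor where going over a stroke twice does
not double its intensity. Activation and deactivation grids are kept
separate, masked to the outline, combined as activation − deactivation,
and smoothed with an isotropic 2-D Gaussian (default σ = 5 px), kernel
truncated at radius ⌈3σ⌉, normalized to unit sum, zero-padded at
borders. Combination happens **before** smoothing by default; a
`smooth_then_combine` switch exists for sensitivity checks (the two
differ only at float precision because smoothing is linear). PPP (the
proportion of in-mask pixels painted) is always computed on the raw,
pre-smoothing maps, per polarity.

QC retains subjects completing at least `min_maps = 17` of 21 maps
(strict less-than exclusion). Visual screening of anomalous drawings is
inherently manual; the package accepts an injectable flagged-subject
list and additionally *warns* (never auto-excludes) when a map's painted
support forms a perfect filled rectangle, a screenshot-style artifact.

## Pixelwise statistics

One-sample t against zero per pixel within each group, and a
pooled-variance two-sample t (df = n₁+n₂−2, positive = first group
higher) for the contrast; Welch is available by option but pooled is the
default, matching the df = n₁+n₂−2 convention of the questionnaire
comparisons. Zero-variance pixels are not dropped: with zero mean they
are clean nulls (t = 0, p = 1); with nonzero mean they are flagged
degenerate (p = 0) and carried in a separate mask. Multiplicity is
handled per map — the Benjamini–Hochberg family is the set of in-mask
pixels of one stimulus × one group/contrast, not pooled across stimuli.
All in-mask pixels enter the family (the alternative of excluding
pixels nobody painted would shrink the family and is deliberately not
done; the degenerate-pixel rule covers them).

## Percentile grouping

The low group is the bottom `low_pct` block: scores at or below the
nearest-rank `low_pct` quantile. The high group is the complement of the
bottom `high_pct` block: scores at or above the *next* order statistic
past the nearest-rank `high_pct` quantile. Ties at either cutoff value
join the extreme groups, so with coarse integer scores the extreme
groups can exceed a third of the sample — the intended behaviour for
questionnaire totals where many subjects sit exactly at a cutoff. A
linear-interpolation quantile is available via `method="linear"`.

## Mixed ANOVA

Split-plot decomposition with one between factor (group) and one within
factor (stimulus): the between effect is tested against the
subjects-within-groups mean square; the within effect and interaction
against the subject × level residual. Effect size is classical
η² = SS_effect/SS_total (partial η² by option). Sphericity is assessed
with Mauchly's W on the **pooled within-group** covariance (df = N − g;
this matches the split-plot error structure — packages that center on
grand means instead give slightly different W and ε on grouped data,
while the F statistics, SS and dfs agree exactly). When Mauchly's
p < 0.05 both dfs of the within and interaction effects are multiplied
by the Greenhouse–Geisser ε̂ = (Σλ)²/((k−1)Σλ²), λ being the eigenvalues
of the contrast-transformed covariance; ε is exactly 1 when k = 2.
Subjects missing any within level are dropped listwise and counted in
the result. With unequal group sizes the weighted (cell-mean) sums of
squares are used; the validation suite exercises balanced designs.

## Classification

Complete classification: one multiclass model discriminating all 21
stimuli, samples = subject × stimulus smoothed map vectors. Per
iteration a fresh stratified 5-fold split is drawn (derived
deterministically from the master seed via an iteration counter); per
fold, PCA to 30 components and LDA are fitted on the training rows only
— the leakage-free default; `pca_scope="global"` exists to demonstrate
what leakage changes. Rows of one subject may fall into different folds
(the sampling unit is the map); `group_by_subject=True` switches to
subject-grouped stratified folds. If the within-class covariance in the
reduced space is rank-deficient, a trace-scaled ridge (shrinkage 10⁻⁶)
is applied with a warning. Chance level is 100/21 ≈ 4.76%.

The group comparison runs a one-way ANOVA over iteration-level overall
accuracies (between df 1, error df 2n−2) and a full mixed group × BSM
model treating iterations as sampling units. That df structure treats
CV iterations as independent, which is anticonservative since all
iterations resample the same subjects; the result therefore also carries
a subject-free label-permutation p-value as a conservative check, and
reports print this caveat.

## Synthetic cohorts

The generator emulates the structure the analyses are designed to
detect, not the mechanics of painting (no strokes, no reaction times,
no item-level questionnaire responses):

- each stimulus has a canonical topography of signed Gaussian blobs
  anchored to landmarks (happiness whole-body positive; sadness limb
  deactivation + chest activation; hunger abdominal; racing heart
  chest-focal; the neutral state lowest-amplitude in the emotion block);
- subject map = topography with per-subject blob-center jitter and
  log-normal amplitude jitter, plus three noise layers: a per-subject
  smooth "style" field shared across that subject's 21 maps
  (SD 0.12), a per-map smooth field (SD 0.18; both spatially correlated
  at σ = 6 px so they survive the analysis smoothing, emulating
  stroke-scale idiosyncrasy), and iid pixel noise (SD 0.03);
- high-group subjects blend their topography toward a fixed shared
  head+chest template with weight w (default 0.5) and scale the positive
  part by the extent gain κ (default 1.3) — producing, respectively, the
  higher between-map similarity / lower classification accuracy and the
  larger activation PPP expected of less-differentiated responders;
- pixels whose latent |intensity| exceeds `paint_threshold = 0.15`
  become events with intensity min(|latent|, 1); each subject × stimulus
  map drops out with probability 0.03 (mean completion ≈ 20.4 of 21);
- questionnaire totals are drawn from normals at the published group
  means/SDs (low drinkers AUDIT 2.62 ± 1.18, high 10.53 ± 3.59, TAS
  total 39.41 ± 11.99 vs 44.07 ± 11.31, …), rounded to integers and
  clamped — not resampled — to instrument ranges; age and gender are
  exchangeable nuisance columns at the published proportions.

Noise scales were fixed once, as values that place map discriminability
between ceiling and chance at desk-scale sample sizes; they are
generator conditions, not fitted quantities. Per-subject random streams
are keyed by the subject's **rank within group**, so the null
configuration (w = 0, κ = 1) paints literally identical low/high groups
— the symmetry the recovery tests rely on.

What passing tests on synthetic data do *not* show: that real painting
data satisfy the generator's assumptions (pixelwise Gaussian noise,
blob-shaped topographies, a single shared confusion template, dropout
independent of subject traits). Synthetic validation establishes that
the estimators recover known structure in the direction and order
expected, not that real-data effect sizes will match.

## Problem sizes and determinism

Desk-scale defaults use a 160 × 64 template (≈ 3.6 k in-mask pixels);
the full-scale silhouette used with real data (≈ 50 k pixels) is
supported by the same code path. The validation suite runs the recovery
cohort at 40+40 subjects with 50 CV iterations and the calibration nulls
at 200 (FDR) and 500 (ANOVA type-I) replicates — sizes chosen so the
whole suite completes in minutes while keeping Monte-Carlo error small
relative to the tested margins. A single master seed fans out to named
sub-seeds (simulation, per-group classification, permutations) recorded
in the report; statistics tables are written with a fixed float format,
so a rerun with the same seed is byte-identical.

## Known limitations

- The mixed ANOVA covers one between and one within factor only (the
  designs used here); no multivariate or Bayesian variants.
- Cosine similarity defaults to unthresholded group-level t-maps; group
  mean maps are available by option, and thresholded variants are not
  implemented.
- FDR is the only multiplicity correction (no cluster-extent or
  permutation-based pixel inference).
- The iteration-level accuracy ANOVA inherits the anticonservative df
  convention described above; treat its p-values as descriptive and use
  the permutation p for inference.
- Real-data exclusion counts, per-stimulus accuracies and pixel maps
  depend on the deposited data and are out of scope here.
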