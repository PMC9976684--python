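# Methods

This note records the statistical procedures, default parameters, and design
choices of the pipeline, and what the synthetic cohorts can and cannot show.

## Synthetic cohorts

**Model.** Serum MS intensities behave multiplicatively, so a feature *f* in a
sample of group *g* is drawn as

    x = exp( mu_f + log FC_g(f) + eps ),   eps ~ Normal(0, sigma)

with a per-feature baseline `mu_f ~ Normal(base_log_mean, feature_log_mean_sd)`
drawn once per cohort. Defaults: `base_log_mean = 14` natural-log units
(median intensity ≈ 1.2 × 10⁶, a typical MS1 peak-area scale),
`feature_log_mean_sd = 1.5`, within-group `sigma = 0.35` (≈ 36% CV, the upper
end of what label-free serum workflows report), and 5% of cells missing
completely at random. An intensity-dependent missingness option (logistic in
centered log intensity) exists but is off by default. Group sizes default to
the target study design: training CON/NS-CAP/S-CAP = 15/15/20, validation =
37/39/53; layers default to 500 proteins and 2500 metabolites.

**Planted effects.** Fold changes are specified relative to CON for NS-CAP
and S-CAP separately, constrained by pattern: increasing
(`fc_s ≥ fc_ns > 1`), decreasing (`fc_s ≤ fc_ns < 1`), inverted-V
(`fc_ns > 1`, `fc_s < fc_ns`), flat (both 1). The default layout plants
~10% non-flat features per layer, split evenly over four trend patterns —
two increasing variants with distinct shapes (early rise 1.8→2.0, late rise
1.3→2.0), one decreasing (0.6→0.5), one inverted-V (2.0→0.9) — plus five
panel markers (2 protein, 3 metabolite) with peak fold changes in 3–5.

The panel markers are deliberately laid out so that **each pairwise contrast
is covered by at least one marker whose |log FC| is ≈ 4× the within-group
log-sd**: a severity protein (1.2→5.0; S-vs-NS log-ratio 4.1σ), an infection
protein (4.0→4.5; NS-vs-CON 4.0σ), a decreasing metabolite (0.25→0.20), an
inverted-V metabolite (4.0→0.95; S-vs-NS 4.1σ), and an increasing metabolite
(2.5→5.0). This is what makes near-complete three-class separation of a
50-sample training cohort achievable by a small tree, while the FC ≤ 2
background decoys keep the ranking stage non-trivial.

**Clinical indices.** PCIS, TT, FIB, and FDP are generated as linear
transforms of a source feature's standardized log intensity plus Gaussian
noise sized via the bivariate-normal relation
`rho_pearson = 2 sin(pi * rho_spearman / 6)` so the population Spearman
correlation hits a target (default |rho| = 0.6; PCIS is negatively coupled to
the severity marker since the score falls as illness worsens).

**What the generator does not emulate:** pathogen heterogeneity within
groups, correlated feature blocks (co-regulated pathways), batch or
run-order drift, intensity-dependent variance, or peptide-to-protein rollup.
Passing recovery tests therefore shows the pipeline's statistics behave
correctly under the stated noise model, not that the specific markers or
effect sizes would replicate in patients.

## Differential abundance

Per contrast (numerator, denominator group), the fold change is the ratio of
raw arithmetic group means with missing values excluded per group. The test
is a two-sided unpaired Welch *t* on raw intensities (a log2 option exists
and is recorded in provenance); BH q-values are computed across all testable
features of the layer-contrast. The calling rule is `FC > 1.5 or FC < 0.67`
with **raw p < 0.05** — both thresholds strict, boundary cases not
significant. The raw-p gate is the default because that is the printed rule
of the workflow this reproduces; gating on q instead is one flag
(`gate="q"`). A feature is skipped (logged, with reason) for a contrast when
either group has fewer than 2 present values or both groups have zero spread.

Calibration caveat: Welch's *t* on raw log-normal intensities at n ≈ 15–20 is
slightly conservative-to-anticonservative depending on skew; on flat features
of the planted benchmark the observed p < 0.05 rate is ≈ 0.04–0.06, inside
the empirical 99% band from 200 regenerated cohorts (asserted in the tests).

## PLS-DA

Two-class PLS-DA encodes classes as ±1 and regresses the centered response on
centered, unit-variance-scaled features by NIPALS with deflation of X only
(max 500 inner iterations, tolerance 1e-10; with a single response the inner
loop converges in one pass). Two components are fitted by default, matching
2-D score plots; each weight vector's largest-magnitude element is made
positive for reproducible signs. R²Y(a) = 1 − RSS(a)/TSS on training data.

Q² uses stratified k-fold CV (default tenfold, seeded): centering and scaling
are re-estimated inside each training fold (a deliberate leak-the-scaling
option exists solely so a regression test can verify leakage changes the
answer), held-out samples are predicted on the ±1 scale, and
Q²(a) = 1 − PRESS(a)/TSS with TSS from the full centered response. PRESS ≥
RSS, so Q² ≤ R²Y at every component count. The PRESS/TSS convention is
declared, not inferred from any external tool.

## Trend clustering

Differential features are summarized as (CON, NS-CAP, S-CAP) group-mean
profiles, each standardized to zero mean and unit **sample** sd (so means
(1,2,3) standardize to (−1,0,1), the Mfuzz convention); constant profiles are
excluded and logged. Fuzzy c-means uses k = 4 (four patterns are expected),
fuzzifier m = 1.25, tolerance 1e-9, max 200 iterations; memberships are
computed in log space (softmax form) so small fuzzifiers do not overflow, and
a profile coinciding with a center takes membership 1 (limit convention).
Centers initialize from k distinct profiles drawn by the seeded generator,
ties broken by lowest row index.

Cluster centers are labeled by shape with a slack of 0.1 standardized units
(increasing: no step drops more than the slack and the net rise exceeds it;
decreasing mirrored; inverted-V: middle tops both ends by more than the
slack; otherwise "other"). Features inherit their max-membership cluster's
label only when that membership ≥ 0.5. As m → 1⁺ the assignment approaches
hard k-means (verified against a same-init k-means oracle at m = 1.01).

## CART and panel discovery

The classification tree is deterministic best-first CART: greedy binary
splits over all (feature, midpoint-threshold) pairs minimizing weighted Gini
impurity; growth stops at the terminal-node cap, pure nodes, or a minimum
leaf of 2. The cap — 6 terminal nodes for the combined panel tree — is the
only capacity control (no cost-complexity pruning). All ties break
deterministically (lower feature index, then lower threshold; earlier node
first), so larger caps extend smaller trees and training accuracy is
monotone in the cap.

Candidate ranking uses one-vs-one ROC AUCs on the three pairwise contrasts
with automatic orientation, ranked by the **maximum pairwise AUC** (ties by
|log2 FC|, then feature id), gated by AUC and FC floors (defaults: protein
AUC ≥ 0.8 capped at 9 candidates, metabolite AUC ≥ 0.9 capped at 4, both
FC floors 1.5); an annotation gate (immunity / infection / death-related
flags) is available. Selection is two-stage: a per-layer tree on that
layer's candidates whose split variables (shallowest first, capped by the
layer budget 2 proteins / 3 metabolites) become the layer's markers, then a
combined tree on the union. The panel's `markers` are exactly the combined
tree's split variables; the (possibly larger) stage-1 union is kept as
`selected_markers` because the combined tree may legitimately cover all
three contrasts with fewer variables — shrinkage is logged, never silent.

Matrices fed to trees and classifiers are kNN-imputed (k = 5, log scale):
a global-median imputation would park a missing cell in the between-group
gap of exactly the discriminative markers under study. The five-classifier
benchmark (L2 logistic regression C=1, 100-tree random forest, linear SVM
C=1, 5-NN, unconstrained Gini decision tree; scale-sensitive models behind a
per-fold standard scaler) runs on identical stratified tenfold splits with a
recorded seed; folds exceeding the smallest class are reduced with a warning.

## Independent validation

The panel is frozen before any validation access — structurally: training
stages only ever receive a view restricted to the training cohort, a config
pointing a training stage at validation data raises a leakage error, and the
report is byte-identical across reruns of the same config. At validation,
each sample routes through the frozen tree; a sample missing any marker value
is excluded from metrics and logged; a missing marker column is a hard error
naming the marker. Per-marker AUCs keep the orientation fixed at training
(an anti-correlated marker can legitimately score < 0.5). The combined-panel
ROC score is the terminal-node class proportion of the contrast's positive
class; each pairwise contrast drops the third group. Combined AUCs carry
stratified nonparametric bootstrap percentile intervals (default 2000
replicates, ≥ 200 required, seeded); stratified resampling keeps both
classes in every replicate.

## Enrichment

Over-representation is the one-sided hypergeometric upper tail
P(X ≥ k) with sets intersected with the background before testing and BH
adjustment across tested sets. The background defaults to all testable
features of the layer — not a genome — and is configurable; the default
synthetic run tests the differential features against gene sets built from
the planted trend patterns.

## Problem sizes and determinism

Default analyses run the full study (500 + 2500 features, 50 + 129 samples)
in well under a minute on one core; the test suite additionally uses a
down-scaled design (8/8/8 and 10/10/10 samples, 40 + 80 features) for
end-to-end determinism checks and 200 regenerated benchmark cohorts for the
null-calibration band. Every stochastic stage takes an explicit seed; a
single master seed derives per-stage seeds, and regeneration with the same
seeds is byte-identical.

## Known limitations

- Two-class PLS-DA only (no multi-class, OPLS-DA, or VIP scores).
- CART has no surrogate splits; validation samples with missing marker
  values are excluded rather than routed.
- No normalization is applied by default (total-intensity scaling is
  available behind a flag); batch correction is out of scope.
- The enrichment stage tests set membership only — no ontology topology or
  term-redundancy handling.
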