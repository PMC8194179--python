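# Methods

This note documents the models behind each stage, the tunable parameters
and their defaults, what the synthetic generators do and do not emulate,
and the numerical choices made where the design was open.

## Invasion scoring

A clone's spheroid invasion assay yields an area-versus-time series
(hourly or 6-hourly frames over 48 h, arbitrary area units). Two summary
statistics feed the invasion factor:

* **Onset time t (h).** The earliest frame whose area exceeds
  (1 + θ) × baseline — baseline being the area at t = 0 — and stays above
  that threshold through the end of the series, with a minimum run length
  of `consecutive` frames. Defaults: θ = 0.05, consecutive = 2, both
  configurable. Requiring persistence to the end, rather than any two
  frames, reflects that invasive growth does not revert and makes the
  detector robust to isolated noise excursions; with a single noisy frame
  as baseline, a two-frame rule alone triggers early on a few percent of
  2%-noise series. The detector is invariant under uniform rescaling of
  the areas.
* **Relative invasion area A.** Fold-area at 48 h (area(48)/area(0),
  linearly interpolated between bracketing frames when 48 h is not
  sampled) divided by the cohort mean fold-area, so mean(A) = 1 over the
  cohort. The normalization is a design choice — the alternative readings
  (raw area, baseline-only normalization) give the exponential term of the
  invasion factor the wrong scale, since it is O(1) for small t.

**Invasion factor.** IF = (A + exp(β₀ + β₁ t))/2 with
β₀ = 86539/44760 ≈ 1.9334 and β₁ = −250/1119 ≈ −0.2234 h⁻¹. The
exponential term equals 1 at t = −β₀/β₁ ≈ 8.654 h and the function is
strictly increasing in A and strictly decreasing in t.
`calibrate_invasion_model` refits the constants by ordinary least squares
of ln A on t — the functional form implied by the exponential term; the
direction of the regression (ln A on t rather than t on ln A) is the
interpretation under which the printed term is the fitted value of A.
On noiseless pairs generated from the constants the fit recovers them to
machine precision with R² = 1.

**Ranking and classing.** Relative invasiveness = IF / cohort-mean IF
(mean exactly 1). Rank 1 is the most invasive clone; ties break by clone
label for determinism. Classes use linear-interpolation percentiles:
high above the 75th, low below the 25th, otherwise mid; with 20 distinct
clones this yields exactly 5 high and 5 low. Classification needs ≥ 4
clones; smaller cohorts are ranked but not classed. Optionally each
high/low clone is compared against the pooled mid-quartile clones with a
Dunnett-adjusted many-to-one test on replicate invasion factors.

**Wound closure.** The closure rate is the OLS slope (%/h) of wound
density on time over the frames strictly before the first attainment of
100%. Frames at the ceiling are censored (the instrument saturates) and
excluded — including them biases the slope downward; at least 3
pre-closure frames are required.

**Spheroid volume.** Fold volume = (area ratio)^{3/2}, treating the
projected area as that of an equivalent sphere.

## Expression association

**qPCR normalization.** Relative expression = 2^(−ΔCt) with
ΔCt = Ct(gene) − mean Ct(reference panel), assuming amplification
efficiency 2. The reference panel (default RPLP0, PPIA, POLR2A) is
aggregated by the arithmetic mean of Ct values, i.e. the geometric mean on
the linear scale — the standard choice for multi-reference normalization.
Optional cohort normalization divides each gene by its mean over samples,
making per-gene cohort means exactly 1. The output is invariant to adding
a constant to all Ct values of a sample (input-amount differences).

**Subgrouping.** Clones are split in the (Vimentin, N-cadherin) plane by
a deterministic 2-means: coordinates are standardized per axis, centroids
initialize at the points with extreme coordinate sums, Lloyd iterations
run to convergence, and the cluster with the larger standardized centroid
sum is labelled high_high. Standardization makes the split invariant
under axis-wise affine rescaling; the fixed initialization removes run-to-
run variability. A median split (both markers above their cohort medians)
is available as a cruder alternative. Identical points produce a single
group with a warning.

**Association fits.** Per gene, expression is regressed on the invasion
factor over the full cohort and within each subgroup with ≥ 3 clones
(smaller subgroups are skipped with a warning), reporting slope, R² and
the two-sided p of the slope. An optional flag regresses on ln(IF)
instead, for cohorts whose area–onset coupling makes the log scale more
natural; the default is the untransformed predictor.

## Differential-expression integration

DE tables carry (gene, log2FC, p, FDR, log2CPM) per contrast, labelled
m / c / s / l / d. Published cut-offs are the defaults throughout:
FDR < 0.05; abundance filter log2CPM > 2 (strict); recurrence in ≥ 3 of 5
contrasts; overrepresentation retained when > 3-fold enriched in ≥ 2
analyses.

* Genes absent from a contrast are treated as untested — they count as
  non-significant and contribute sign 0 to the LCS, never as log2FC = 0
  measurements.
* LCS = Σ_{m,c} sign(log2FC) − Σ_{s,l,d} sign(log2FC), an integer in
  [−5, 5], antisymmetric under negating all fold changes. Signs are
  counted regardless of per-contrast significance (recurrence is filtered
  upstream); display order is |LCS| descending, then mean |log2FC|, then
  gene label.
* The sign-corrected mean log2FC negates the m and c values before
  averaging over present contrasts, putting all five on the "response to
  kinase loss" axis.
* Candidate Venn lists: significantly up in m or c AND significantly down
  in ≥ 1 of s/l/d (list 1), and the mirror (list 2); a gene matching both
  patterns is excluded from both with a warning, so the lists are disjoint
  and every member is significant in ≥ 2 contrasts by construction.

Overrepresentation uses the one-sided upper-tail hypergeometric test with
fold enrichment (hits/query)/(set/universe), BH-adjusted across terms.

## Junctional enrichment

Segments of length ≳ 150 px and width 20 px are drawn across bicellular
contacts with the contact at the segment midpoint. The profile takes one
sample per unit step along the segment; each sample averages 20 bilinear
interpolations at the centers of 20 unit-width strips spanning ±10 px
perpendicular to the segment. Coordinates are 0-based (row, col).

EF = mean of the 10 px junction window / mean of the pooled 2 × 10 px end
windows. The junction window is centered at the profile midpoint by
default; a peak-aligned mode (maximum within the central third) handles
slightly off-center contacts. Pooling the end pixels (rather than
averaging two per-end means) is stated for determinism; the two coincide
for equal-length ends. EF is exactly invariant under multiplicative
intensity rescaling and symmetric under end-to-end mirroring. Minimum
profile length is 30 px (two ends plus the junction window).

## Synthetic data

Every generator is a pure function of its parameters and a seed; one
global seed fans out to fixed named substreams, so adding a generator
never perturbs another's stream.

* **Counts.** Five contrasts × (3 vs 3 replicates), 5000 genes, library
  size 1.5 million (desk-scale rather than sequencing-scale depth;
  detectability is governed by the dispersion, not depth). Baselines are
  log-normal (median ≈ 200 counts, log-sd 1). Negative-binomial sampling
  uses the gamma–Poisson mixture with var = μ + αμ², α = 0.1 by default.
  20 planted genes carry the kinase-consistent pattern (+2 log2 in m and
  c, −2 in s, l, d). Planting is restricted to genes of at least median
  baseline abundance: the emulated candidate genes are moderately-to-well
  expressed, and a 4-fold change in a ~20-count gene is not identifiable
  at triplicate depth by any test, which would make the planted set
  ill-defined as a recovery truth.
* **DE test.** A moderated two-sample t on log2CPM (pseudo-count 0.5):
  gene-wise pooled variances are shrunk toward an abundance-trended prior
  (lowess of the log variance on mean log2CPM, scaled-F moment fit for the
  prior degrees of freedom d₀), with d₀ + n − 2 degrees of freedom for the
  test. The trend absorbs the mean–variance relationship of count data;
  without it, low-abundance genes are moderated toward too small a prior
  and the empirical FDR exceeds its nominal level. This is a minimal
  moderated-t test, not a negative-binomial GLM: it does not model
  per-gene dispersion or library-size offsets beyond CPM scaling, and its
  log2FC estimates are attenuated at very low counts.
* **Invasion series.** area = A₀ before t₀ and A₀·exp(r(t − t₀ + h))
  from t₀ on (h = sampling step, r = 0.1 h⁻¹ default ≈ 7 h doubling of
  invaded area), with multiplicative Gaussian noise (default 2%). t₀ is
  defined as the first frame showing growth — the convention under which
  noiseless detection returns t₀ exactly; the underlying continuous growth
  begins within the preceding sampling interval.
* **Wound series.** density = clip(rate·t + noise, 0, 100) every 4 h for
  24 h; frames beyond closure read exactly 100 (saturating confluence
  measure).
* **Contact images.** A vertical Gaussian ridge (σ = 3 px) of amplitude j
  on constant cytoplasm c, with the 150 px scan's midpoint window centered
  on the ridge. The true EF has a closed form from the Gaussian integral
  over the 10 px junction window and the two end windows, and the
  amplitude for a prescribed EF is obtained by exact inversion. Discrete
  sampling vs the continuous window integral differs by well under 1% at
  σ = 3. Optional additive Gaussian pixel noise.
* **qPCR.** Ct(gene) = ref_ct − log2(fold) + noise; reference genes read
  ref_ct + noise.

What the generators do **not** emulate: mapping/counting artifacts,
batch effects, between-replicate library-size spread, correlated genes,
non-exponential invasion kinetics, uneven illumination or out-of-focus
light in images, and qPCR efficiency ≠ 2. Passing tests therefore
demonstrate correctness of the computations and calibration under the
stated models, not robustness to those real-data artifacts.

## Statistical core

* OLS fits are computed from the explicit normal equations; a constant
  response is defined to give slope 0 and R² = 0 (rather than NaN), and
  slope/correlation p-values (two-sided t, n − 2 df) are reported only for
  n ≥ 3.
* BH adjustment uses the standard cumulative-minimum step-up; ties are
  handled by that formulation.
* The Dunnett many-to-one adjustment evaluates the multivariate-t
  distribution of the comparison statistics (seeded quasi-Monte-Carlo
  integration, two-sided). Each adjusted p is clipped from below at its
  unadjusted pooled-t p so integration noise can never make the adjusted
  value anti-conservative. Groups with zero pooled variance and equal
  means are defined to give F = 0, p = 1.

## Problem sizes and determinism

Default analysis sizes: 20 clones, 5000 genes × 5 contrasts × 6 samples,
100–500 contact measurements per condition — chosen as comfortable
desk-scale sizes that still exercise every code path. The orchestrated
pipeline (`clonotrace run`) writes all numeric output with fixed
formatting and derives all randomness from the config seed, so repeated
runs are byte-identical; this is asserted in the test suite.

## Known limitations

* The calibration R² printed in the original study (0.611) depends on its
  raw 20-clone measurements and cannot be reproduced; only recovery of the
  calibration constants from data generated under the model is tested.
* The LCS is a formalization of a verbally described score; alternative
  weightings (by fold change or significance) would need the original
  implementation to compare against. A flag restricts sign-counting to
  significant contrasts for sensitivity analyses.
* The EF's peak-alignment mode and the pooled-vs-per-end cytoplasm choice
  are interpretations of an imaging protocol whose details are not fully
  specified; both options are exposed.
* The DE stand-in is intentionally minimal (see above) and should not be
  used as a general-purpose DE tool.
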