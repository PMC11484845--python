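# Methods

This note records the models, conventions and design choices behind
`hydrotraits`, at the level of detail a maintainer or reviewer needs to
interpret its outputs.

## The analysis model

The pipeline treats a *community* as the pooled sample of living trees
(DBH strictly > 12.7 cm) inside one half-open grid cell
`[x·res, (x+1)·res) × [y·res, (y+1)·res)` at `res = 0.25°` by default.
Species abundance is the species' share of the community's total basal area
(`π(DBH/200)²` m²), pooled over all the cell's plots rather than averaged
per plot — "relative basal area of the species in that community" reads as
cell-level pooling, and the per-plot alternative is exactly recovered by the
plot-split invariance the tests enforce. The community-weighted mean of a
trait is the share-weighted average of per-species transformed values;
because one value per species is used, intraspecific variation is outside
the model.

Trait transforms: natural log for N, Ks, LS, LMA, Slope; `ln(−x)` for the
water potentials P50 and TLP (negative by convention); wood density enters
untransformed. The log base is irrelevant to the correlation-matrix PCA
(per-column affine maps cancel) but is fixed for bit-reproducibility; a
property test verifies the invariance.

Functional-type labelling uses a strict majority: the group (broadleaved
deciduous BD, broadleaved evergreen BE, needleleaved conifer NC) whose
basal-area share exceeds 0.5; exact ties and pluralities are "excluded"
(`> 50%` is read strictly).

## Gap-filling hierarchy

Missing species × trait cells are filled in order: (1) median of *observed*
congeneric species values; (2) median of observed confamilial values; (3) a
taxonomic k-NN imputation. "Median of the genus" is computed over observed
species-median values, never over previously imputed ones — this prevents
imputation cascades and makes the operator idempotent (tested). The k-NN
step is a deliberately simple, fully specified stand-in for tree-based
phylogenetic imputers: donors are species with an observed value for the
target trait, at taxonomic distance d = 1 (congeneric), 2 (confamilial) or
3 (other); the k = 5 nearest donors (ties broken by Euclidean distance over
shared z-scored traits, residual ties by a seeded permutation) contribute a
1/d-weighted mean. The module boundary allows swapping in a richer imputer.

**Masking validation.** For each proportion p ∈ {0.2, …, 0.8} and replicate
(100 by default), a fraction p of each trait's observed species is hidden
(selection per trait, uniform; all traits masked jointly within a
replicate, which is statistically equivalent under MCAR and eight times
cheaper than per-trait chains), the chain re-fills the table, and
predictions at masked cells are compared to the held-out values. Both sides
are z-transformed with the *full* observed distribution's mean/sd so
replicates share a scale; R² is the squared Pearson correlation (the
"predicted versus observed" reading; it differs from 1 − SS_res/SS_tot for
biased predictors) and RMSE is on the z scale. Replicates leaving < 2
unmasked or a degenerate masked set are skipped and logged.

## Ordination

PCA is computed from first principles: columns z-scored with sd(ddof = 1),
SVD of the standardised matrix (algebraically the eigendecomposition of the
Pearson correlation matrix; an independent `eigh` oracle pins agreement to
1e−8). Explained-variance shares use all eight eigenvalues as denominator.
Since eigenvector signs are arbitrary, each component is flipped so the
trait with the largest |loading| is positive — a fixed convention that
makes loadings, scores and Procrustes inputs reproducible. Scores are raw
projections `z-row · loadings` (not re-standardised), so their covariance
is diagonal with the eigenvalues on the diagonal (tested). Contributions
are `100 · loading²/Σ loading²` per axis.

Procrustes congruence uses the symmetric, scaled variant on the first two
loading columns: both configurations centred and scaled to unit Frobenius
norm, `m² = 1 − (Σ singular values of X'Y)²` ∈ [0, 1] (equal to scipy's
disparity, which serves as a cross-check), with significance from `n_perm`
row permutations of the second configuration and the +1-corrected p-value
`p = (1 + #{m²_perm ≤ m²_obs})/(n_perm + 1)` so p never reaches zero.

## Climate relative importance

LMG decomposes the full-model R² of a PC score on the five climate
variables into nonnegative per-regressor shares: the average R² increment
over all p! orderings, i.e. a Shapley value. It is computed through the
subset-weighted identity (2ᵖ subset R² values, each one solve against the
regressor correlation matrix); equivalence with literal p! enumeration is
pinned to 1e−10 in tests, and shares sum to the full R² to 1e−10 on every
fit including every bootstrap draw. Regressors are standardised first —
LMG itself is scale-invariant; this only conditions the solves.
Uncertainty comes from a nonparametric bootstrap over communities
(1000 draws by default) with percentile 95 % intervals; degenerate draws
are redrawn (bounded, logged). Communities lacking climate are dropped from
this module only, with the count recorded.

Aridity divergence is measured as the per-bin variance of PC scores over
equal-count AI bins, with the monotone trend summarised by the Spearman
correlation between bin median AI and bin variance (negative = divergence
at the arid end).

## The synthetic study system

The generator emulates exactly the features the analysis assumes, with
defaults chosen once as a realistic desk-scale study:

* **Taxonomy**: 10 families × 4 genera × 5 species (200 species), balanced;
  functional groups assigned per family.
* **Traits**: two standard-normal latent axes per species — axis 1
  acquisitive–conservative (N +, Ks +, LS +, LMA −, ln(−P50) −), axis 2
  isohydricity (ln(−TLP) +, WD +, Slope +) — plus nested family/genus
  intercepts (sd 0.3 each) and residual sd 0.2 on the transformed scale,
  then per-trait affine location/scale to land raw traits in realistic
  ranges (N ≈ 15 mg g⁻¹, P50 ≈ −3 MPa, WD ≈ 0.6 g cm⁻³). The per-trait
  affine maps are invisible to the correlation PCA. Axis scores carry
  phylogenetic signal (intra-family correlation 0.6) and a functional-group
  contrast on axis 1 (BD acquisitive, NC conservative, spacing 1.5 before
  re-standardisation) so that >50 % dominance arises at realistic rates;
  marginals remain ≈ N(0, 1). Missingness is MCAR at 0.3 per trait.
* **Inventory**: 2000 plots, 30 trees each, uniform over an 8° × 4° window.
  Summer_T follows longitude, MAT latitude (so the two temperature
  variables are separable); AI decreases log-linearly with Summer_T's
  gradient plus noise, and MAP/Summer_P follow AI noisily. Species enter a
  plot with probability ∝ exp(−(a₁ − μ₁)²/(2w²)), μ₁ = 1.2 standardised
  Summer_T; an analogous axis-2 factor activates when a MAT → axis 2 effect
  is configured (off by default — axis 1 carries the climate story). Niche
  breadth w = 0.35 + 0.9·(1 − AI scaled to [0, 1]) widens toward the arid
  end, planting the divergence signal; configurations with w ≤ 0 anywhere
  are rejected. DBH is 12.7 cm + lognormal(ln 8, 0.7); 10 % of stems are
  emitted dead and 5 % below threshold to exercise the filters.
* **Truth**: species axis positions, per-plot expected CWM axis values
  (niche-weight expectations computed before sampling) and the planted
  climate effect sizes are stored for recovery tests; realised
  basal-area-weighted CWMs of the true axis scores per cell are available
  via `true_cwm_axes`.

What the generator does **not** emulate: national inventory designs (plot
sizes, subplot fans, expansion factors), spatial autocorrelation beyond the
smooth gradient, intraspecific trait variation, non-MCAR missingness, and
taxonomic misidentification. Passing recovery tests therefore demonstrate
correctness of the estimators under the assumed data-generating model, not
robustness to these field realities.

## Problem sizes and fixtures

The default world (200 species / 2000 plots / ≈330 communities) runs the
full pipeline in under a second, so tests and the acceptance script use it
directly. Recovery checks use purpose-built worlds: axis recovery uses low
noise (residual sd 0.05, no missingness, no axis phylogenetic signal, MAT →
axis 2 effect 0.8) so both axes are expressed across communities; the
divergence check turns the climate → axis 1 mean effect off entirely so
that *all* score variance is compositional sampling variance and the
planted heteroscedasticity (w from 0.30 wet to 1.50 dry) is isolated, with
8 equal-count AI bins over ~480 communities (≥3 plots each); its control
sets the breadth slope to zero. Driver recovery is checked at the
regression level (n = 1000, exchangeable climate correlation 0.4, planted
unit effects, 200 bootstrap draws, 50 replicates). The masking experiment
uses a 120-species table with strong genus signal (genus sd 1.0 vs residual
0.15) so the hierarchy's ordering (genus > family > global mean) is
identifiable.

## Known limitations

* The taxonomic k-NN imputer ignores branch lengths; with very sparse
  traits its tie-breaking Euclidean distance may rest on few shared traits.
* Dominance-based exclusion interacts with the generator: worlds without
  environmental filtering have few >50 % communities, which is why
  divergence analyses skip that screen.
* LMG is exponential in the regressor count and capped at p = 12.
* The aridity-divergence Spearman p-value is computed over bins (n = bins),
  so with few bins only the sign, not significance, is informative.
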