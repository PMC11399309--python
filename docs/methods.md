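# Methods

This note documents the models, the synthetic-data design, the numerical
choices, and the limits of what the tests demonstrate.

## Community-weighted means

Group membership is probabilistic: each growth form maps to a triple
P(non-woody, woody-deciduous, woody-evergreen). Minority forms (ferns,
palms, cycads, bamboos, cacti, succulents) carry zero total probability and
contribute to no community aggregate; group relative covers renormalise
over the remaining taxa and therefore always sum to one where any taxon
survives.

CWMs average **native-unit** species values with weights
RC(taxon)·P(group), renormalised per trait over taxa that have the trait
measured (so missingness does not drag means toward zero), and take the
natural log afterwards. The alternative order — weighted mean of logs — is
available via `log_first=True`; the two differ by a Jensen term that grows
with within-plot trait spread. The default follows the convention of
plot-level trait products (weighted averages of trait values); the
mean-of-logs switch exists because species-level aggregation conventions
differ between datasets, and because linear averaging in log space is the
regime in which the generator's planted covariance is exactly analytic
(see below).

Log transforms of traits that can be non-positive (e.g. δ¹⁵N) raise an
error unless a per-trait additive offset is configured — silently shifting
a scale is not something a pipeline should do on its own.

Standardisation rescales each column to mean 0, sd 1 with the n−1
denominator (the default of the statistical environments this workflow
usually lives in), excluding missing entries from the moments.

## Bioclimatic variables

* MI = Σ₁²pr / Σ₁²PET; ln MI is reported and used throughout because the
  ecological action is at the dry end.
* MTCO = min of the 12 monthly means.
* MGST = GDD₀/NGD₀, missing (not zero) where NGD₀ = 0; a pixel with no
  growing season has no growing-season temperature, and that missingness
  propagates into every downstream model and map.
* PET, when not supplied, is Priestley–Taylor:
  PET = α·s/(s+γ)·Rn/λ with α = 1.26, the FAO-56 saturation-slope formula
  for s, γ = 0.0665 kPa/°C, λ = 2.45 MJ/kg, and Rn approximated as 0.77 ×
  monthly shortwave total (albedo 0.23, longwave neglected). This is a
  deliberately simple, closed-form stand-in for a full soil-moisture/
  radiation model: it is linear in radiation, monotone in temperature, and
  exactly testable by hand. Users with better PET inject it through the
  `pet` channel, which bypasses the stand-in entirely.
* Daily temperatures for GDD, when only monthly means exist, come from
  periodic linear interpolation between month-midpoint means over a 365-day
  year — the simplest reproducible scheme; climatology products that ship
  GDD₀/NGD₀ precomputed can supply them directly.
* The raster path and the per-plot path are the same vectorised code, so a
  one-pixel raster equals the scalar computation bit for bit.

## Ordination

PCA operates on the standardized log-CWM matrix (covariance of standardized
columns, n−1 scaling — i.e. the correlation structure), with a
deterministic sign convention: the largest-magnitude loading on each axis
is positive. Rows with missing entries are dropped complete-case per
analysis and reported.

RDA is the PCA of the fitted values of the multivariate least-squares
regression Ŷ = X(XᵀX)⁻¹XᵀY, with the residual PCA as the unconstrained
complement; the constrained fraction is ‖Ŷ‖²/‖Y‖². Per-axis fractions are
emitted both as a share of total variance and as a share of constrained
variance, since reported "% of trait variation" figures are ambiguous
between the two. `rotate_to_reference` flips axis signs (and optionally
reorders axes only within numerically equal-eigenvalue blocks) to match a
reference orientation without touching eigenvalues.

## Additive trait–climate models

The smoother is a Gaussian additive model over penalized cubic B-splines
(P-splines): k = 10 basis functions per term by default, second-order
difference penalty, the per-term sum-to-zero constraint absorbed by a QR
reparameterisation, and the per-term penalty rescaled to the magnitude of
its design block so smoothing parameters live on comparable scales.
Smoothing parameters minimise the profiled restricted-likelihood (REML)
criterion

V(ρ) = (n−M_p)/2·(1+log 2πσ̂²) + ½(log|XᵀX+S_λ| − log|S_λ|₊),

with σ̂² = (RSS+penalty)/(n−M_p) and M_p the total penalty null-space
dimension, optimised by Nelder–Mead from ρ = 0. The suite cross-checks the
fitter against an independent REML P-spline implementation (R mgcv):
deviance explained agrees to well under a point and fitted surfaces
correlate above 0.999 on shared data. Predictions clamp inputs to the
training range of each term (constant extrapolation of the boundary
value); extrapolation policy belongs to the hull mask, not the spline.

Bioclim × cover-fraction interactions are varying-coefficient terms: the
smooth of the bioclim variable multiplied pointwise by the cover fraction.
Because the three group covers sum to one, only two of them should enter a
model alongside an intercept.

**Relative importance** is a Shapley (LMG) decomposition: all 2³−1
submodels are fitted and each predictor's share is its average increment in
deviance explained over all entry orderings. Shapley increments sum exactly
to the full-model deviance explained, so the full-model and sum
normalisations coincide; for the cheaper leave-one-out variant (provided
for comparison) they differ, and both are emitted. Shares can be slightly
negative when a predictor is pure noise.

**Concurvity** is the "observed" measure: the fraction of a fitted term's
variance reproducible by least-squares projection onto the span of the
other terms' basis columns, clipped to [0, 1]. Note that on smooth climate
grids the three bioclim variables are strongly concurve (MGST especially),
so individual importance shares on gridded worlds spread across correlated
predictors — the joint fit is unaffected.

**Climate-space surfaces** sample a regular grid from the observed minimum
to maximum per axis (default increments 0.05 for ln MI, 0.25 °C for MTCO
and MGST) and mask nodes outside the 3-D convex hull (Delaunay membership)
of the observed sample, so the surface is only drawn where data constrain
it. Two-dimensional slices at fixed MTCO reproduce the usual
climate-space-diagram layout.

## Geospatial steps

Plots on cropland, urban, bare, water or permanent snow/ice land-cover
pixels are removed as unnatural vegetation. Fractional group cover comes
from the all-vascular-plot median group coverage per natural sub-class —
componentwise medians need not sum to one, so they are renormalised —
painted onto the fine land-cover grid and block-averaged (unweighted; a
latitude-weighted variant is a flag away) to the target resolution. Trait
maps evaluate a fitted model per pixel with missing-value propagation from
every input band; hull masking of the map is optional because global trait
maps are conventionally drawn unmasked.

Raster convention throughout: geographic lon/lat, origin upper-left, value
at cell centre, half-open cells; files are ESRI-ASCII text grids with a
JSON sidecar for names/units.

## Map evaluation

Maps are compared after valid-pixel block-mean aggregation to the coarser
grid (pixels below 50% valid fine coverage become missing — an explicit
choice, since no standard exists) with bilinear alignment only if grids are
offset; a literal bilinear resample is available as `literal-bilinear` for
comparison, because "aggregate and reproject bilinearly" is ambiguous at
large coarsening ratios. Metrics are computed on the log-trait scale over
jointly valid pixels with the regression direction fixed as observed ~
predicted: R² (squared Pearson r), RRMSE and bias as proportions of the
observed mean, and the slope. The agreement rule is R² ≥ 0.13 with slope in
the open interval (0.5, 2).

## Synthetic world

The generator emulates the *structure* of the real inputs, not their
content: plots with taxon relative covers summing to one, a species-level
table of the six major traits, monthly climate on a lon/lat grid, and a
land-cover mosaic with natural and unnatural sub-classes.

* **Climate.** The grid is an abstract climate gradient: the southern edge
  plays the tropics (annual mean 27 °C, seasonal amplitude 2 °C), the
  northern edge the high latitudes (−5 °C mean, 20 °C amplitude), with a
  west→east moisture gradient and harmonic longitudinal texture.
  Precipitation is clipped at zero; radiation follows the temperature
  season. Everything is smooth and deterministic.
* **Species.** Each species has a group (sampled from the group mix), a
  growth form (one representative form per group, plus a configurable
  minority "fern" fraction exercising the omission rule and an optional
  mixed form exercising probabilistic weighting), a home location, two
  independent standard-normal latent factors, and log-traits
  base + loadings·factors + climate effect at the home pixel + N(0, noise_sd²)
  with noise_sd = 0.2 by default. The two loading columns (size and leaf
  economics) are orthogonalised at construction, so the planted covariance
  is analytic: community averaging rescales latent and noise variance by
  the same effective factor, which cancels in the correlation matrix
  R = D^(−½)(LLᵀ + σ²I)D^(−½).
* **Axis identifiability.** Loadings are chosen with distinct column
  strengths per group so the two leading eigenvalues of R are separated;
  with symmetric 3+3 trait blocks the correlation spectrum degenerates and
  the planted axes are unrecoverable in principle at any sample size.
* **Plots.** Plots sample species through a Gaussian locality kernel
  (width 8% of the domain) combined with the generative group mixture of
  the plot's land-cover sub-class; covers are Dirichlet(1). Richness is
  uniform on 5–25. Record scope (all-vascular / unspecified / partial) is
  assigned at fractions 0.5/0.4/0.1 — the all-vascular share is far above
  the real-world ~16% so that sub-class medians are estimable at desk-scale
  plot counts.
* **Truth.** The world stores the orthogonalised loadings and factor
  scores, noise-free species log-traits, per-plot noise-free log-CWMs (the
  exact round-trip target for the traits module), per-pixel climate-effect
  surfaces per group and mixture-weighted over groups, the generative
  pixel group mixtures, and generative importance shares (per-component
  effect variance fractions over natural pixels).

Because the climate shift is evaluated at the species' **home** pixel (the
species table is the single source of trait values, so a per-occurrence
shift would be unobservable to the pipeline), plot CWMs track the local
climate effect only through the locality kernel; this contributes a small
extra smoothing that the recovery studies absorb.

## Recovery studies (the conditions behind the headline numbers)

Implemented once in `traitclim.studies`, used by both the test suite and
`scripts/acceptance.py`:

* *Planted-dimension recovery*: 1000 plots, 1500 species (≈ the
  taxa-per-plot ratio of large plot compilations), climate effects off,
  mixed form off, mean-of-logs CWMs — the conditions under which the
  two-factor correlation matrix is exactly analytic. Measured: per-group
  top-two PCA variance vs the planted fraction, and cosines between sample
  and analytic leading axes.
* *GAM surface recovery*: n = 2000, response f(ln MI) + g(MGST) + N(0, 0.2²)
  with smooth nonlinear f, g on realistic predictor ranges; planted R²
  computed from the drawn signal variance.
* *Importance recovery*: three exactly orthogonalised predictors with
  50/30/20% planted variance contributions at n = 2000, plus exact
  agreement of the Shapley combinator with permutation enumeration on
  ordinary-least-squares R² values.
* *End-to-end map recovery*: the default 40×40-pixel world with 3000 plots;
  the strong-signal trait (plant height, identical effect coefficients
  across groups) within the woody-evergreen group, since the major-trait
  maps are per-group products; the all-taxa CWM would mix composition-driven
  base-offset variation into the map while the truth surface is the pure
  climate effect.

Problem sizes are desk-scale by design; they keep every study seconds-fast
while leaving the measured quantities comfortably clear of their
thresholds.

## What passing tests do and do not show

The synthetic world has smooth climate, iid Gaussian trait noise, Dirichlet
covers, no taxonomic error, no trait imputation, no sampling-effort bias,
no spatial autocorrelation in the residuals, and no soil, land-use, CO₂ or
phylogenetic drivers. Recovery on it demonstrates that the pipeline's
algebra and plumbing are correct and that the estimators are consistent
under their own assumptions — not that three bioclim variables suffice for
real floras, nor that real CWM maps reach any particular accuracy.

## Known limitations

* The PET stand-in omits soil moisture, snow, and radiation geometry; MI
  values are only as good as the PET fed in.
* REML optimisation is derivative-free (Nelder–Mead); with many interaction
  terms (> ~8 smoothing parameters) it slows and a gradient-based optimiser
  would be preferable.
* `regrid` supports integer-ratio coarsening plus bilinear alignment, not
  arbitrary reprojection between coordinate systems.
* Concurvity of gridded bioclim predictors is intrinsically high; single-
  predictor importance on gridded worlds should be read with that in mind.
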