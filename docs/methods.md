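# Methods

This note documents the statistical models the package implements, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical choices a maintainer should know about.

## Trans-Gaussian geostatistics

Soil and microbial variables are rarely Gaussian, so each variable is first
mapped to normal scores: with rᵢ the (mean-tie) rank of value i among n,
score = Φ⁻¹((rᵢ − 0.5)/n).  All spatial modelling happens in score space;
kriged scores are mapped back by linear interpolation of the empirical
quantile pairs.  Scores outside the observed score range clamp to the
observed minimum/maximum — a rank transform carries no information beyond
the observed extremes, so the back-transform cannot extrapolate.  This also
means kriged maps never overshoot the data range.

The variogram model is γ(h) = c₀ + c₁(1 − ρ(h)) with Matérn correlation
ρ(h) = [2^(1−ν)/Γ(ν)](h/φ)^ν K_ν(h/φ).  Parameters: nugget c₀ (variance at
vanishing distance: measurement + micro-scale variation), partial sill c₁
(spatially structured variance), distance parameter φ (m), smoothness ν.
ν = 0.5 is exactly the exponential model; half-integer ν use closed forms
instead of Bessel evaluations (tested against the Bessel expression to
1e-8).

**Maximum-likelihood fit.**  The Gaussian log-likelihood
ℓ = −½[n ln 2π + ln|Σ| + (z−μ1)ᵀΣ⁻¹(z−μ1)], Σ = c₁R(φ,ν) + c₀I, is
maximized with μ profiled by generalized least squares (consistent with
ordinary kriging's unknown-constant-mean assumption) and c₁ profiled
analytically, leaving a 2-D Nelder–Mead search over (ln c₀/c₁, ln φ) from
six starting points (two nugget ratios × three ranges spread over the
distance span).  Because the likelihood is notoriously flat in ν, ν is by
default optimized over the grid {0.25, 0.5, 1, 1.5, 2, 3} with the other
parameters re-optimized per value; `fix_nu` skips the grid.  Failure of
every start raises a fit error carrying the diagnostics.

**Effective range** is the 95 %-of-sill distance (the Matérn sill is only
asymptotic, so the conventional practical range is used): closed forms for
the exponential (−φ ln 0.05 ≈ 3φ) and Gaussian (φ√ln 20) families, Brent
root-finding otherwise.

**Ordinary kriging** is solved in semivariance form with the classical
bordered system; γ(0) = 0 on the diagonal and in the right-hand side, so the
predictor honors the data at sampled locations.  Weights sum to 1 by
construction (asserted to 1e-10 in tests).  Duplicate sites make the system
singular and are reported by index pair.

**SSPE cross-validation.**  Each site is predicted from all others with the
*fixed* fitted model (no per-fold refit — refitting would destroy the
χ²(1 df) reference distribution of θᵢ = eᵢ²/σᵢ²).  Internally the
leave-one-out errors and variances come from the inverse of the
covariance-form bordered matrix (eᵢ = (Bz)ᵢ/Bᵢᵢ, σᵢ² = 1/Bᵢᵢ), an exact
identity validated in the tests against naive per-fold solves; it makes the
1000-simulation confidence limits and the 500-replicate calibration
experiments cheap because the inverse is shared across simulations.  The
verdict is "accepted" iff both mean(θ) and median(θ) fall inside their
simulated 95 % limits (reference values 1 and 0.455; the latter is the
χ²(1) median, reproduced by root-finding in the tests).

**Maps** are predicted on a regular grid restricted to the convex hull of
the sites (plus an optional buffer) and written as x,y,value CSV and as an
ESRI ASCII grid — plain-text formats readable by any GIS.

## PCNM spatial descriptors

The truncation distance t is the largest edge of the Euclidean minimum
spanning tree (the smallest threshold keeping the site graph connected);
distances above t are replaced by 4t; the Gower-centered −½D*² matrix is
eigendecomposed and positive-eigenvalue vectors retained, ordered from
broadest (PCNM₁) to finest scale.  Signs follow a fixed convention (largest
component positive) so results are reproducible.

Screening keeps vectors with Moran's I above the permutation-null
expectation −1/(n−1) and a one-sided permutation p ≤ 0.001.  The threshold
is inclusive because with 999 permutations the smallest attainable p is
exactly (1+0)/(999+1) = 0.001; a strict inequality could never retain
anything at that permutation count.  Moran weights reuse the truncated
connectivity (wᵢⱼ = 1 iff dᵢⱼ ≤ t).

Each retained vector's scale is the 95 % range of a Gaussian-family
variogram (γ = c₀ + c₁(1 − e^{−(h/φ)²})) fitted by weighted least squares
(weights = pair counts) to the vector's empirical variogram.  Only the
rising limb up to the first local maximum is fitted: eigenvector variograms
oscillate beyond it (hole effect), and a monotone model fitted across the
oscillations returns meaningless ranges.  WLS rather than ML is used
because an eigenvector is a smooth deterministic pattern, not a stochastic
realization, and dozens of vectors must be fitted.  Default scale bands:
fine ≤ 630 m < medium ≤ 800 m < coarse, configurable.

## Variance partitioning

Responses are univariate (biomass, S, J, H analyzed separately), so RDA
reduces exactly to multiple regression and the adjusted R² is Ezekiel's
1 − (1−R²)(n−1)/(n−p−1), with p the *rank* of the centered predictor matrix
so collinear columns are not double-counted.

**Management clustering**: factor analysis for mixed data (quantitative
columns standardized with population sd; each categorical level
indicator-coded, scaled by 1/√proportion, centered; SVD scores U·S — with
purely quantitative input this is exactly standardized PCA), then Ward
clustering of the leading components.  When k is not given it maximizes the
elbow ratio (W(k−1)−W(k))/(W(k)−W(k+1)) of within-cluster inertia losses.
Clusters enter the partition as full-rank indicator columns (first cluster
as reference).

**Forward selection** adds at each step the candidate with the largest
adjusted-R² gain and stops when either the adjusted R² stops increasing or
the AIC n·ln(RSS/n) + 2p stops decreasing — whichever triggers first; ties
break by column order.  The optional `alpha` argument adds the two
significance guards standard in ecological forward selection: a global
F-test of the full candidate set before any selection, and a partial F-test
of each entering variable.  Without them, greedy selection over many
candidates (e.g. ~100 PCNMs) almost always admits spurious variables under
the null — the AIC penalty of 2 is no match for the best of 100 candidates.
Spatial descriptors are selected against the residuals of the environmental
model, per the residual-based two-stage procedure.

**Partition.**  Adjusted R² is computed for all seven non-empty unions of
the three sets and the 7×7 inclusion–exclusion system is solved for the
three unique, three pairwise-shared and one triple-shared fraction; by
construction they sum exactly to the full-model adjusted R² (asserted to
1e-10).  Slightly negative adjusted fractions are reported as computed —
flooring would break the identity.  Shared fractions carry no significance
test (overlap cannot be permuted apart).  Unique fractions are tested by
permuting reduced-model residuals (response ~ other two sets), recomputing
the fraction per permutation, p = (1 + #{perm ≥ obs})/(n_perm + 1); the
package verifies this test's type-I error (0.05 ± 0.02 at α = 0.05 over 500
null datasets) and that p-values are invariant to affine transforms of the
response.  An independent cross-check against `vegan::varpart` (R) on a
small dataset agrees to 1e-6.

## Synthetic landscapes

The generator emulates the sampling structure the pipeline assumes: a
square grid (default 248 sites at 215 m) plus 30 infill points placed
10–100 m from a random grid node (below half the spacing, so the chosen
node is also the nearest); soil fields as stationary Gaussian random fields
(Cholesky factorization of the full covariance; default Matérn models with
effective ranges ~600–840 m); a land-management mosaic obtained by
thresholding a smooth auxiliary field at its empirical quantiles (giving
contiguous patches with near-exact category frequencies, default
(44,7,22,57,104,33)/278); responses as linear combinations of standardized
soil fields, category effects, an optional spatially structured residual
and white noise, with the implied variance fractions recorded as ground
truth; and OTU tables from a lognormal rank-abundance curve whose pool size
grows with a richness driver and whose shape σ shrinks with an evenness
driver, sampled by one multinomial draw per sample (row sums exactly equal
the read depth).

Defaults were calibrated once so that rarefied profiles at 10,800 reads
span realistic ranges for temperate agricultural topsoils — richness
roughly 850–1760 OTUs (mean ≈ 1270), evenness ≈ 0.66–0.88, Shannon
≈ 4.2–6.8 nats — via pool size 3000 ± 450 per driver sd and σ = 2.2 − 0.25
per driver sd.  An optional `cross_corr` parameter correlates soil fields
through a shared latent field (off by default: the joint distribution of
real soil variables is campaign-specific and no fidelity is claimed).

What the generator does **not** emulate: sequencing error and chimeras
(communities are generated at the OTU-count level), irregular landscape
outlines (the extent is rectangular — no tested property depends on the
shape), non-stationary or anisotropic soil fields, and abundance
distributions other than the lognormal.  Passing tests therefore demonstrate
the statistical machinery under the model's own assumptions, not robustness
to real-data pathologies such as spatially varying variance or sample
contamination.

All randomness descends from a single integer seed: `make_landscape` spawns
one child stream per stage (design, fields, land use, responses, OTU table,
in that order), and the pipeline derives per-stage seeds the same way, so
any stage can be reproduced in isolation.

## Calibration experiments and problem sizes

`soilscape.calibration` fixes the experimental conditions used by the
acceptance suite and `scripts/acceptance.py`: the 278-site design; the
reference Matérn model (c₀ = 0.1, c₁ = 0.9, φ = 200 m, ν = 0.5; effective
range 599 m); 500 replicates for the SSPE calibration; 100 refits for
range recovery (smoothness fixed at the generating ν — the experiment
measures recovery of the distance structure, and the ν grid search is
exercised separately in the unit suite); 100 replicates for the partition
recovery with truth 0.40/0.20/0.05 (components scaled to exact sample
variances; the partition is computed on the generative sets — one soil
field, six-cluster indicators, three PCNM columns — so the experiment
isolates the partition arithmetic from selection behavior, which has its
own tests); and 500 null datasets × 199 permutations for the type-I-error
check.

## Known limitations

* The full-covariance Cholesky approach caps practical problem sizes at a
  few thousand sites; no sparse/approximate kriging is provided.
* Isotropic variograms only; no anisotropy, universal kriging, or
  conditional simulation.
* The partition handles exactly three predictor sets and univariate
  responses; community-matrix RDA is out of scope.
* Rarefaction is a single draw, not an average over draws; samples below
  the target depth are an error rather than silently dropped, because
  dropping would change n for the spatial models downstream.
* Scale classification of PCNMs depends on the empirical-variogram binning;
  vectors whose Gaussian fit fails are labelled "unresolved" rather than
  guessed.
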