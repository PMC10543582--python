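# Methods

## The ALPS index

The index measures water diffusivity along perivascular spaces at the level
of the lateral-ventricle bodies. There, projection-fiber tracts run
inferior–superior (z) and association-fiber tracts anterior–posterior (y),
both perpendicular to the medullary-vein/perivascular direction, which is
right–left (x). Diffusivity along x that exceeds the diffusivity
perpendicular to the local fibers therefore indicates flow along the
perivascular space:

ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc).

The package consumes already-fitted axis maps (Dxx, Dyy, Dzz, in mm²/s, on a
common grid). Registration to a template and anatomically informed ROI
placement are upstream of this package: ROIs arrive either as explicit masks
(preferred; fully reproducible) or as a center + in-plane size rule. The
placement rule is deliberately pinned down to be unambiguous: a single axial
slice; square of edge `size_mm` centered on the voxel containing the center
coordinate; a voxel is included iff its center lies in the half-open square
[c − s/2, c + s/2) on both in-plane axes; world coordinates in mm with
0-based voxel indexing and an axis-aligned affine. ROI means are unweighted
voxel averages (no partial-volume weighting). Negative diffusivities — which
ordinary-least-squares tensor fits can produce — are kept in the means but
trigger a warning.

## ComBat harmonization

Model: y(i,j,v) = α(v) + X(i,j)·β(v) + γ(i,v) + δ(i,v)·ε(i,j,v) with
ε ~ N(0, σ²(v)); i indexes the scanner (batch), j the subject, v the feature
(here: left and right ALPS index), X the biological covariates.

The model is overparameterized (a constant can move between α and the γᵢ);
we identify it with the sample-size-weighted constraint Σᵢ nᵢγ̂ᵢ = 0, making
α̂ a grand intercept. A reference-batch parameterization would reproduce the
same harmonized values up to the choice of α̂; it is not offered in v1.

Conventions, stated because they silently matter:

- σ̂(v) is the root-mean-square residual of the full least-squares fit
  (batch indicators + covariates), 1/N convention.
- δ̂²(i,v) is the within-batch variance of the standardized data, 1/nᵢ
  convention. Using 1/(n−1) anywhere here breaks the exact single-batch
  identity y* = y.
- Hyperpriors use population (1/n) moments across features: γ̄ᵢ, τᵢ² are the
  across-feature mean/variance of γ̂(i,·); the inverse-gamma (λᵢ, θᵢ) solve
  the moment equations for the across-feature mean m and variance s² of
  δ̂²(i,·): λ = m²/s² + 2, θ = m(m²/s² + 1).

The EB estimates are the fixed point of the conditional posterior means
(parametric empirical Bayes in the genomics batch-correction lineage):

γ* = (nτ²γ̂ + δ*²γ̄)/(nτ² + δ*²),
δ*² = (θ + ½Σⱼ(z − γ*)²)/(n/2 + λ − 1),

iterated from the unshrunk estimates until the maximum absolute change is
below 1e−6 (configurable), cap 100 iterations; non-convergence returns the
last iterate flagged with a warning. τ² = ∞ reproduces the unshrunk γ̂
(no pooling); τ² = 0 pools completely to γ̄.

Degenerate cases, handled explicitly because this package's primary use case
has only two features (left/right index), where across-feature moments are
weakly determined:

- zero across-feature spread of γ̂ (τ² = 0) → complete pooling, with warning;
- zero spread of δ̂² (s² = 0, inverse-gamma moments undefined) → δ*² pooled
  to the across-feature mean, with warning;
- a single feature → no shrinkage at all, with warning;
- `eb=False` (CLI `--no-eb`) disables shrinkage entirely, which is exactly a
  per-batch location/scale re-standardization of the covariate-adjusted data.

Missing values are rejected, not imputed. With one batch the whole procedure
is an identity to machine precision; this is asserted in tests at 1e−8
relative.

## Evaluation statistics

- **Cohen's d**: S_c = √((n₁s₁² + n₂s₂²)/(n₁+n₂)) with per-group s the
  1/(n−1) sample SD, d = |x̄₁−x̄₂|/S_c, reported non-negative. The divisor
  n₁+n₂ (not n₁+n₂−2) combined with 1/(n−1) group SDs is a deliberate hybrid
  kept for comparability with the multisite DTI-ALPS literature; it differs
  from Hedges' pooled SD by O(1/n).
- **Welch's t** with Welch–Satterthwaite degrees of freedom (scipy); the
  both-groups-constant, equal-means corner returns t = 0, p = 1.
- **Pearson r** with the two-sided t-transform p (scipy).
- **GLM ANOVA** of the index on scanner (categorical), age (continuous) and
  group (categorical), Type II sums of squares (robust to the mild imbalance
  typical of multisite cohorts), partial η² = SS_factor/(SS_factor +
  SS_resid); fitted via statsmodels.
- **Power**: exact two-sided noncentral-t with df = n₁+n₂−2 and
  noncentrality d·√(n₁n₂/(n₁+n₂)); sample size by integer search at a fixed
  allocation ratio (power is monotone in n, so the first hit is minimal).
  The published post-harmonization worked-example powers (0.65 at d = 0.438
  and 0.73 at d = 0.480, 45/82 split, α = 0.05 two-sided) are reproduced by
  this convention. The corresponding pre-harmonization figures circulating
  for the same cohort (0.32, 0.40) are *not* reproduced by any standard
  noncentral-t setting we tried (we obtain 0.34 and 0.42); the original
  power tool and its settings are unstated, so those figures are documented
  here rather than asserted.
- Correlation tables report raw p values; Benjamini–Hochberg adjustment is
  available as a clearly separate helper, not applied by default.

## Synthetic data

`generate_cohort` draws directly from the ComBat generative model, so
harmonization is evaluated under exactly the conditions it assumes: per-cell
(scanner × group) balanced samples; ages uniform on 60–85 years (the study
window; the simplest distribution covering it); group as a 0/1 AD indicator;
sex supported as an optional indicator but off by default (the emulated
cohort is all-male); Gaussian noise (no heavy-tail option in v1).
Ground-truth components (covariate part, batch shift, scale, raw noise draw)
are stored per subject so recovery tests compare against the draw itself.

Defaults: intercept 1.90 with age slope −0.005/yr puts observed values at
~1.54 (CN) and ~1.39 (AD) at the mean age, matching the observed level and
group gap of published multisite ALPS tables; noise SD 0.2 index units;
scanner effects γ = (0, −0.05, +0.10), δ = (1.0, 0.8, 1.2) with the
Prisma-like scanner highest and the HDxt-like lowest, the ordering reported
across these scanner models; 50 subjects per cell (balanced, unlike the real
unbalanced cohorts, because tiny cells make Monte-Carlo checks noisy).

`generate_diffusivity_volumes` builds toy volumes whose only purpose is to
exercise the volume → ROI → index path: axis-aligned boxes stand in for the
projection/association areas, Dzz is boosted inside projection boxes and Dyy
inside association boxes (each area's dominant fiber direction), and Dxx
carries a configurable perivascular level, so the noise-free index equals
perivascular_dxx/baseline by construction. Boxes must lie inside the grid
and not overlap; generated diffusivities are clipped at zero. Default noise
is zero (exactness by default; pass `noise_sd` for stochastic volumes).

What passing on these data does **not** show: robustness to non-Gaussian or
heteroscedastic noise, site-correlated demographics (confounded batches),
registration/placement error, anatomical ROI shapes, or protocol effects
that do not reduce to a per-scanner location/scale change (e.g. a
gradient-scheme effect that varies by tissue). Real multisite cohorts can
violate all of these.

## Problem sizes and numerical choices

The synthetic recovery study uses 3 scanners × 2 groups × 200 subjects per
cell over 50 replicates — large enough that the Monte-Carlo standard error
of a between-scanner Cohen's d is ~0.07 and of the group-effect estimate
~0.017, so the "residual d < 0.1" and "|bias| < 3 SE" checks are
informative. The demo study uses 50 per cell (300 subjects), the scale of a
respectable single-disease multisite cohort. EB convergence tolerance 1e−6
(max absolute change) with cap 100 iterations; on these data the fixed point
is reached in well under 20 iterations. All randomness flows through
`numpy.random.default_rng` seeded per run.

## Known limitations

No nonparametric-prior or reference-batch ComBat, no longitudinal ComBat, no
GAM covariates, no missing-data handling, no nonparametric test battery
(Mann–Whitney/Spearman), and no dMRI preprocessing or registration — the
package begins at fitted diffusivity maps and ends at the evaluation report.
With only two features the EB priors rest on two points; when left/right
behave very differently, compare `eb=True` against `--no-eb` before trusting
the shrinkage.
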