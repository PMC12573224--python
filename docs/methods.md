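# Methods notes

This note records the models, parameter choices and numerical decisions
behind `dendrosync`, and what the synthetic-data tests do and do not
demonstrate about real tree-ring networks.

## Chronology building

**Detrending.** Individual series are detrended by the ratio to a cubic
smoothing spline.  "An n-year smoothing spline" is parameterized by its
frequency response: the penalty weight is chosen so the smoother passes
50% of the amplitude at the design wavelength (30 years by default).  For
unit annual spacing the spline smoother attenuates angular frequency ω by
approximately 1/(1 + λω⁴), giving λ = (1−f)/(f·ω₀⁴) for response f at
ω₀ = 2π/wavelength.  The realized response is verified empirically (a
30-year sinusoid on a constant passes at 0.50 ± 0.05 away from the
boundaries).  Fitted values are floored at 0.001 mm before division.
Series shorter than 15 years are under-determined for the spline and fall
back to a horizontal-mean detrend with a warning.

**Averaging.** Site chronologies are Tukey biweight robust means
(c = 9, median/MAD start, iterated to 1e-8 or 50 iterations; arithmetic
mean for n ≤ 2, median when the MAD collapses to zero).  Years with
fewer than 5 contributing trees are masked, except that the threshold
never exceeds the number of series, so a single-tree collection still
yields a (fully flagged) chronology.

**Pre-whitening** is applied at the chronology level (averaging first,
AR removal second), with an option to pre-whiten individual series before
averaging as a sensitivity variant.  AR(p) models with intercept,
p ∈ 0..5, are fitted by maximum likelihood and selected by AIC.  AIC is
the common dendro choice but retains spurious low-order structure on
roughly a quarter of pure white-noise inputs (its no-overfit probability
over six candidate orders is ~75%); `criterion="bic"` selects order 0 on
white noise ≥ 90% of the time and is preferable when conservative null
behaviour matters.  Residuals are re-centered to the input mean.
Non-stationary fits (AR root on the unit circle) raise.

## Climate derivation

Daily VPD uses the Tetens saturation curve; relative humidity is
accepted as a fraction or percent (values > 1.5 are treated as percent,
matching gridded products that serve percent).  Monthly PET uses the
standard Hargreaves–Samani form with the +17.8 °C offset, the square
root of the diurnal range and the 0.408 radiation conversion, evaluated
with FAO-56 extraterrestrial radiation at the mid-month day of year and
clamped at zero for cold months (negative evapotranspiration is
unphysical).  A reduced literal variant without offset/root/conversion is
available behind `literal_form=True` for comparison only.  CWB is
precipitation minus PET, exactly, per month.  Seasonal CWB aggregates by
sum and temperature/VPD by mean; for complete seasons the sum-vs-mean
choice only rescales and does not affect Pearson correlations.
Bioclimatic quarters are the 12 circular 3-consecutive-month windows on
a 30-year monthly climatology (1981–2010 by default), not calendar
quarters.

## Climate–growth correlations

Windows are all contiguous 1–5-month runs inside each season and never
cross season boundaries.  Correlations need at least 20 overlapping
years, which protects early-period estimates.  Significance is a pairs
bootstrap (year pairs resampled with replacement, 1000 replications):
95% percentile intervals and a two-sided p equal to twice the smaller
sign-crossing fraction.  "Best" per season means the largest absolute
correlation with sign retained — negative best responses (temperature,
VPD) are real and must not be discarded — with deterministic tie-breaks
(longer window, then earlier start).  Because the best window is selected
over ~15–20 correlated candidates, its per-window p-value is optimistic;
the network-level percentage-significant figures inherit that selection
bias, as do comparable analyses that report best-window responses.

## Synchrony

Running rbar uses 20-year windows, complete-overlap trees only, and a
minimum of 6 trees per window (unstable small-overlap correlations are
excluded rather than patched).  Regional synchrony uses the
homoscedastic variance-components model with group-specific independent
year effects and a common residual variance, fitted by REML; the
likelihood is evaluated cluster-wise (group × year) with Sherman–Morrison
inverses, optimized over log-variances (hence non-negative) by
Nelder–Mead with up to three random restarts, and the standard error of
â_C comes from the delta method on a central-difference Hessian.
A between-group year-effect covariance is a possible extension of the
model family but is not implemented; the headline grouping structure does
not use it.

## The synthetic generator

The generator emulates the statistical skeleton of a two-group oak
network: per-site daily climate (latitude-dependent mean, sinusoidal
seasonal cycle, 0.02 °C/yr warming trend, AR(1) = 0.7 daily weather
noise, Bernoulli–gamma precipitation, humidity anti-correlated with warm
anomalies) and multiplicative tree growth
w = (a·e^(−b·age) + k)·exp(g), with

g = Σ_v β_v·z_v + u_site(t) + u_region(t) + ε_tree(t), then AR(1)-filtered
(variance-preserving, φ = 0.25).

Forcings z_v are standardized seasonal climate aggregates, so β is a
correlation-scale quantity and recovery is analytic: the expected
site-chronology correlation is ≈ β/σ_chron with
σ²_chron = s²_climate + σ²_site + σ²_region + σ²_tree/n̄, and the expected
within-site rbar is (s²_climate + σ²_site + σ²_region)/(… + σ²_tree).

Default calibration (the study conditions of the simulated network):
contraction β_CWB,current = 0.13, β_T,current = −0.05; persistence
β_CWB,current = 0.05, β_CWB,previous = 0.065, β_T,previous = −0.04;
σ²_site = 0.022/0.026, σ²_region = 0.014/0.005
(contraction/persistence), σ²_tree = 0.05, per-site coefficient spread
0.04.  These put site-level CWB correlations near 0.5 (contraction) and
0.25 (persistence), within-site rbar near 0.55 vs 0.46 (the "high" vs
"moderate" synchrony ranges for oak), and a clear â_C contrast — the
qualitative configuration the pipeline is meant to detect.  Sites are
10–75 trees (mean ≈ 22, shifted-Poisson), established 1890–1940 with a
±10-year per-tree jitter so sample depth ramps realistically.

All randomness descends from one seed through stable (SHA-256) hashing
of site/tree identifiers: outputs are byte-reproducible and independent
of iteration order.

**What the generator does not emulate:** spatially correlated climate
between sites (cross-site synchrony here is only the explicit regional
year effect, so â_C magnitudes are smaller than in real networks where
neighbouring sites share weather), disturbance and management history,
cross-dating error, missing-ring clustering, and non-stationary age
effects.  Passing tests therefore demonstrate the statistical machinery
and directional group contrasts, not field-scale effect sizes.

## Sensitivity models

The response is the best-window correlation per site × period × season.
Crossed random intercepts (season, site) are fitted as variance
components within a single group in statsmodels' MixedLM, by REML.
Continuous covariates are centered and scaled internally; marginal
effects at the mean are therefore grid predictions at covariate zero in
the standardized space, with SEs from the fixed-effects covariance, and
are invariant to affine covariate rescaling.  Season enters as a random
intercept despite having only three levels, mirroring the stated model;
`season_fixed=True` provides the fixed-season robustness variant.  A
variance component estimated at zero is reported as a singular fit with
a warning, not an error.  Tukey contrasts use the studentized-range
distribution with residual degrees of freedom n − p (a pragmatic stand-in
for Satterthwaite df; with hundreds of rows the difference is
negligible), and the compact letter display uses insert-and-absorb with
letters assigned in estimate order.  Both "all correlations" and
"significant windows only" model inputs are supported (`lmm_mode`).

## Periods, Δr and tests

Early = 1950–1985, late = 1986 to the end of record (each ≥ 20 years; a
site record ending before 2023 simply shortens the late period).
Δr = |r_late| − |r_early| is computed for every window significant over
the full period and pooled per variable.  Group differences use the
two-sample Wilcoxon rank-sum with normal approximation and tie
correction (all-tied input degenerates to p = 1 with a warning); with
more than two groups all pairs are tested with Holm adjustment.
Correlation distributions are compared with the asymptotic two-sample
Kolmogorov–Smirnov test.

## Problem sizes

Defaults are sized for a single CPU: the demonstration network is 12
sites (6 per group) × ~22 trees × 74 years with 1000 bootstrap
replications (~30 s end-to-end); calibration experiments use 1000 null
sites for the bootstrap type-I error, 50 replicates for â_C and
mixed-model recovery, 200 sites for the Δr null, and 50 replicates for
the shift sign test.  Larger networks scale linearly in sites and
bootstrap replications.
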