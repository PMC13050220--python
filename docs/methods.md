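# Methods

This note documents the models, parameter choices and numerical decisions
behind `canosif`, and what the synthetic-data validation does and does not
demonstrate about real field data.

## SIF retrieval (spectral fitting method)

The forward model over the O₂-A window (default 758.68–770.37 nm) is
L(λ) = ρ(λ)·I(λ)/π + F(λ). The reflectance continuum ρ is a quadratic
polynomial in λ − λ_mid (recentring to the window midpoint keeps the
design matrix well conditioned). Three fluorescence models are offered:

- `constant` — one parameter;
- `linear` (default) — intercept and slope in λ; keeps the whole fit
  linear and well conditioned in an 11.7 nm window;
- `gaussian` — a fixed far-red shape (center 760.5 nm, FWHM 25 nm) scaled
  by one amplitude.

The solution is ordinary linear least squares on the design matrix
[I·{1, x, x²}/π | F-basis]. Separability of the reflected and emitted
terms rests entirely on the depth of the oxygen absorption feature in I:
an exactly flat irradiance makes the design rank deficient (raised as an
error), and a shallow feature (max/min irradiance ratio below 1.2 by
default) triggers an ill-conditioning warning. SIF is reported as F
evaluated at 760 nm — the conventional O₂-A reporting wavelength — and
the model tag records the choice. Negative SIF values are retained;
clipping them would bias any downstream averaging.

Retrieval accuracy, measured on the generator: exact (≤10⁻⁶ relative) on
noiseless model-consistent input; at SNR 10,000:1 and 0.07 nm sampling a
single scan is recovered to ~0.3% (sd ≈ 0.005 mW m⁻² nm⁻¹ sr⁻¹), and the
mean over 200 replicates is within 1% of truth even when a linear F model
is fit to Gaussian-shaped truth (the model-mismatch bias is ≈ −0.3%).

Band reflectances for NDVI/NIRv are means over ±1 nm around 680 and
770 nm (configurable). Note one real effect the generator reproduces:
fluorescence in-fills the apparent NIR reflectance (πL/I includes F), so
spectra-derived NDVI sits a few 10⁻³ above the structural truth value.

## Radiation

Standard astronomical formulas: δ = 0.409·sin(2πJ/365 − 1.39),
d_r = 1 + 0.033·cos(2πJ/365), ω_s = arccos(−tan φ·tan δ),
N = (24/π)ω_s, and R_a = (24·60/π)·G_sc·d_r·(ω_s sin φ sin δ +
cos φ cos δ sin ω_s) with G_sc = 0.082 MJ m⁻² min⁻¹. Latitude is
converted degrees→radians by π/180. Polar conditions raise an error
rather than silently clamping (clamping is available by flag).

Two day-of-year modes exist. The legacy shortcut J = int(275M/9 − 30 + D) − 2
(truncation toward zero) is provided as a `verbatim` mode for traceability, but it
lacks month and leap corrections — it returns −1 for Jan 1 and only
matches the calendar for March of non-leap years — so the pipeline
default is the true calendar DOY.

The Ångström–Prescott step uses the recommended a_s = 0.25, b_s = 0.5 and
converts MJ m⁻² d⁻¹ to W m⁻² with a fixed factor of 23.1, as used by this
measurement chain. The physical provenance of 23.1 is not documented
anywhere we know of (a uniform 24 h energy spread gives 11.574; a factor
near 23 corresponds to concentrating the daily energy into ~12 daylight
hours); it is applied as specified and exposed as an argument so users
can substitute their own conversion.

## Light use

fPAR = 1.37·NDVI − 0.17 is an affine proxy and can leave [0, 1]
(negative below NDVI ≈ 0.124, ≥1 above NDVI ≈ 0.854). For pipeline use
it is clamped to [0, 0.95]; the 0.95 cap keeps the Beer–Lambert
inversion LAI = −ln(1 − fPAR)/k finite (LAI ≤ ~6 at k = 0.5, the upper
end of real rice canopies). Raw values remain available for diagnostics.
APAR = R_s·η_Q·μ·fPAR with η_Q = 0.5 (PAR fraction of shortwave) and
μ = 4.55 µmol J⁻¹.

## Chamber fluxes

No single canonical formula exists for static-chamber flux conversion;
the standard ideal-gas form is used: flux = slope·P·V/(R·T·A), slope in
ppm s⁻¹ from OLS over the full one-minute record (2 s cadence), V = A·h.
An optional initial-transient discard window (default 0 s) excludes
mixing artifacts; the fit R² is reported as a mixing diagnostic. Defaults
when unlogged: T = 298.15 K, P = 101325 Pa. GPP = |NEE| + |ER|, which is
insensitive to sign conventions for the dark-chamber flux.

Chlorophyll uses the two-wavelength spectrophotometric equations
verbatim (C_a = 0.00127·A663 − 0.000269·A645, C_b = 0.00229·A645 −
0.000468·A663, C_ab = (C_a + C_b)·0.0094·10⁶); the combined scale factor's
dimensional basis is not documented, so C_ab is treated as being on the
µg cm⁻² scale and used only relationally. Grain yield divides the
dry-ratio-scaled harvest mass by an explicit plot area (2 × 2 m plots by
default in the generator).

## Statistical design

The replication unit is the plot (n = 9). Per-date regressions relate a
response (plot yield, or GPP) to one index across the nine plots at each
measurement date, flagging p < 0.1 and p < 0.05; no multiple-testing
correction is applied, matching the design being reproduced. Phase-level
regressions collapse each plot to its phase-mean index (a peak-value rule
is available) — one point per plot per phase. R² is the squared Pearson
correlation; p-values use the t distribution with n − 2 df, exact for
OLS at these sample sizes. With n = 9 the null expectation of R² is
1/(n − 1) = 0.125, which the permutation checks verify.

The phase split is vegetative DOY 198–243, reproductive DOY 244–287;
out-of-season days are labelled `outside`. Daily aggregation offers a
full-day (08:00–18:00) and a midday (10:00–14:00) rule, since the
appropriate averaging window for sub-daily scans is a user choice.

## Synthetic seasons

The generator emulates the field design: nine 2 × 2 m plots (three
nitrogen levels × three replicates) at 29.45° N, sampled every 8 days
over DOY 198–287 (12 dates), rice LAI rising logistically to ~4.5 near
DOY 225 then declining linearly, chlorophyll ~45 µg cm⁻² senescing from
DOY 250. Spectra carry a Gaussian O₂-A absorption line (depth 0.85 at
760.4 nm), 0.07 nm sampling for retrieval-scale tests and a 0.2 nm grid
over 670–780 nm for season-scale scans (fixture size), and noise at
SNR 10,000:1.

Plot variability has two deliberately separated axes:

- a **structural factor** (nitrogen ±12% per level + 3% plot noise) that
  scales LAI and, with partly independent plot noise (8%), chlorophyll,
  and persists all season;
- a **physiological factor** (sd 25%, drawn independently per plot and
  per phase, floor 0.2) that scales SIF and GPP.

SIF is modelled as absorbed-light × activity:
sif = sif_max·(fPAR/0.95)·s(DOY)·physio·(1 + ε_date), with s a logistic
late-season decline (midpoint DOY 260) so SIF peaks near DOY 220 and
falls faster than structure, and ε_date ~ N(0, 0.08). GPP = LUE·APAR·physio
with LUE = 0.04. NDVI is constructed by inverting the fPAR proxy from
fPAR(LAI), so the NDVI → fPAR → LAI chain recovers LAI exactly; NIRv is
NDVI·R_NIR(LAI) plus small noise. Chamber CO₂ series are built by
inverting the flux equation so their OLS slopes reproduce the target
NEE/ER exactly in the noiseless limit (0.3 ppm record noise otherwise).

Grain yield couples to the vegetative-phase latent SIF level
T_p = (vegetative mean of fPAR·s)·physio_veg:
yield = 0.8 + 0.5·(T_p − 1) + ε, with sd(ε) calibrated per season from
the realized between-plot variance so the conditional population R² is
exactly `target_r2` (default 0.6). Because the physiological factor
decorrelates across phases, the reproductive-phase SIF–yield R² sits
near the 0.125 null by design, which produces the vegetative >
reproductive ordering in ≈96% of seeds (verified by Monte Carlo over
20,000 design draws and 200 full pipeline runs before the defaults were
frozen). The small-sample estimator inflates mean R̂² slightly
(≈0.61–0.63 at a population value of 0.6), the expected OLS bias at
n = 9.

`noise_scale` multiplies every observation-noise term; at 0 the season
is noiseless (signal variability between plots is retained) and coupled
relationships reach R² = 1. All randomness derives from (config, seed);
fixtures are written with a fixed float format so identical inputs give
byte-identical files (verified by checksum).

### What passing tests do not show

The generator is a statistical emulator, not a radiative-transfer model:
no atmospheric path effects, no BRDF/multi-angle geometry, no dark-current
or spectral-calibration drift, Gaussian (not shot-limited) noise, one
scan per plot-date at season scale, and GPP generated directly from the
light couplings rather than a process model. Recovery results therefore
validate the estimators and the inference chain under the stated noise
model — they do not certify accuracy on real spectra with unmodelled
systematics.

## Problem sizes

Default verification sizes: 200 replicates for the noisy-retrieval mean,
2000 draws / 2000 permutations for the statistical calibration, 200
seasons (spectra included, chambers omitted — the yield chain does not
use them) for end-to-end recovery. The full test suite runs in ~20 s,
the acceptance script in ~20 s on one CPU.
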