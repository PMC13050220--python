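# canosif

Canopy solar-induced chlorophyll fluorescence (SIF) retrieval and
stage-resolved yield analysis for paddy-rice field experiments.

## The problem

Near-surface spectroscopy can track a rice canopy through the season with
three complementary signals: **NDVI** (canopy greenness), **NIRv**
(NDVI × near-infrared reflectance, a structural proxy that suppresses the
soil background) and **SIF** (light re-emitted by chlorophyll during
photosynthesis, a physiological signal). Field campaigns that relate these
indices to grain yield and to chamber-measured gross primary productivity
(GPP) need a long chain of small computations — spectral fitting, solar
geometry, light-use bookkeeping, flux conversion, small-sample regression —
each easy to get subtly wrong. `canosif` packages that chain as a tested
library for researchers working with paired irradiance/radiance spectra,
closed-chamber CO₂ records and plot-level harvests.

## What it computes

**SIF by the spectral fitting method (SFM).** Over the O₂-A absorption band
(758.68–770.37 nm) the upwelling radiance is decomposed as

    L(λ) = ρ(λ)·I(λ)/π + F(λ)

with ρ a quadratic reflectance continuum and F a low-order fluorescence
model (constant, linear, or fixed-shape Gaussian). Everything is linear in
the coefficients, so the fit is exact linear least squares; SIF is F(760 nm).
Negative retrievals are retained — they are legitimate estimator output
under noise.

**Vegetation indices.** R = πL/I; NDVI = (R_NIR − R_red)/(R_NIR + R_red)
and NIRv = NDVI·R_NIR from band means at 680 and 770 nm (±1 nm).

**Radiation and light use.** Extraterrestrial radiation R_a from the solar
constant (0.082 MJ m⁻² min⁻¹), declination, Earth–Sun distance and sunset
hour angle; incident shortwave R_s = (0.25 + 0.5·n/N)·R_a·23.1 from
relative sunshine duration; fPAR = 1.37·NDVI − 0.17;
APAR = R_s·0.5·4.55·fPAR; LAI = −ln(1 − fPAR)/k with k = 0.5.

**Chamber fluxes.** NEE and ER from the OLS CO₂ trend of one-minute
closed-chamber records via flux = slope·P·V/(R·T·A); GPP = |NEE| + |ER|.
Chlorophyll a+b from two-wavelength absorbances (645/663 nm); grain yield
from hundred-grain dry/fresh ratio, harvest mass and plot area.

**Stage-resolved analysis.** Per-plot daily aggregation, the
vegetative/reproductive phase split at DOY 244, per-date and per-phase OLS
regressions of yield and GPP on each index (R² = squared Pearson r,
p from the t distribution with n − 2 df), driver regressions against LAI
and C_ab, and the index correlation matrix.

**Synthetic seasons.** Because no field data are distributed, a generator
produces instrument-faithful spectra (0.07 nm sampling, SNR 10,000:1) and
complete nine-plot seasons (3 nitrogen levels × 3 replicates, DOY 198–287)
with every truth stored, so each stage is validated by recovery.

## Worked example

```
$ python examples/retrieve_sif.py
injected SIF at 760 nm : 1.5000 mW m-2 nm-1 sr-1
retrieved SIF at 760 nm: 1.4976 mW m-2 nm-1 sr-1
relative error         : 0.16%
fit RMSE               : 0.0224 (radiance units)
window / model         : (758.68, 770.37) nm, sfm-quadratic-rho/linear-F@760nm
```

A single noisy scan at the instrument signal-to-noise ratio is retrieved to
sub-percent accuracy. At season scale (`examples/season_analysis.py`, seed 7):

```
index_name window_or_phase  slope    r2  p_value  sig_005
      ndvi      vegetative -0.588 0.011    0.788    False
       sif      vegetative  0.349 0.578    0.017     True
       sif    reproductive  0.095 0.007    0.831    False
```

The generator couples yield to vegetative-phase SIF with population
R² = 0.6; the pipeline recovers a significant vegetative SIF–yield
regression (R² = 0.58 on this seed) while the reproductive phase and the
structural indices stay near the small-sample null, exactly as designed.
Other examples cover radiation/light-use and chamber fluxes.

A thin CLI wraps the same functions:
`canosif simulate --seed 42 --out fixtures/`,
`canosif retrieve --spectra-dir fixtures/ --out retrievals.csv`,
`canosif analyze --daily fixtures/daily.csv --yields fixtures/yields.csv --out results/`.

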