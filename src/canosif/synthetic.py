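"""Synthetic canopy spectra and full multi-plot seasons with known truth.

No field data accompany the measurement design this package implements,
so every stage is validated by recovery: the generator emits
instrument-faithful spectra (O2-A absorption feature, 0.07 nm sampling,
signal-to-noise 10,000:1) and complete nine-plot seasons (three nitrogen
levels x three replicates, DOY 198-287 sampled every ~8 days) in which
every quantity the pipeline estimates — SIF, NDVI, NIRv, LAI, C_ab, GPP,
chamber fluxes, grain yield — has a stored ground truth.

Season structure
----------------
Plot-level variability has two axes.  A *structural* factor (nitrogen
effect +/- 12% per level plus 3% plot noise) scales the LAI and
chlorophyll trajectories and persists all season.  A *physiological*
factor (sd 25%, drawn independently per plot and per phase) scales SIF
and GPP, representing photosynthetic regulation that canopy structure
does not show.  Grain yield is coupled to the vegetative-phase latent SIF
level, with residual noise calibrated so the conditional population R^2
equals ``target_r2`` (default 0.6) exactly; because the physiological
factor decorrelates across phases, the reproductive-phase SIF-yield
correlation is near the null level by design.

NDVI is derived by inverting the affine fPAR proxy from fPAR(LAI), so
the NDVI -> fPAR -> LAI chain recovers the generator's LAI exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from . import radiation
from .errors import ConfigError, DegenerateInputError
from .light_use import DEFAULT_PARAMS as LIGHT_PARAMS, fpar_from_lai, ndvi_from_fpar
from .field_measures import R_GAS
from .spectra import SpectrumPair, gaussian_sif_shape

#: O2-A absorption line used by the irradiance simulator (nm).
O2A_LINE_CENTER = 760.4
O2A_LINE_FWHM = 1.5


def default_grid(start: float = 755.0, stop: float = 775.0, step: float = 0.07) -> np.ndarray:
    """Wavelength grid in nm (inclusive start, end short of stop)."""
    return np.arange(start, stop, step)


@dataclass(frozen=True)
class SpectralTruth:
    """Ground truth for one simulated canopy spectrum.

    ``reflectance_poly`` are quadratic coefficients (c0, c1, c2) of the
    true reflectance in powers of (lambda - 765 nm).  ``sif_amplitude``
    is the fluorescence at 760 nm, mW m-2 nm-1 sr-1; ``sif_shape`` is
    'gaussian' (center 760.5 nm, FWHM 25 nm) or 'linear'.  ``snr`` of
    None disables noise.
    """

    reflectance_poly: tuple[float, float, float] = (0.45, 0.001, -2e-5)
    sif_amplitude: float = 1.5
    sif_shape: str = "gaussian"
    absorption_depth: float = 0.85
    snr: float | None = 10000.0
    continuum_level: float = 1200.0  # mW m-2 nm-1 at 765 nm
    continuum_slope: float = -3.0  # mW m-2 nm-1 per nm
    linear_shape_slope: float = -0.015  # per nm, for sif_shape='linear'

    def __post_init__(self) -> None:
        if not 0.0 <= self.absorption_depth < 1.0:
            raise DegenerateInputError("absorption depth must lie in [0, 1)")
        if self.snr is not None and self.snr <= 0:
            raise DegenerateInputError("snr must be positive (or None for noiseless)")
        if self.sif_shape not in ("gaussian", "linear"):
            raise DegenerateInputError(f"unknown sif shape {self.sif_shape!r}")


def simulate_irradiance(
    grid: np.ndarray,
    absorption_depth: float = 0.85,
    level: float = 1200.0,
    slope: float = -3.0,
    line_center: float = O2A_LINE_CENTER,
    line_fwhm: float = O2A_LINE_FWHM,
) -> np.ndarray:
    """Smooth solar continuum times an O2-A Gaussian absorption line.

    I(lam) = (level + slope*(lam-765)) * (1 - depth * g(lam)) with g a
    unit-peak Gaussian at ``line_center``.  Strictly positive for depth
    in [0, 1) and a positive continuum over the grid.
    """
    if not 0.0 <= absorption_depth < 1.0:
        raise DegenerateInputError("absorption depth must lie in [0, 1)")
    grid = np.asarray(grid, dtype=float)
    continuum = level + slope * (grid - 765.0)
    if np.any(continuum <= 0):
        raise DegenerateInputError("continuum must be strictly positive on the grid")
    line = np.exp(-4.0 * np.log(2.0) * ((grid - line_center) / line_fwhm) ** 2)
    return continuum * (1.0 - absorption_depth * line)


def sif_shape_values(grid: np.ndarray, truth: SpectralTruth) -> np.ndarray:
    """Fluorescence spectral shape normalised to 1 at 760 nm."""
    if truth.sif_shape == "gaussian":
        return gaussian_sif_shape(grid)
    return 1.0 + truth.linear_shape_slope * (np.asarray(grid, float) - 760.0)


def simulate_canopy_spectrum(
    truth: SpectralTruth,
    seed: int | np.random.Generator | None = None,
    grid: np.ndarray | None = None,
) -> SpectrumPair:
    """Forward-model one irradiance/radiance pair from known truth.

    radiance = rho(lam) * I(lam) / pi + F(lam), plus Gaussian noise with
    sd = |signal| / snr on each spectrum independently (matched noise on
    the irradiance).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    irr = simulate_irradiance(
        grid, truth.absorption_depth, truth.continuum_level, truth.continuum_slope
    )
    x = grid - 765.0
    c0, c1, c2 = truth.reflectance_poly
    rho = c0 + c1 * x + c2 * x * x
    fluor = truth.sif_amplitude * sif_shape_values(grid, truth)
    rad = rho * irr / np.pi + fluor
    if truth.snr is not None and np.isfinite(truth.snr):
        irr = irr + rng.normal(0.0, np.abs(irr) / truth.snr)
        rad = rad + rng.normal(0.0, np.abs(rad) / truth.snr)
    return SpectrumPair(grid, np.clip(irr, 0.0, None), rad)


# --------------------------------------------------------------------------
# season-scale generator


@dataclass(frozen=True)
class SeasonConfig:
    """Study conditions for one simulated season.

    Defaults emulate the field design: nine 2 x 2 m plots (L/M/H nitrogen
    x 3 replicates) at 29.45 deg N, observed every 8 days over
    DOY 198-287, LAI peaking near DOY 225, SIF near DOY 220, chlorophyll
    senescing from DOY 250.  ``noise_scale`` multiplies every observation
    noise term (0 gives a noiseless season; plot-to-plot signal
    variability is retained).
    """

    n_plots: int = 9
    doy_start: int = 198
    doy_end: int = 287
    sampling_interval_days: int = 8
    latitude_deg: float = 29.45
    plot_area_m2: float = 4.0

    # canopy trajectories
    lai_max: float = 4.5
    lai_rise_rate: float = 0.12  # d-1 logistic rate
    lai_rise_mid_doy: float = 210.0
    lai_peak_doy: float = 225.0
    lai_decline_per_day: float = 0.006
    cab_max: float = 45.0  # ug cm-2
    cab_rise_rate: float = 0.15
    cab_rise_mid_doy: float = 208.0
    cab_senescence_start: float = 250.0
    cab_senescence_per_day: float = 0.01
    cab_plot_sigma: float = 0.08  # chlorophyll plot variability beyond N effect
    cab_date_sigma: float = 0.04  # leaf-sampling noise per plot-date

    # SIF couplings: SIF tracks absorbed light (fPAR) modulated by a
    # late-season physiological decline, so it peaks earlier and falls
    # faster than canopy structure.
    sif_max: float = 1.6  # mW m-2 nm-1 sr-1 at fPAR = fpar_cap, full activity
    sif_decline_mid_doy: float = 260.0
    sif_decline_rate_days: float = 12.0
    nitrogen_effect: float = 0.12  # structural factor step per N level
    plot_sigma: float = 0.03  # structural plot noise
    physio_sigma: float = 0.25  # per plot-phase physiological sd
    sif_date_sigma: float = 0.08  # relative per-date SIF noise

    # GPP / chamber
    lue: float = 0.04  # umol C per umol absorbed photon
    er_fraction: float = 0.3
    er_base: float = 1.0  # umol m-2 s-1
    chamber_duration_s: float = 60.0
    chamber_cadence_s: float = 2.0
    chamber_co2_noise_ppm: float = 0.3
    chamber_base_area_m2: float = 0.25
    ambient_co2_ppm: float = 420.0

    # yield coupling
    yield_base_kg_m2: float = 0.8
    yield_beta: float = 0.5  # kg m-2 per unit latent SIF factor
    target_r2: float = 0.6

    # spectra
    spectral_step_nm: float = 0.2
    spectral_range_nm: tuple[float, float] = (670.0, 780.0)
    snr: float = 10000.0
    noise_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.n_plots % 3 != 0 or self.n_plots < 3:
            raise ConfigError("n_plots must be a positive multiple of 3 (3 N levels)")
        if not 0.0 < self.target_r2 < 1.0:
            raise ConfigError("target_r2 must lie in (0, 1)")
        if not 7 <= self.sampling_interval_days <= 10:
            raise ConfigError("sampling interval must be 7-10 days")
        if self.nitrogen_effect == 0 and self.plot_sigma == 0 and self.physio_sigma == 0:
            raise ConfigError(
                "yield coupling requested with zero between-plot variance"
            )
        if self.noise_scale < 0:
            raise ConfigError("noise_scale must be >= 0")

    @property
    def dates(self) -> np.ndarray:
        return np.arange(self.doy_start, self.doy_end + 1, self.sampling_interval_days)

    @property
    def plot_ids(self) -> list[str]:
        reps = self.n_plots // 3
        return [f"{lvl}{i + 1}" for lvl in "LMH" for i in range(reps)]

    @property
    def nitrogen_levels(self) -> np.ndarray:
        reps = self.n_plots // 3
        return np.repeat([-1.0, 0.0, 1.0], reps)


@dataclass
class SeasonDataset:
    """One generated season: truth tables, observations and metadata."""

    config: SeasonConfig
    seed: int
    daily: pd.DataFrame  # per plot-date truth (lai, cab, ndvi, nirv, sif, gpp, ...)
    weather: pd.DataFrame
    yields: pd.DataFrame  # per plot grain sample and yield
    leaf: pd.DataFrame  # per plot-date absorbances
    chamber: pd.DataFrame  # long CO2 records
    chamber_geometry: pd.DataFrame
    spectra: dict = field(default_factory=dict)  # (plot_id, doy) -> SpectrumPair
    truth: dict = field(default_factory=dict)


def _lai_base(doy: np.ndarray, cfg: SeasonConfig) -> np.ndarray:
    rise = cfg.lai_max / (1.0 + np.exp(-cfg.lai_rise_rate * (doy - cfg.lai_rise_mid_doy)))
    peak = cfg.lai_max / (
        1.0 + np.exp(-cfg.lai_rise_rate * (cfg.lai_peak_doy - cfg.lai_rise_mid_doy))
    )
    decline = peak * (1.0 - cfg.lai_decline_per_day * (doy - cfg.lai_peak_doy))
    return np.where(doy <= cfg.lai_peak_doy, rise, np.clip(decline, 0.0, None))


def _cab_base(doy: np.ndarray, cfg: SeasonConfig) -> np.ndarray:
    rise = cfg.cab_max / (1.0 + np.exp(-cfg.cab_rise_rate * (doy - cfg.cab_rise_mid_doy)))
    sene = np.clip(
        1.0 - cfg.cab_senescence_per_day * np.clip(doy - cfg.cab_senescence_start, 0, None),
        0.0,
        None,
    )
    return rise * sene


def _sif_activity(doy: np.ndarray, cfg: SeasonConfig) -> np.ndarray:
    """Seasonal fluorescence-yield modulation: ~1 early, logistic decline."""
    return 1.0 / (
        1.0 + np.exp((np.asarray(doy, float) - cfg.sif_decline_mid_doy) / cfg.sif_decline_rate_days)
    ) / (1.0 / (1.0 + np.exp((cfg.doy_start - cfg.sif_decline_mid_doy) / cfg.sif_decline_rate_days)))


def _r_nir_from_lai(lai: np.ndarray) -> np.ndarray:
    """Dense canopies reflect more NIR; saturating in LAI."""
    return 0.12 + 0.45 * (1.0 - np.exp(-0.45 * lai))


def _absorbances_for_cab(cab: np.ndarray, ratio_645_663: float = 0.45):
    """Invert the chlorophyll equations at a fixed A645/A663 ratio."""
    per_a663 = (0.00127 - 0.000468) + ratio_645_663 * (0.00229 - 0.000269)
    a663 = cab / (0.0094e6 * per_a663)
    return ratio_645_663 * a663, a663


def _scan_timestamp(doy: int) -> datetime:
    return datetime(2021, 1, 1, 11, 0) + timedelta(days=int(doy) - 1)


def simulate_season(
    config: SeasonConfig = SeasonConfig(),
    seed: int = 0,
    include_spectra: bool = True,
    include_chamber: bool = True,
) -> SeasonDataset:
    """Generate one full season with ground truth.

    All randomness derives from ``seed``; the same (config, seed) pair
    reproduces the dataset bit for bit.
    """
    cfg = config
    rng = np.random.default_rng(seed)
    dates = cfg.dates
    plots = cfg.plot_ids
    n_levels = cfg.nitrogen_levels
    n_plots = cfg.n_plots
    ns = cfg.noise_scale

    struct = 1.0 + cfg.nitrogen_effect * n_levels + rng.normal(0, cfg.plot_sigma, n_plots)
    # chlorophyll shares the nitrogen response but not the full structural
    # factor: leaf pigment varies partly independently of canopy size
    struct_cab = (
        1.0 + cfg.nitrogen_effect * n_levels + rng.normal(0, cfg.cab_plot_sigma, n_plots)
    )
    physio = {
        phase: np.clip(1.0 + rng.normal(0, cfg.physio_sigma, n_plots), 0.2, None)
        for phase in ("vegetative", "reproductive")
    }

    # weather (exogenous, seeded)
    sunshine_frac = rng.uniform(0.3, 0.85, dates.size)
    air_temp_c = 27.0 + 3.0 * np.sin((dates - 200.0) / 30.0) + rng.normal(0, 1.0, dates.size)
    weather_rows = []
    for d, frac, temp in zip(dates, sunshine_frac, air_temp_c):
        geom = radiation.solar_geometry(cfg.latitude_deg, int(d))
        ra = radiation.extraterrestrial_radiation(
            int(d), radiation.latitude_radians(cfg.latitude_deg)
        )
        rs = radiation.incident_shortwave(ra, float(frac))
        weather_rows.append(
            {
                "doy": int(d),
                "latitude_deg": cfg.latitude_deg,
                "sunshine_hours": float(frac) * geom.day_length,
                "air_temp_c": float(temp),
                "day_length_h": geom.day_length,
                "ra_mj": ra,
                "rs_wm2": rs,
            }
        )
    weather = pd.DataFrame(weather_rows)
    rs_by_doy = dict(zip(weather["doy"], weather["rs_wm2"]))
    temp_by_doy = dict(zip(weather["doy"], weather["air_temp_c"]))

    lai_b = _lai_base(dates.astype(float), cfg)
    cab_b = _cab_base(dates.astype(float), cfg)
    sif_act = _sif_activity(dates.astype(float), cfg)

    from .analysis import label_phase  # local import to avoid cycle at module load

    daily_rows = []
    for j, d in enumerate(dates):
        phase = label_phase(int(d))
        for p in range(n_plots):
            lai = lai_b[j] * struct[p]
            cab = (
                cab_b[j]
                * struct_cab[p]
                * (1.0 + ns * rng.normal(0, cfg.cab_date_sigma))
            )
            fpar = fpar_from_lai(lai, LIGHT_PARAMS)
            ndvi = ndvi_from_fpar(fpar, LIGHT_PARAMS)
            r_nir = float(_r_nir_from_lai(np.array([lai]))[0])
            nirv = ndvi * r_nir + ns * rng.normal(0, 0.005)
            sif = (
                cfg.sif_max
                * (fpar / LIGHT_PARAMS.fpar_cap)
                * sif_act[j]
                * physio[phase][p]
                * (1.0 + ns * rng.normal(0, cfg.sif_date_sigma))
            )
            apar_val = rs_by_doy[int(d)] * LIGHT_PARAMS.eta_q * LIGHT_PARAMS.mu * fpar
            gpp = cfg.lue * apar_val * physio[phase][p]
            daily_rows.append(
                {
                    "plot_id": plots[p],
                    "doy": int(d),
                    "phase": phase,
                    "lai": lai,
                    "c_ab": cab,
                    "fpar": fpar,
                    "ndvi": ndvi,
                    "r_nir": r_nir,
                    "nirv": nirv,
                    "sif": sif,
                    "gpp": gpp,
                    "rs_wm2": rs_by_doy[int(d)],
                    "apar": apar_val,
                }
            )
    daily = pd.DataFrame(daily_rows)

    # leaf absorbances reproducing the chlorophyll truth
    a645, a663 = _absorbances_for_cab(daily["c_ab"].to_numpy())
    leaf = daily[["plot_id", "doy"]].copy()
    leaf["a645"] = a645
    leaf["a663"] = a663

    # grain yield coupled to the vegetative-phase latent SIF level: the
    # noise-free per-plot mean of the SIF model over vegetative dates
    veg_mask = np.array([label_phase(int(d)) == "vegetative" for d in dates])
    fpar_pd = 1.0 - np.exp(-LIGHT_PARAMS.k * np.outer(struct, lai_b[veg_mask]))
    structural_base = (fpar_pd * sif_act[veg_mask]).mean(axis=1)
    structural_base = structural_base / structural_base.mean()
    latent = structural_base * physio["vegetative"]  # T_p
    signal = cfg.yield_beta * latent
    var_sig = float(np.var(signal, ddof=1))
    if var_sig == 0:
        raise ConfigError("zero between-plot signal variance; cannot calibrate yield")
    sd_eps = np.sqrt(var_sig * (1.0 - cfg.target_r2) / cfg.target_r2)
    eps = ns * rng.normal(0, sd_eps, n_plots)
    yield_kg_m2 = cfg.yield_base_kg_m2 + cfg.yield_beta * (latent - 1.0) + eps
    yield_kg_m2 = np.clip(yield_kg_m2, 0.05, None)
    dry_fresh_ratio = 0.8
    yields = pd.DataFrame(
        {
            "plot_id": plots,
            "nitrogen_level": ["LMH"[int(v) + 1] for v in n_levels],
            "yield_kg_m2": yield_kg_m2,
            "hundred_dry_g": 2.0,
            "hundred_fresh_g": 2.0 / dry_fresh_ratio,
            "total_fresh_g": yield_kg_m2 * cfg.plot_area_m2 * 1000.0 / dry_fresh_ratio,
            "plot_area_m2": cfg.plot_area_m2,
        }
    )

    # chamber CO2 records whose slopes reproduce the target NEE / ER
    chamber_rows = []
    geometry_rows = []
    if include_chamber:
        t_grid = np.arange(0.0, cfg.chamber_duration_s + 1e-9, cfg.chamber_cadence_s)
        for _, row in daily.iterrows():
            d = int(row["doy"])
            height = 0.5 if d < dates[min(5, dates.size - 1)] else 1.0
            temp_k = temp_by_doy[d] + 273.15
            scale = (
                101325.0
                * (cfg.chamber_base_area_m2 * height)
                / (R_GAS * temp_k * cfg.chamber_base_area_m2)
            )
            er = cfg.er_fraction * row["gpp"] + cfg.er_base
            nee = er - row["gpp"]
            for mode, flux in (("NEE", nee), ("ER", er)):
                slope = flux / scale
                co2 = (
                    cfg.ambient_co2_ppm
                    + slope * t_grid
                    + ns * rng.normal(0, cfg.chamber_co2_noise_ppm, t_grid.size)
                )
                for t, c in zip(t_grid, co2):
                    chamber_rows.append(
                        {
                            "plot_id": row["plot_id"],
                            "doy": d,
                            "mode": mode,
                            "t_s": t,
                            "co2_ppm": c,
                        }
                    )
                geometry_rows.append(
                    {
                        "plot_id": row["plot_id"],
                        "doy": d,
                        "mode": mode,
                        "base_area_m2": cfg.chamber_base_area_m2,
                        "height_m": height,
                        "temp_c": temp_by_doy[d],
                        "pressure_pa": 101325.0,
                        "true_flux": flux,
                    }
                )
    chamber = pd.DataFrame(chamber_rows)
    geometry = pd.DataFrame(geometry_rows)

    # spectra consistent with the designed per-plot-date indices
    spectra: dict = {}
    if include_spectra:
        grid = default_grid(
            cfg.spectral_range_nm[0], cfg.spectral_range_nm[1], cfg.spectral_step_nm
        )
        edge = 1.0 / (1.0 + np.exp(-(grid - 715.0) / 5.0))
        irr_clean = simulate_irradiance(grid, 0.85, 1200.0, -1.0)
        shape760 = gaussian_sif_shape(grid)
        snr = None if ns == 0 else cfg.snr
        for _, row in daily.iterrows():
            r_nir = row["r_nir"]
            ndvi = row["ndvi"]
            r_red = r_nir * (1.0 - ndvi) / (1.0 + ndvi)
            rho = r_red + (r_nir - r_red) * edge
            rad = rho * irr_clean / np.pi + row["sif"] * shape760
            irr = irr_clean
            if snr is not None:
                irr = irr + rng.normal(0.0, np.abs(irr) / snr)
                rad = rad + rng.normal(0.0, np.abs(rad) / snr)
            spectra[(row["plot_id"], int(row["doy"]))] = SpectrumPair(
                grid,
                np.clip(irr, 0.0, None),
                rad,
                timestamp=_scan_timestamp(int(row["doy"])),
                plot_id=row["plot_id"],
            )

    truth = {
        "seed": int(seed),
        "config": asdict(cfg),
        "struct_factor": dict(zip(plots, struct.tolist())),
        "physio_vegetative": dict(zip(plots, physio["vegetative"].tolist())),
        "physio_reproductive": dict(zip(plots, physio["reproductive"].tolist())),
        "latent_veg_sif_factor": dict(zip(plots, latent.tolist())),
        "yield_noise_sd": float(sd_eps),
        "target_r2": cfg.target_r2,
    }
    return SeasonDataset(
        config=cfg,
        seed=int(seed),
        daily=daily,
        weather=weather,
        yields=yields,
        leaf=leaf,
        chamber=chamber,
        chamber_geometry=geometry,
        spectra=spectra,
        truth=truth,
    )


def write_fixtures(dataset: SeasonDataset, directory: str | Path) -> pd.DataFrame:
    """Write a season to CSV/JSON fixtures; returns the checksum manifest.

    Files use the interface schemas of the processing modules: one
    spectrum CSV per scan (``<plot>_<datetime>.csv`` with columns
    wavelength_nm, irradiance, radiance), daily.csv, weather.csv,
    yields.csv, leaf.csv, chamber.csv, chamber_geometry.csv and
    truth.json.  Identical (config, seed) yield byte-identical files.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write_df(df: pd.DataFrame, name: str) -> None:
        path = directory / name
        df.to_csv(path, index=False, float_format="%.10g")
        written.append(path)

    _write_df(dataset.daily, "daily.csv")
    _write_df(dataset.weather, "weather.csv")
    _write_df(dataset.yields, "yields.csv")
    _write_df(dataset.leaf, "leaf.csv")
    if not dataset.chamber.empty:
        _write_df(dataset.chamber, "chamber.csv")
        _write_df(dataset.chamber_geometry, "chamber_geometry.csv")

    scan_rows = []
    for (plot, doy), pair in sorted(dataset.spectra.items()):
        stamp = pair.timestamp.strftime("%Y%m%dT%H%M%S")
        name = f"{plot}_{stamp}.csv"
        _write_df(
            pd.DataFrame(
                {
                    "wavelength_nm": pair.wavelengths,
                    "irradiance": pair.irradiance,
                    "radiance": pair.radiance,
                }
            ),
            name,
        )
        scan_rows.append(
            {"file": name, "plot_id": plot, "timestamp": pair.timestamp.isoformat()}
        )
    if scan_rows:
        _write_df(pd.DataFrame(scan_rows), "scans.csv")

    truth_path = directory / "truth.json"
    truth_path.write_text(json.dumps(dataset.truth, indent=2, sort_keys=True))
    written.append(truth_path)

    manifest = pd.DataFrame(
        {
            "file": [p.name for p in written],
            "sha256": [hashlib.sha256(p.read_bytes()).hexdigest() for p in written],
        }
    )
    manifest.to_csv(directory / "manifest.csv", index=False)
    return manifest
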