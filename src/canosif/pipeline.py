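"""End-to-end chains gluing retrieval, aggregation and regression.

These helpers run the measurement-to-inference chain on in-memory
objects: per-scan SIF/NDVI/NIRv retrieval from spectra, chamber flux and
GPP recovery, daily aggregation, and the stage-resolved yield analysis.
"""

from __future__ import annotations

import pandas as pd

from . import analysis
from .field_measures import ChamberSeries, flux_from_chamber, gpp_from_nee_er
from .spectra import (
    BandDefinition,
    DEFAULT_SFM_WINDOW,
    ndvi_nirv_from_pair,
    retrieve_sif_sfm,
)


def process_spectra(
    spectra,
    window: tuple[float, float] = DEFAULT_SFM_WINDOW,
    fluorescence_model: str = "linear",
    bands: BandDefinition = BandDefinition(),
) -> pd.DataFrame:
    """Retrieve SIF, NDVI and NIRv for every scan.

    ``spectra`` is an iterable of SpectrumPair (or a dict of them).  NDVI
    and NIRv are skipped (NaN) when the grid does not cover both bands.
    Returns the retrieval-output table: plot_id, timestamp, sif, ndvi,
    nirv, rmse, model_tag.
    """
    if isinstance(spectra, dict):
        spectra = spectra.values()
    rows = []
    for pair in spectra:
        ret = retrieve_sif_sfm(pair, window=window, fluorescence_model=fluorescence_model)
        wl = pair.wavelengths
        covers = wl[0] <= bands.red_center - bands.halfwidth and wl[-1] >= bands.nir_center
        if covers:
            ndvi, nirv = ndvi_nirv_from_pair(pair, bands)
        else:
            ndvi = nirv = float("nan")
        rows.append(
            {
                "plot_id": pair.plot_id,
                "timestamp": pair.timestamp,
                "sif": ret.sif_at_peak,
                "ndvi": ndvi,
                "nirv": nirv,
                "rmse": ret.rmse,
                "model_tag": ret.model_tag,
            }
        )
    return pd.DataFrame(rows)


def process_chamber_table(
    chamber: pd.DataFrame, geometry: pd.DataFrame, discard_seconds: float = 0.0
) -> pd.DataFrame:
    """Fluxes and GPP per plot-date from long-format chamber records.

    ``chamber`` columns: plot_id, doy, mode, t_s, co2_ppm.  ``geometry``
    columns: plot_id, doy, mode, base_area_m2, height_m, temp_c,
    pressure_pa.  Returns one row per plot-date with nee, er, gpp and the
    fit diagnostics.
    """
    geom = geometry.set_index(["plot_id", "doy", "mode"])
    out = []
    for (plot, doy), grp in chamber.groupby(["plot_id", "doy"]):
        rec: dict = {"plot_id": plot, "doy": int(doy)}
        for mode in ("NEE", "ER"):
            sub = grp[grp["mode"] == mode].sort_values("t_s")
            g = geom.loc[(plot, doy, mode)]
            series = ChamberSeries(
                times=sub["t_s"].to_numpy(),
                co2=sub["co2_ppm"].to_numpy(),
                base_area=float(g["base_area_m2"]),
                height=float(g["height_m"]),
                air_temp=float(g["temp_c"]) + 273.15,
                pressure=float(g["pressure_pa"]),
                mode=mode,
            )
            flux = flux_from_chamber(series, discard_seconds=discard_seconds)
            rec[mode.lower()] = flux.flux
            rec[f"{mode.lower()}_r2"] = flux.r_squared
        rec["gpp"] = gpp_from_nee_er(rec["nee"], rec["er"])
        out.append(rec)
    return pd.DataFrame(out)


def season_yield_analysis(
    daily: pd.DataFrame,
    yields: pd.DataFrame,
    indices: tuple[str, ...] = ("ndvi", "nirv", "sif"),
    plot_stat: str = "mean",
) -> pd.DataFrame:
    """Per-phase yield regressions for each index; tidy summary table."""
    y = yields.set_index("plot_id")["yield_kg_m2"]
    summaries = []
    for index in indices:
        summaries.extend(
            analysis.phase_regression(daily, index, "yield", yields=y, plot_stat=plot_stat)
        )
    return analysis.summaries_to_frame(summaries)


def run_season_pipeline(dataset, fluorescence_model: str = "linear") -> dict:
    """Full chain on one simulated season.

    Retrieves every scan, aggregates to the daily table, joins the truth
    structure columns (lai, c_ab, gpp) for the driver analyses, and runs
    the per-date, per-phase and structural regressions.  Returns a dict
    of DataFrames.
    """
    records = process_spectra(dataset.spectra, fluorescence_model=fluorescence_model)
    daily = analysis.aggregate_daily(records, rule="full-day")
    truth_cols = dataset.daily[["plot_id", "doy", "lai", "c_ab", "gpp"]]
    daily = daily.merge(truth_cols, on=["plot_id", "doy"], how="left")
    y = dataset.yields.set_index("plot_id")["yield_kg_m2"]
    out = {
        "records": records,
        "daily": daily,
        "phase_yield": season_yield_analysis(daily, dataset.yields),
        "per_date_sif_yield": analysis.summaries_to_frame(
            analysis.per_date_regression(daily, "sif", "yield", yields=y)
        ),
    }
    corr_r, corr_p = analysis.correlation_matrix(daily, ["ndvi", "nirv", "sif"])
    out["correlation_r"] = corr_r
    out["correlation_p"] = corr_p
    return out
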