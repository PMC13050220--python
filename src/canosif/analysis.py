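"""Stage-resolved regression analysis of canopy indices.

The experimental design has nine 2 x 2 m plots (three nitrogen levels x
three replicates) observed every 7-10 days across a ~90-day season
(DOY 198-287), split at flowering into a vegetative phase (DOY 198-243)
and a reproductive phase (DOY 244-287).  Per-scan retrievals are averaged
to a per-plot per-day table; yield and GPP are then regressed on each
index either date by date (nine plots per fit) or per phase (one
phase-mean point per plot), and the indices are related to canopy
structure (LAI) and chlorophyll (C_ab) per phase.

All fits are ordinary least squares; R^2 is the squared Pearson
correlation and p-values come from the two-sided t test with n - 2
degrees of freedom, exact for OLS at these sample sizes.  Significance is
flagged at p < 0.1 and p < 0.05 without multiple-testing correction,
matching the design being reproduced.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateFitError, InsufficientDataError

logger = logging.getLogger(__name__)

#: Phase split (inclusive bounds) in day-of-year.
SEASON_START_DOY = 198
FLOWERING_DOY = 244
SEASON_END_DOY = 287

#: Daily aggregation rules: local-hour windows (inclusive start, exclusive end).
AGGREGATION_RULES = {"full-day": (8, 18), "midday": (10, 14)}

#: Significance thresholds as flagged in the per-date analysis.
P_WEAK = 0.1
P_STRONG = 0.05


@dataclass(frozen=True)
class RegressionSummary:
    """One index-response OLS fit in one window or phase."""

    index_name: str
    response_name: str
    window_or_phase: str
    slope: float
    intercept: float
    r2: float
    p_value: float
    n: int

    @property
    def significant_010(self) -> bool:
        return self.p_value < P_WEAK

    @property
    def significant_005(self) -> bool:
        return self.p_value < P_STRONG


def label_phase(doy: int) -> str:
    """'vegetative' for DOY 198-243, 'reproductive' for 244-287, else 'outside'."""
    doy = int(doy)
    if SEASON_START_DOY <= doy < FLOWERING_DOY:
        return "vegetative"
    if FLOWERING_DOY <= doy <= SEASON_END_DOY:
        return "reproductive"
    return "outside"


def fit_linear(
    x, y, index_name: str = "x", response_name: str = "y", label: str = ""
) -> RegressionSummary:
    """Ordinary least-squares fit of y on x with exact small-sample inference."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise InsufficientDataError("x and y must have equal length")
    if x.size < 3:
        raise InsufficientDataError(f"n = {x.size} < 3: no meaningful fit")
    if np.ptp(x) == 0:
        raise DegenerateFitError("regressor is constant; slope undefined")
    fit = stats.linregress(x, y)
    r2 = 0.0 if np.isnan(fit.rvalue) else float(fit.rvalue) ** 2
    p = 1.0 if np.isnan(fit.pvalue) else float(fit.pvalue)
    return RegressionSummary(
        index_name=index_name,
        response_name=response_name,
        window_or_phase=label,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=r2,
        p_value=p,
        n=int(x.size),
    )


def summaries_to_frame(summaries) -> pd.DataFrame:
    """RegressionSummary sequence -> tidy table with significance flags."""
    rows = []
    for s in summaries:
        d = asdict(s)
        d["sig_010"] = s.significant_010
        d["sig_005"] = s.significant_005
        rows.append(d)
    return pd.DataFrame(rows)


def aggregate_daily(retrievals: pd.DataFrame, rule: str = "full-day") -> pd.DataFrame:
    """Per-plot per-day means of index columns from time-stamped retrievals.

    ``retrievals`` needs ``plot_id`` and ``timestamp`` columns plus any
    numeric index columns (sif, ndvi, nirv, ...).  ``rule`` selects the
    local-hour window: 'full-day' keeps 08:00-18:00 scans, 'midday'
    10:00-14:00.  The observation count per plot-day is kept as ``n_obs``;
    plot-days with no scan in the window are omitted (logged).
    """
    if rule not in AGGREGATION_RULES:
        raise InsufficientDataError(
            f"unknown rule {rule!r}; choose from {sorted(AGGREGATION_RULES)}"
        )
    lo, hi = AGGREGATION_RULES[rule]
    df = retrievals.copy()
    ts = pd.to_datetime(df["timestamp"])
    df["doy"] = ts.dt.dayofyear
    hours = ts.dt.hour + ts.dt.minute / 60.0
    keep = (hours >= lo) & (hours < hi)
    dropped = df.loc[~keep, ["plot_id", "doy"]].drop_duplicates()
    for _, row in dropped.iterrows():
        logger.info(
            "rule %s: scans outside %02d-%02d h dropped for plot %s DOY %d",
            rule, lo, hi, row["plot_id"], row["doy"],
        )
    df = df.loc[keep]
    value_cols = [
        c
        for c in df.columns
        if c not in ("plot_id", "timestamp", "doy")
        and pd.api.types.is_numeric_dtype(df[c])
    ]
    grouped = df.groupby(["plot_id", "doy"], as_index=False)[value_cols].mean()
    counts = df.groupby(["plot_id", "doy"], as_index=False).size()
    out = grouped.merge(counts.rename(columns={"size": "n_obs"}), on=["plot_id", "doy"])
    out["phase"] = out["doy"].map(label_phase)
    return out


def per_date_regression(
    daily: pd.DataFrame,
    index_name: str,
    response: str,
    yields: pd.Series | None = None,
) -> list[RegressionSummary]:
    """Regress a response on one index date by date, across plots.

    For ``response='yield'`` pass ``yields`` as a Series indexed by
    plot_id (one harvest value per plot, regressed on every date's index
    values).  Any other response must be a column of ``daily`` matched per
    plot-date (e.g. 'gpp').  Dates with fewer than 3 plots are skipped
    with a log entry.
    """
    out: list[RegressionSummary] = []
    for doy, grp in daily.groupby("doy"):
        if response == "yield":
            if yields is None:
                raise InsufficientDataError("yield response requires a yields series")
            y = grp["plot_id"].map(yields).to_numpy(float)
        else:
            y = grp[response].to_numpy(float)
        x = grp[index_name].to_numpy(float)
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < 3:
            logger.info("DOY %d skipped: only %d complete plots", doy, int(ok.sum()))
            continue
        out.append(
            fit_linear(x[ok], y[ok], index_name, response, label=f"doy_{int(doy)}")
        )
    return out


def _phase_plot_index(
    daily: pd.DataFrame, index_name: str, plot_stat: str
) -> pd.DataFrame:
    if plot_stat == "mean":
        agg = "mean"
    elif plot_stat == "peak":
        agg = "max"
    else:
        raise InsufficientDataError(f"unknown plot_stat {plot_stat!r}")
    sub = daily[daily["phase"].isin(["vegetative", "reproductive"])]
    return sub.groupby(["phase", "plot_id"], as_index=False)[index_name].agg(agg)


def phase_regression(
    daily: pd.DataFrame,
    index_name: str,
    response: str,
    yields: pd.Series | None = None,
    plot_stat: str = "mean",
) -> list[RegressionSummary]:
    """Per-phase regression of a response on the phase-collapsed index.

    The index is collapsed to one value per plot per phase (phase mean by
    default; 'peak' uses the maximum).  Yield gives one point per plot;
    any other response column is collapsed the same way.  Raises
    ``InsufficientDataError`` when a phase has fewer than 3 plots.
    """
    collapsed = _phase_plot_index(daily, index_name, plot_stat)
    summaries = []
    for phase in ("vegetative", "reproductive"):
        grp = collapsed[collapsed["phase"] == phase]
        if grp.shape[0] < 3:
            raise InsufficientDataError(
                f"phase {phase!r} has {grp.shape[0]} plots; >= 3 required"
            )
        if response == "yield":
            if yields is None:
                raise InsufficientDataError("yield response requires a yields series")
            y = grp["plot_id"].map(yields).to_numpy(float)
        else:
            resp = _phase_plot_index(daily, response, plot_stat)
            merged = grp.merge(resp, on=["phase", "plot_id"], suffixes=("", "_resp"))
            y = merged[response].to_numpy(float)
        x = grp[index_name].to_numpy(float)
        summaries.append(fit_linear(x, y, index_name, response, label=phase))
    return summaries


def structure_regression(
    daily: pd.DataFrame, index_name: str, driver: str
) -> list[RegressionSummary]:
    """Per-phase regression of an index on a structural driver (lai or c_ab).

    Uses every plot-date record in the phase, relating each index to the
    canopy property that putatively drives it.
    """
    summaries = []
    for phase in ("vegetative", "reproductive"):
        grp = daily[daily["phase"] == phase]
        if grp.shape[0] < 3:
            raise InsufficientDataError(
                f"phase {phase!r} has {grp.shape[0]} records; >= 3 required"
            )
        summaries.append(
            fit_linear(
                grp[driver].to_numpy(float),
                grp[index_name].to_numpy(float),
                driver,
                index_name,
                label=phase,
            )
        )
    return summaries


def correlation_matrix(
    daily: pd.DataFrame, columns: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r and two-sided p over complete rows.

    Returns (r, p) DataFrames with unit diagonal.  A constant column makes
    its correlations undefined: the entries are NaN and a warning is
    issued rather than silently reporting zero.
    """
    data = daily[columns].dropna()
    if data.shape[0] < 3:
        raise InsufficientDataError("correlation needs >= 3 complete rows")
    k = len(columns)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            xi = data[columns[i]].to_numpy(float)
            xj = data[columns[j]].to_numpy(float)
            if np.ptp(xi) == 0 or np.ptp(xj) == 0:
                warnings.warn(
                    f"correlation between {columns[i]!r} and {columns[j]!r} "
                    "undefined: constant column",
                    stacklevel=2,
                )
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            res = stats.pearsonr(xi, xj)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    return (
        pd.DataFrame(r, index=columns, columns=columns),
        pd.DataFrame(p, index=columns, columns=columns),
    )
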