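"""Daily aggregation, phase labelling and the regression engine."""

import numpy as np
import pandas as pd
import pytest

from canosif import (
    aggregate_daily,
    correlation_matrix,
    fit_linear,
    label_phase,
    per_date_regression,
    phase_regression,
    structure_regression,
    summaries_to_frame,
)
from canosif.errors import DegenerateFitError, InsufficientDataError


class TestLabelPhase:
    @pytest.mark.parametrize(
        "doy, phase",
        [
            (198, "vegetative"),
            (243, "vegetative"),
            (244, "reproductive"),
            (287, "reproductive"),
            (297, "outside"),
            (100, "outside"),
        ],
    )
    def test_boundaries(self, doy, phase):
        assert label_phase(doy) == phase


class TestFitLinear:
    def test_perfect_fit(self):
        x = np.arange(9.0)
        s = fit_linear(x, 2 * x + 1)
        assert s.slope == pytest.approx(2.0)
        assert s.intercept == pytest.approx(1.0)
        assert s.r2 == pytest.approx(1.0)
        assert s.n == 9

    def test_constant_response_gives_zero_r2(self):
        s = fit_linear(np.arange(9.0), np.full(9, 3.0))
        assert s.r2 == pytest.approx(0.0)
        assert s.p_value == 1.0

    def test_constant_regressor_rejected(self):
        with pytest.raises(DegenerateFitError):
            fit_linear(np.full(9, 1.0), np.arange(9.0))

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            fit_linear([1, 2], [1, 2])

    def test_r2_equals_squared_pearson(self, rng):
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        s = fit_linear(x, y)
        assert s.r2 == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2, abs=1e-12)

    def test_type_i_error_calibrated(self, rng):
        """Null draws at n = 9: p < 0.05 in ~5% of fits."""
        hits = 0
        n_draws = 1000
        for _ in range(n_draws):
            s = fit_linear(rng.normal(size=9), rng.normal(size=9))
            hits += s.p_value < 0.05
        assert hits / n_draws == pytest.approx(0.05, abs=0.02)


def make_retrievals():
    rows = []
    for plot, val in [("L1", 0.4), ("L2", 0.6)]:
        for stamp in ["2021-07-17 08:30", "2021-07-17 11:00", "2021-07-17 13:30"]:
            rows.append({"plot_id": plot, "timestamp": stamp, "sif": val})
    return pd.DataFrame(rows)


class TestAggregateDaily:
    def test_mean_of_observations(self):
        df = make_retrievals()
        daily = aggregate_daily(df, rule="full-day")
        assert set(daily["n_obs"]) == {3}
        assert daily.loc[daily.plot_id == "L1", "sif"].iloc[0] == pytest.approx(0.4)

    def test_midday_rule_excludes_morning_scan(self):
        df = make_retrievals()
        full = aggregate_daily(df, rule="full-day")
        mid = aggregate_daily(df, rule="midday")
        assert full["n_obs"].iloc[0] == 3 and mid["n_obs"].iloc[0] == 2

    def test_two_values_average(self):
        df = pd.DataFrame(
            {
                "plot_id": ["L1", "L1"],
                "timestamp": ["2021-07-17 10:00", "2021-07-17 12:00"],
                "ndvi": [0.4, 0.6],
            }
        )
        daily = aggregate_daily(df)
        assert daily["ndvi"].iloc[0] == pytest.approx(0.5)
        assert daily["phase"].iloc[0] == "vegetative"


def make_daily(n_plots=9, doys=(200, 210, 250, 260), seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    plots = [f"P{i}" for i in range(n_plots)]
    base = rng.normal(1.0, 0.3, n_plots)
    for doy in doys:
        for p, b in zip(plots, base):
            rows.append(
                {
                    "plot_id": p,
                    "doy": doy,
                    "phase": label_phase(doy),
                    "sif": b + rng.normal(0, 0.05),
                    "lai": 2 * b + rng.normal(0, 0.05),
                    "c_ab": rng.normal(40, 5),
                    "gpp": 10 * b + rng.normal(0, 0.5),
                }
            )
    return pd.DataFrame(rows), plots, base


class TestPerDateRegression:
    def test_r2_matches_independent_correlation(self):
        daily, plots, base = make_daily()
        yields = pd.Series(0.5 * base + 0.3, index=plots)
        fits = per_date_regression(daily, "sif", "yield", yields=yields)
        assert len(fits) == 4
        for s in fits:
            grp = daily[daily.doy == int(s.window_or_phase.split("_")[1])]
            r = np.corrcoef(grp["sif"], grp["plot_id"].map(yields))[0, 1]
            assert s.r2 == pytest.approx(r * r, abs=1e-10)

    def test_noiseless_coupling_gives_unit_r2(self):
        daily, plots, base = make_daily()
        daily["proxy"] = daily["lai"] * 3.0 + 1.0
        fits = per_date_regression(daily, "lai", "proxy")
        assert all(s.r2 == pytest.approx(1.0) for s in fits)

    def test_permutation_null_mean_r2(self, rng):
        """Permuting responses across plots: E[R^2] = 1/(n-1) at n = 9."""
        daily, plots, base = make_daily()
        one_date = daily[daily.doy == 200]
        x = one_date["sif"].to_numpy()
        y = (0.5 * base + 0.3).copy()
        vals = []
        for _ in range(1000):
            vals.append(fit_linear(x, rng.permutation(y)).r2)
        assert np.mean(vals) == pytest.approx(1 / 8, abs=0.015)

    def test_sparse_dates_skipped(self):
        daily, plots, base = make_daily(n_plots=2)
        yields = pd.Series([0.1, 0.2], index=plots)
        assert per_date_regression(daily, "sif", "yield", yields=yields) == []


class TestPhaseRegression:
    def test_identical_phases_give_identical_summaries(self):
        daily, plots, base = make_daily()
        # force identical index values and responses in both phases
        veg = daily[daily.phase == "vegetative"].copy()
        rep = veg.copy()
        rep["doy"] = rep["doy"] + 50
        rep["phase"] = "reproductive"
        sym = pd.concat([veg, rep])
        yields = pd.Series(0.5 * base + 0.3, index=plots)
        a, b = phase_regression(sym, "sif", "yield", yields=yields)
        assert a.slope == pytest.approx(b.slope)
        assert a.r2 == pytest.approx(b.r2)

    def test_missing_phase_rejected(self):
        daily, plots, base = make_daily(doys=(200, 210))
        yields = pd.Series(0.5 * base + 0.3, index=plots)
        with pytest.raises(InsufficientDataError):
            phase_regression(daily, "sif", "yield", yields=yields)

    def test_invariant_to_row_order_and_relabeling(self):
        daily, plots, base = make_daily()
        yields = pd.Series(0.5 * base + 0.3, index=plots)
        ref = phase_regression(daily, "sif", "yield", yields=yields)
        shuffled = daily.sample(frac=1.0, random_state=1)
        relabel = {p: f"Q{i}" for i, p in enumerate(plots)}
        shuffled = shuffled.assign(plot_id=shuffled["plot_id"].map(relabel))
        yields2 = pd.Series(yields.to_numpy(), index=[relabel[p] for p in plots])
        out = phase_regression(shuffled, "sif", "yield", yields=yields2)
        for s1, s2 in zip(ref, out):
            assert s1.r2 == pytest.approx(s2.r2, abs=1e-12)
            assert s1.slope == pytest.approx(s2.slope, abs=1e-12)

    def test_gpp_response_uses_phase_means(self):
        daily, plots, base = make_daily()
        fits = phase_regression(daily, "sif", "gpp")
        assert [s.window_or_phase for s in fits] == ["vegetative", "reproductive"]
        assert all(s.n == 9 for s in fits)
        assert fits[0].r2 > 0.5  # shared base factor couples sif and gpp


class TestStructureRegression:
    def test_perfect_linear_driver(self):
        daily, plots, base = make_daily()
        daily["index"] = 0.2 * daily["lai"] + 0.05
        fits = structure_regression(daily, "index", "lai")
        assert all(s.r2 == pytest.approx(1.0) for s in fits)

    def test_constant_driver_rejected(self):
        daily, plots, base = make_daily()
        daily["flat"] = 1.0
        with pytest.raises(DegenerateFitError):
            structure_regression(daily, "sif", "flat")

    def test_lai_beats_cab_when_lai_driven(self):
        daily, plots, base = make_daily()
        lai_fits = structure_regression(daily, "sif", "lai")
        cab_fits = structure_regression(daily, "sif", "c_ab")
        for lf, cf in zip(lai_fits, cab_fits):
            assert lf.r2 > cf.r2


class TestCorrelationMatrix:
    def test_proportional_columns(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8]})
        r, p = correlation_matrix(df, ["a", "b"])
        assert r.loc["a", "b"] == pytest.approx(1.0)

    def test_negation_and_symmetry(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 5], "b": [-1.0, -2, -3, -5], "c": [1.0, 0, 2, 1]})
        r, p = correlation_matrix(df, ["a", "b", "c"])
        assert r.loc["a", "b"] == pytest.approx(-1.0)
        assert np.allclose(r.to_numpy(), r.to_numpy().T, equal_nan=True)
        assert np.allclose(np.diag(r.to_numpy()), 1.0)

    def test_constant_column_flagged_not_zero(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [5.0, 5, 5, 5]})
        with pytest.warns(UserWarning, match="constant"):
            r, p = correlation_matrix(df, ["a", "b"])
        assert np.isnan(r.loc["a", "b"])


def test_summary_frame_flags_significance():
    daily, plots, base = make_daily()
    yields = pd.Series(0.5 * base + 0.3, index=plots)
    frame = summaries_to_frame(phase_regression(daily, "sif", "yield", yields=yields))
    assert {"sig_010", "sig_005", "r2", "p_value"} <= set(frame.columns)
    assert ((frame["p_value"] < 0.05) == frame["sig_005"]).all()
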