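"""Simulation campaigns: aggregation, change tables, factorials, scenarios."""

import numpy as np
import pandas as pd
import pytest

import brutia_flux as bf
from brutia_flux import experiments as ex
from brutia_flux import fluxes as fx


def _flat_daily(year, gpp=1.0):
    dates = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
    n = len(dates)
    npp = 0.53 * gpp + 66.05 / 365
    rhet = 0.4
    return pd.DataFrame(
        {
            "date": dates,
            "gpp": np.full(n, gpp),
            "npp": np.full(n, npp),
            "rhet": np.full(n, rhet),
            "nep": np.full(n, npp - rhet),
        }
    )


# -- annual aggregation -----------------------------------------------------

def test_annual_aggregate_constant_flux():
    ann = bf.annual_aggregate(_flat_daily(2001))
    assert ann.loc[0, "gpp"] == pytest.approx(365.0)


def test_annual_aggregate_leap_year():
    ann = bf.annual_aggregate(_flat_daily(2004))
    assert ann.loc[0, "gpp"] == pytest.approx(366.0)


def test_annual_aggregate_rejects_partial_year():
    partial = _flat_daily(2001).iloc[:200]
    with pytest.raises(ValueError, match="2001"):
        bf.annual_aggregate(partial)


def test_annual_nep_is_npp_minus_rhet(forcing_3y, elevation_plots):
    daily = bf.simulate_plot(elevation_plots[0], forcing_3y)
    ann = bf.annual_aggregate(daily)
    np.testing.assert_allclose(ann["nep"], ann["npp"] - ann["rhet"], atol=1e-9)


def test_complete_years_drops_leap_remainder():
    daily = pd.concat([_flat_daily(2001), _flat_daily(2002).iloc[:10]])
    kept = ex.complete_years(daily)
    assert set(kept["date"].dt.year) == {2001}


# -- percent change ---------------------------------------------------------

def _summary(plot_values):
    rows = []
    for pid, vals in plot_values.items():
        for year, v in enumerate(vals, start=2000):
            rows.append(
                {"plot_id": pid, "year": year, "gpp": v, "npp": v, "rhet": v, "nep": v}
            )
    return pd.DataFrame(rows)


def test_percent_change_identity_and_doubling():
    base = _summary({"A": [10, 12], "B": [8, 9]})
    assert (bf.percent_change(base, base) == 0).all()
    double = _summary({"A": [20, 24], "B": [16, 18]})
    assert bf.percent_change(double, base)["gpp"] == pytest.approx(100.0)


def test_percent_change_sign_convention_below_minus_100():
    base = _summary({"A": [10.0]})
    negative = _summary({"A": [-5.0]})
    assert bf.percent_change(negative, base)["nep"] == pytest.approx(-150.0)


def test_percent_change_guards():
    base = _summary({"A": [10.0]})
    with pytest.raises(ValueError, match="plot"):
        bf.percent_change(_summary({"B": [10.0]}), base)
    zero = _summary({"A": [0.0]})
    with pytest.raises(ZeroDivisionError, match="baseline"):
        bf.percent_change(base, zero)


def test_percent_change_pooled_variant():
    base = _summary({"A": [10.0], "B": [30.0]})
    scen = _summary({"A": [20.0], "B": [30.0]})
    per_plot = bf.percent_change(scen, base)["gpp"]
    pooled = bf.percent_change(scen, base, per_plot_first=False)["gpp"]
    assert per_plot == pytest.approx(50.0)
    assert pooled == pytest.approx(25.0)


# -- factorial setups -------------------------------------------------------

def test_varlai_vart_equals_plain_simulation(forcing_3y, elevation_plots):
    plots = elevation_plots[:2]
    fact = bf.run_factorial(plots, bf.ExperimentSetup("varLAIvarT"), forcing_3y)
    for plot in plots:
        direct = bf.annual_aggregate(
            ex.complete_years(bf.simulate_plot(plot, forcing_3y)), plot_id=plot.plot_id
        )
        block = fact[fact["plot_id"] == plot.plot_id].reset_index(drop=True)
        pd.testing.assert_frame_equal(block, direct)


def test_conlai_with_equal_elevations_degenerates(forcing_3y, elevation_plots):
    # two plots at the same elevation and latitude with the same soil differ
    # only in LAI; fixing LAI must make their outputs identical
    a = elevation_plots[2]
    b = fx.PlotSpec(
        plot_id="clone",
        latitude=a.latitude,
        elevation=a.elevation,
        lai=a.lai * 2,
        stand_age=50,
        soil=a.soil,
    )
    fact = bf.run_factorial([a, b], bf.ExperimentSetup("conLAIvarT"), forcing_3y)
    left = fact[fact["plot_id"] == a.plot_id].drop(columns="plot_id").reset_index(drop=True)
    right = fact[fact["plot_id"] == "clone"].drop(columns="plot_id").reset_index(drop=True)
    pd.testing.assert_frame_equal(left, right)


def test_constant_lai_defaults_to_plot_mean(elevation_plots):
    assert np.mean([p.lai for p in elevation_plots]) == pytest.approx(1.96, abs=0.005)


def test_temperature_control_is_closer_to_realistic_than_lai_control(
    forcing_3y, elevation_plots
):
    """Across the elevation gradient, holding temperature constant barely
    changes GPP while holding LAI constant changes it a lot: stand structure
    dominates the elevation signal."""
    full = bf.run_factorial(elevation_plots, bf.ExperimentSetup("varLAIvarT"), forcing_3y)
    con_lai = bf.run_factorial(elevation_plots, bf.ExperimentSetup("conLAIvarT"), forcing_3y)
    con_t = bf.run_factorial(
        elevation_plots,
        bf.ExperimentSetup("varLAIconT", reference_plot="OLY3"),
        forcing_3y,
    )
    dev_lai = np.mean(np.abs(con_lai["gpp"].to_numpy() - full["gpp"].to_numpy()))
    dev_t = np.mean(np.abs(con_t["gpp"].to_numpy() - full["gpp"].to_numpy()))
    assert dev_t < dev_lai


def test_varlaicont_requires_reference(forcing_3y, elevation_plots):
    with pytest.raises(ValueError, match="reference"):
        bf.run_factorial(
            elevation_plots, bf.ExperimentSetup("varLAIconT"), forcing_3y
        )
    with pytest.raises(ValueError, match="not in plot list"):
        bf.run_factorial(
            elevation_plots,
            bf.ExperimentSetup("varLAIconT", reference_plot="NOPE"),
            forcing_3y,
        )


def test_gpp_increases_with_lai_across_fixture_plots(forcing_3y, elevation_plots):
    """With common forcing and identical everything-else, annual GPP is
    strictly increasing in LAI (canopy light absorption)."""
    ref = elevation_plots[2]
    lais = [0.67, 1.23, 1.96, 2.80, 4.26]
    totals = [
        bf.simulate_plot(ref.with_lai(lai), forcing_3y)["gpp"].sum() for lai in lais
    ]
    assert all(a < b for a, b in zip(totals, totals[1:]))


# -- scenario runs ----------------------------------------------------------

@pytest.fixture(scope="module")
def scenario_inputs(elevation_plots):
    plots = elevation_plots[:3]
    baseline = bf.synth_weather(bf.WeatherGenParams(seed=13), 11, start_year=1995)
    future = bf.synth_weather(bf.WeatherGenParams(seed=13), 11, start_year=2050)
    rcp_like = future.perturb(dt=3.0, precip_factor=0.8, co2_delta=200.0)
    periods = [
        ex.ScenarioPeriod("baseline", 1996, 2005),
        ex.ScenarioPeriod("rcp85", 2051, 2060),
    ]
    forcing = {"baseline": baseline, "rcp85": rcp_like}
    return plots, periods, forcing


def test_scenario_period_validation():
    with pytest.raises(ValueError, match="10 years"):
        ex.ScenarioPeriod("baseline", 1996, 2000)
    with pytest.raises(ValueError, match="scenario"):
        ex.ScenarioPeriod("rcp60", 2051, 2060)


def test_run_scenarios_tables(scenario_inputs):
    plots, periods, forcing = scenario_inputs
    result = bf.run_scenarios(plots, periods, forcing)
    change = result["change_table"]
    # baseline-vs-baseline row is identically zero
    assert np.allclose(change.loc["baseline_2005"], 0.0)
    # ten annual rows per plot and period
    counts = result["summaries"].groupby(["period", "plot_id"]).size()
    assert (counts == 10).all()
    # per-plot NEP table covers the baseline plots
    assert set(result["nep_table"]["plot_id"]) == {p.plot_id for p in plots}


def test_run_scenarios_warmer_drier_future_reduces_nep(scenario_inputs):
    plots, periods, forcing = scenario_inputs
    result = bf.run_scenarios(plots, periods, forcing)
    summaries = result["summaries"]
    base = summaries[summaries["period"] == "baseline_2005"]
    scen = summaries[summaries["period"] == "rcp85_2060"]
    for plot in plots:
        b = base.loc[base["plot_id"] == plot.plot_id, "nep"].mean()
        s = scen.loc[scen["plot_id"] == plot.plot_id, "nep"].mean()
        assert s < b
    assert result["change_table"].loc["rcp85_2060", "nep"] < 0


def test_run_scenarios_requires_window_coverage(scenario_inputs):
    plots, periods, forcing = scenario_inputs
    with pytest.raises(ValueError, match="cover"):
        bf.run_scenarios(
            plots,
            [ex.ScenarioPeriod("baseline", 1996, 2005), ex.ScenarioPeriod("rcp45", 2051, 2060)],
            {"baseline": forcing["baseline"], "rcp45": forcing["baseline"]},
        )


# -- tree-ring evaluation ---------------------------------------------------

def test_pearson_self_and_negation():
    years = pd.Index(range(2000, 2010), name="year")
    npp = pd.Series(np.linspace(300, 500, 10) + np.sin(np.arange(10)), index=years)
    rho, p = bf.pearson_eval(npp, npp)
    assert rho == pytest.approx(1.0)
    rho, _ = bf.pearson_eval(npp, -npp)
    assert rho == pytest.approx(-1.0)


def test_pearson_closed_form_oracle():
    years = pd.Index(range(2001, 2006), name="year")
    npp = pd.Series([310.0, 325.0, 298.0, 340.0, 330.0], index=years)
    rwi = pd.Series([0.95, 1.08, 0.88, 1.15, 1.02], index=years)
    x, y = npp.to_numpy(), rwi.to_numpy()
    cov = np.mean((x - x.mean()) * (y - y.mean()))
    oracle = cov / (x.std() * y.std())
    rho, p = bf.pearson_eval(npp, rwi)
    assert rho == pytest.approx(oracle, abs=1e-12)
    assert 0.0 <= p <= 1.0


def test_pearson_alignment_and_minimum_overlap():
    a = pd.Series([1.0, 2.0, 3.0, 4.0], index=pd.Index([2000, 2001, 2002, 2003]))
    b = pd.Series([2.0, 4.0, 6.0], index=pd.Index([2001, 2002, 2003]))
    rho, _ = bf.pearson_eval(a, b)
    assert rho == pytest.approx(1.0)
    with pytest.raises(ValueError, match="overlap"):
        bf.pearson_eval(a, pd.Series([1.0, 2.0], index=pd.Index([2002, 2003])))


def test_detrend_rwi_removes_age_trend():
    t = np.arange(60)
    raw = pd.Series(2.5 * np.exp(-0.05 * t) + 0.8, index=pd.Index(1950 + t, name="year"))
    rwi = ex.detrend_rwi(raw)
    np.testing.assert_allclose(rwi, 1.0, atol=1e-3)
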