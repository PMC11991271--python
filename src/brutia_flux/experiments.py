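"""Simulation campaigns over sets of plots.

Annual aggregation of daily fluxes, percent-change tables of scenario
runs against a baseline period, the factorial LAI-versus-temperature
setups that separate stand-structure from elevation (temperature)
effects, multi-scenario period runs, and the Pearson evaluation of
simulated NPP against an annual tree-ring width index.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import fluxes as fx
from .forcing import ForcingSeries

__all__ = [
    "ExperimentSetup",
    "ScenarioPeriod",
    "FLUX_COLUMNS",
    "annual_aggregate",
    "percent_change",
    "run_factorial",
    "run_scenarios",
    "pearson_eval",
    "detrend_rwi",
]

FLUX_COLUMNS = ("gpp", "npp", "rhet", "nep")

MODES = ("conLAIvarT", "varLAIconT", "varLAIvarT")


@dataclass(frozen=True)
class ExperimentSetup:
    """A factorial setup: ``conLAIvarT`` fixes LAI at a common constant
    (the across-plot mean by default) while temperature varies with
    elevation; ``varLAIconT`` keeps measured LAIs but forces every plot
    with the reference plot's temperature; ``varLAIvarT`` lets both vary
    (the plain simulation)."""

    mode: str
    constant_lai: float | None = None
    reference_plot: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.constant_lai is not None and self.constant_lai <= 0:
            raise ValueError("constant_lai must be positive")


@dataclass(frozen=True)
class ScenarioPeriod:
    """A scenario paired with a ten-year reference window: baseline
    1996-2005, mid-term 2051-2060 or long-term 2091-2100."""

    scenario: str
    start_year: int
    end_year: int

    def __post_init__(self) -> None:
        if self.scenario not in ("baseline", "rcp45", "rcp85"):
            raise ValueError("scenario must be baseline, rcp45 or rcp85")
        if self.end_year - self.start_year + 1 != 10:
            raise ValueError("reference windows are 10 years long")

    @property
    def label(self) -> str:
        return f"{self.scenario}_{self.end_year}"


def annual_aggregate(daily: pd.DataFrame, plot_id: str | None = None) -> pd.DataFrame:
    """Sum daily fluxes to calendar-year totals (g C m-2 year-1).

    Every year in the input must be complete (365 or 366 rows as the
    calendar requires); a partial year raises, naming the year.
    """
    years = daily["date"].dt.year
    counts = years.value_counts()
    for year, n in counts.items():
        expected = 366 if calendar.isleap(int(year)) else 365
        if n != expected:
            raise ValueError(f"partial year {year}: {n} of {expected} days")
    out = (
        daily.assign(year=years)
        .groupby("year", as_index=False)[list(FLUX_COLUMNS)]
        .sum()
    )
    if plot_id is not None:
        out.insert(0, "plot_id", plot_id)
    return out


def complete_years(daily: pd.DataFrame) -> pd.DataFrame:
    """Drop rows belonging to partial calendar years (e.g. the remainder of
    a leap year after a 365-day spin-up)."""
    years = daily["date"].dt.year
    counts = years.value_counts()
    full = {
        int(y) for y, n in counts.items()
        if n == (366 if calendar.isleap(int(y)) else 365)
    }
    return daily[years.isin(full)]


def percent_change(
    summaries: pd.DataFrame,
    baseline_summaries: pd.DataFrame,
    per_plot_first: bool = True,
) -> pd.Series:
    """Mean percent difference of annual fluxes against a baseline.

    With ``per_plot_first`` (the default) the change is computed per plot
    — 100 (mean_scenario - mean_baseline) / mean_baseline over that plot's
    annual values — and then averaged across plots. The alternative pools
    all plots before taking the ratio.
    """
    for df in (summaries, baseline_summaries):
        if "plot_id" not in df.columns:
            raise ValueError("summaries need a plot_id column")
    plots = set(summaries["plot_id"])
    if plots != set(baseline_summaries["plot_id"]):
        raise ValueError("scenario and baseline cover different plot sets")
    result = {}
    for fluxcol in FLUX_COLUMNS:
        if per_plot_first:
            changes = []
            for pid in sorted(plots):
                base = baseline_summaries.loc[baseline_summaries["plot_id"] == pid, fluxcol].mean()
                scen = summaries.loc[summaries["plot_id"] == pid, fluxcol].mean()
                if base == 0:
                    raise ZeroDivisionError(
                        f"undefined percent change: baseline mean {fluxcol} is 0 for plot {pid}"
                    )
                changes.append(100.0 * (scen - base) / base)
            result[fluxcol] = float(np.mean(changes))
        else:
            base = baseline_summaries[fluxcol].mean()
            if base == 0:
                raise ZeroDivisionError(f"undefined percent change: baseline mean {fluxcol} is 0")
            result[fluxcol] = float(100.0 * (summaries[fluxcol].mean() - base) / base)
    return pd.Series(result)


def run_factorial(
    plots: list[fx.PlotSpec],
    setup: ExperimentSetup,
    forcing: ForcingSeries,
    params: fx.PhotosynParams = fx.DEFAULT_PHOTOSYN,
    **sim_kwargs,
) -> pd.DataFrame:
    """Run one factorial setup over a common forcing series.

    Returns stacked annual summaries (plot_id, year, gpp, npp, rhet, nep).
    The constant LAI for ``conLAIvarT`` defaults to the mean LAI of the
    supplied plots; ``varLAIconT`` needs a ``reference_plot`` id whose
    elevation (hence lapse-corrected temperature) is imposed on all plots.
    """
    if not plots:
        raise ValueError("plots must be non-empty")
    if setup.mode == "conLAIvarT":
        lai = setup.constant_lai if setup.constant_lai is not None else float(
            np.mean([p.lai for p in plots])
        )
        sim_plots = [p.with_lai(lai) for p in plots]
    elif setup.mode == "varLAIconT":
        if setup.reference_plot is None:
            raise ValueError("varLAIconT requires a reference_plot id")
        ref = {p.plot_id: p for p in plots}.get(setup.reference_plot)
        if ref is None:
            raise ValueError(f"reference plot {setup.reference_plot!r} not in plot list")
        sim_plots = [p.with_elevation(ref.elevation) for p in plots]
    else:
        sim_plots = list(plots)
    pieces = []
    for original, plot in zip(plots, sim_plots):
        daily = complete_years(fx.simulate_plot(plot, forcing, params, **sim_kwargs))
        pieces.append(annual_aggregate(daily, plot_id=original.plot_id))
    return pd.concat(pieces, ignore_index=True)


def run_scenarios(
    plots: list[fx.PlotSpec],
    scenario_periods: list[ScenarioPeriod],
    forcing_by_scenario: dict[str, ForcingSeries],
    params: fx.PhotosynParams = fx.DEFAULT_PHOTOSYN,
    spin_up_days: int = 365,
    per_plot_first: bool = True,
    **sim_kwargs,
) -> dict:
    """Simulate every plot under every scenario-period and compare to the
    baseline period.

    ``forcing_by_scenario`` maps scenario name to a forcing series that
    must cover each requested window plus one spin-up year. Returns a dict
    with ``summaries`` (annual rows labelled by scenario/period),
    ``change_table`` (mean percent difference per flux and scenario-period
    against baseline; the baseline row is identically 0) and ``nep_table``
    (per-plot mean and SD of annual NEP under the baseline period).
    """
    baseline_periods = [sp for sp in scenario_periods if sp.scenario == "baseline"]
    if len(baseline_periods) != 1:
        raise ValueError("scenario_periods must contain exactly one baseline period")
    all_summaries = []
    per_period = {}
    for sp in scenario_periods:
        if sp.scenario not in forcing_by_scenario:
            raise ValueError(f"no forcing supplied for scenario {sp.scenario!r}")
        forcing = forcing_by_scenario[sp.scenario]
        window = _window_with_spinup(forcing, sp, spin_up_days)
        pieces = []
        for plot in plots:
            daily = fx.simulate_plot(
                plot, window, params, spin_up_days=spin_up_days, **sim_kwargs
            )
            daily = daily[daily["date"].dt.year.between(sp.start_year, sp.end_year)]
            pieces.append(annual_aggregate(daily, plot_id=plot.plot_id))
        block = pd.concat(pieces, ignore_index=True)
        block.insert(0, "period", sp.label)
        block.insert(0, "scenario", sp.scenario)
        per_period[sp.label] = block
        all_summaries.append(block)
    baseline_block = per_period[baseline_periods[0].label]
    change_rows = {}
    for sp in scenario_periods:
        change_rows[sp.label] = percent_change(
            per_period[sp.label], baseline_block, per_plot_first=per_plot_first
        )
    nep_table = (
        baseline_block.groupby("plot_id")["nep"]
        .agg(nep_mean="mean", nep_sd="std")
        .reset_index()
    )
    return {
        "summaries": pd.concat(all_summaries, ignore_index=True),
        "change_table": pd.DataFrame(change_rows).T.rename_axis("period"),
        "nep_table": nep_table,
    }


def _window_with_spinup(
    forcing: ForcingSeries, sp: ScenarioPeriod, spin_up_days: int
) -> ForcingSeries:
    spin_years = int(np.ceil(spin_up_days / 365))
    try:
        return forcing.slice_years(sp.start_year - spin_years, sp.end_year)
    except ValueError as err:
        raise ValueError(
            f"forcing for {sp.scenario} does not cover {sp.start_year}-{sp.end_year} "
            f"plus {spin_years} spin-up year(s)"
        ) from err


def pearson_eval(npp_annual: pd.Series, rwi: pd.Series) -> tuple[float, float]:
    """Pearson correlation between annual NPP and a ring-width index.

    Both series are indexed by year; the evaluation aligns them on their
    overlapping years (at least 3 required) and returns (rho, two-sided p).
    """
    joined = pd.concat({"npp": npp_annual, "rwi": rwi}, axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError(f"only {len(joined)} overlapping years; need at least 3")
    rho, p = stats.pearsonr(joined["npp"], joined["rwi"])
    return float(rho), float(p)


def detrend_rwi(ring_width: pd.Series) -> pd.Series:
    """Convenience ring-width detrender (not part of the flux model): ratio
    of raw ring width to a fitted negative-exponential age curve
    ``a exp(-b t) + k``. Dedicated dendrochronology software should be
    preferred for real chronologies."""
    t = np.arange(len(ring_width), dtype=float)
    y = ring_width.to_numpy(dtype=float)

    def curve(t, a, b, k):
        return a * np.exp(-b * t) + k

    p0 = (max(y[0] - y[-1], 1e-3), 0.05, max(y[-1], 1e-3))
    try:
        popt, _ = optimize.curve_fit(curve, t, y, p0=p0, maxfev=10000)
        fitted = np.maximum(curve(t, *popt), 1e-9)
    except RuntimeError:
        fitted = np.full_like(y, np.mean(y))
    return pd.Series(y / fitted, index=ring_width.index, name="rwi")
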