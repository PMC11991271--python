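"""Empirical soil heterotrophic respiration model machinery.

Synthetic chamber-style observation generation, linear mixed-effects
fitting of log flux with a random intercept per plot (REML for the
reported fit, ML refits for AIC-based comparison of fixed-effect
structures), Nakagawa-Schielzeth marginal and conditional R2, and
selection over a registry of candidate fixed-effect structures.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from statsmodels.regression.mixed_linear_model import MixedLM

from .fluxes import RHET_COEFFS

__all__ = [
    "CandidateModel",
    "MixedFit",
    "FitError",
    "TERMS",
    "generate_synthetic_rhet",
    "fit_lmm",
    "marginal_r2",
    "rank_candidates",
    "select_best",
    "partition_rs",
    "load_candidates",
    "fitted_form_candidate",
]

logger = logging.getLogger(__name__)

#: Supported fixed-effect terms (beyond the always-present intercept) and
#: how each is computed from the observation columns.
TERMS = {
    "ts": lambda d: d["ts"],
    "ts2": lambda d: d["ts"] ** 2,
    "theta": lambda d: d["theta"],
    "theta2": lambda d: d["theta"] ** 2,
    "loglai": lambda d: np.log(d["lai"]),
    "ts_theta": lambda d: d["ts"] * d["theta"],
}


class FitError(RuntimeError):
    """A mixed-model fit failed (singular design or optimisation failure)."""


@dataclass(frozen=True)
class CandidateModel:
    """A candidate fixed-effect structure on the log-flux scale. ``terms``
    draw from ``TERMS``; the intercept is implicit and always present."""

    id: str
    terms: tuple

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError("term list must be non-empty")
        unknown = [t for t in self.terms if t not in TERMS]
        if unknown:
            raise ValueError(f"unknown terms: {unknown}; supported: {list(TERMS)}")


@dataclass
class MixedFit:
    """A fitted mixed model: fixed-effect coefficients (with 95% confidence
    intervals), variance components, Nakagawa-Schielzeth R2s and the
    ML-based AIC used for structure comparison."""

    model_id: str
    coefficients: dict
    conf_int: dict
    var_plot: float
    var_resid: float
    r2_marginal: float
    r2_conditional: float
    aic: float
    n_obs: int
    n_plots: int

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "coefficients": self.coefficients,
            "conf_int": {k: list(v) for k, v in self.conf_int.items()},
            "var_plot": self.var_plot,
            "var_resid": self.var_resid,
            "r2_marginal": self.r2_marginal,
            "r2_conditional": self.r2_conditional,
            "aic": self.aic,
            "n_obs": self.n_obs,
            "n_plots": self.n_plots,
        }


def fitted_form_candidate() -> CandidateModel:
    """The shipped full temperature-quadratic + moisture-quadratic + log-LAI
    form (the structure of the fitted respiration equation)."""
    return CandidateModel(id="M09_tt2ww2l", terms=("ts", "ts2", "theta", "theta2", "loglai"))


def load_candidates(path: str | None = None) -> list[CandidateModel]:
    """Load the candidate registry (the shipped twelve forms by default)."""
    if path is None:
        with resources.files("brutia_flux.data").joinpath("rhet_candidates.yaml").open() as fh:
            raw = yaml.safe_load(fh)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    return [CandidateModel(id=c["id"], terms=tuple(c["terms"])) for c in raw["candidates"]]


def generate_synthetic_rhet(
    true_coeffs: dict | None = None,
    plot_lais: list | np.ndarray = (0.67, 1.66, 2.13, 1.67),
    n_per_plot: int = 60,
    sigma_plot: float = 0.15,
    sigma_resid: float = 0.30,
    ts_range: tuple = (5.0, 30.0),
    theta_range: tuple = (0.05, 0.45),
    seed: int = 0,
) -> pd.DataFrame:
    """Generate synthetic soil-respiration observations.

    One plot per entry of ``plot_lais`` (LAI varies between plots only, as
    in a field campaign). Soil temperature and moisture are uniform on the
    stated ranges; log flux is the linear predictor of ``true_coeffs``
    (the fitted respiration equation by default) plus a Gaussian plot
    random intercept (sd ``sigma_plot``) and residual noise (sd
    ``sigma_resid``). Columns: ``plot, ts, theta, lai, flux`` with flux in
    micromol CO2 m-2 s-1.
    """
    c = true_coeffs or RHET_COEFFS
    plot_lais = np.asarray(plot_lais, dtype=float)
    if plot_lais.size == 0:
        raise ValueError("plot_lais must be non-empty")
    if n_per_plot < 1:
        raise ValueError("n_per_plot must be >= 1")
    if sigma_plot < 0 or sigma_resid < 0:
        raise ValueError("noise standard deviations must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for i, lai in enumerate(plot_lais):
        b_plot = rng.normal(0.0, sigma_plot) if sigma_plot > 0 else 0.0
        ts = rng.uniform(*ts_range, n_per_plot)
        theta = rng.uniform(*theta_range, n_per_plot)
        eta = (
            c["intercept"]
            + c["ts"] * ts
            + c["ts2"] * ts**2
            + c["theta"] * theta
            + c["theta2"] * theta**2
            + c["loglai"] * np.log(lai)
            + b_plot
        )
        eps = rng.normal(0.0, sigma_resid, n_per_plot) if sigma_resid > 0 else 0.0
        rows.append(
            pd.DataFrame(
                {
                    "plot": f"P{i + 1:02d}",
                    "ts": ts,
                    "theta": theta,
                    "lai": lai,
                    "flux": np.exp(eta + eps),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def _design(observations: pd.DataFrame, model: CandidateModel) -> pd.DataFrame:
    cols = {"intercept": np.ones(len(observations))}
    for term in model.terms:
        cols[term] = np.asarray(TERMS[term](observations), dtype=float)
    return pd.DataFrame(cols, index=observations.index)


def _check_rank(x: pd.DataFrame) -> None:
    mat = x.to_numpy()
    if np.linalg.matrix_rank(mat) < mat.shape[1]:
        # name the columns involved in the deficiency
        bad = []
        for j in range(1, mat.shape[1]):
            if np.linalg.matrix_rank(mat[:, : j + 1]) < j + 1:
                bad.append(x.columns[j])
        raise FitError(f"collinear fixed-effect design; offending terms: {bad}")


def _prepare(observations: pd.DataFrame) -> pd.DataFrame:
    obs = observations.copy()
    n_bad = int((obs["flux"] <= 0).sum())
    if n_bad:
        logger.info("dropping %d non-positive flux observations before log transform", n_bad)
        obs = obs[obs["flux"] > 0]
    return obs


def fit_lmm(observations: pd.DataFrame, model: CandidateModel) -> MixedFit:
    """REML fit of log flux on the candidate's fixed-effect terms with a
    random intercept per plot.

    Requires at least two plots and more observations than fixed-effect
    terms. The reported AIC comes from an ML refit of the same structure,
    so AICs are comparable across fixed-effect structures.
    """
    obs = _prepare(observations)
    groups = obs["plot"]
    if groups.nunique() < 2:
        raise ValueError("need observations from at least 2 plots for a random intercept")
    x = _design(obs, model)
    if len(obs) <= x.shape[1]:
        raise ValueError("need more observations than fixed-effect terms")
    _check_rank(x)
    y = np.log(obs["flux"].to_numpy())

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            reml = MixedLM(y, x, groups=groups).fit(reml=True)
            ml = MixedLM(y, x, groups=groups).fit(reml=False)
        except np.linalg.LinAlgError as err:  # pragma: no cover
            raise FitError(f"mixed-model fit failed for {model.id}: {err}") from err

    coefficients = dict(zip(x.columns, reml.fe_params))
    ci = reml.conf_int().loc[list(x.columns)]
    conf_int = {k: (float(ci.loc[k, 0]), float(ci.loc[k, 1])) for k in x.columns}
    var_plot = float(np.asarray(reml.cov_re)[0, 0])
    var_resid = float(reml.scale)
    # ML AIC: fixed effects + random-intercept variance + residual variance
    k_params = x.shape[1] + 2
    aic = float(-2.0 * ml.llf + 2.0 * k_params)

    var_fixed = float(np.var(x.to_numpy() @ reml.fe_params))
    total = var_fixed + var_plot + var_resid
    fit = MixedFit(
        model_id=model.id,
        coefficients=coefficients,
        conf_int=conf_int,
        var_plot=var_plot,
        var_resid=var_resid,
        r2_marginal=var_fixed / total,
        r2_conditional=(var_fixed + var_plot) / total,
        aic=aic,
        n_obs=len(obs),
        n_plots=int(groups.nunique()),
    )
    return fit


def marginal_r2(fit: MixedFit, observations: pd.DataFrame) -> float:
    """Nakagawa-Schielzeth marginal R2 recomputed from the fit and its
    observations: variance of the fixed-effect predictions over the total
    (fixed + plot random-intercept + residual) variance."""
    obs = _prepare(observations)
    model = CandidateModel(id=fit.model_id, terms=tuple(t for t in fit.coefficients if t != "intercept"))
    x = _design(obs, model)
    beta = np.array([fit.coefficients[c] for c in x.columns])
    var_fixed = float(np.var(x.to_numpy() @ beta))
    return var_fixed / (var_fixed + fit.var_plot + fit.var_resid)


def rank_candidates(
    candidates: list[CandidateModel], observations: pd.DataFrame
) -> pd.DataFrame:
    """Fit every candidate and rank by AIC (ties broken by fewer terms,
    then registry order). Returns the ranking table with one row per
    candidate; failed fits are kept with their error message."""
    records = []
    fits = {}
    for order, cand in enumerate(candidates):
        try:
            fit = fit_lmm(observations, cand)
            fits[cand.id] = (cand, fit)
            records.append(
                {
                    "model_id": cand.id,
                    "n_terms": len(cand.terms),
                    "aic": fit.aic,
                    "r2_marginal": fit.r2_marginal,
                    "r2_conditional": fit.r2_conditional,
                    "order": order,
                    "error": "",
                }
            )
        except (FitError, ValueError) as err:
            records.append(
                {
                    "model_id": cand.id,
                    "n_terms": len(cand.terms),
                    "aic": np.inf,
                    "r2_marginal": np.nan,
                    "r2_conditional": np.nan,
                    "order": order,
                    "error": str(err),
                }
            )
    table = pd.DataFrame(records).sort_values(
        ["aic", "n_terms", "order"], kind="stable"
    ).reset_index(drop=True)
    table.attrs["fits"] = fits
    return table


def select_best(
    candidates: list[CandidateModel], observations: pd.DataFrame
) -> tuple[CandidateModel, MixedFit]:
    """Return the AIC-best candidate and its fit (see ``rank_candidates``)."""
    if not candidates:
        raise ValueError("candidate list must be non-empty")
    table = rank_candidates(candidates, observations)
    fits = table.attrs["fits"]
    if not fits:
        details = "; ".join(f"{r.model_id}: {r.error}" for r in table.itertuples())
        raise FitError(f"all candidate fits failed — {details}")
    winner_id = table.loc[table["aic"] < np.inf, "model_id"].iloc[0]
    return fits[winner_id]


def partition_rs(rs_total, rhet):
    """Autotrophic soil respiration as total minus heterotrophic.

    Negative results (field noise where measured Rhet exceeds total Rs)
    are returned as-is with a warning, not rejected.
    """
    raut = np.asarray(rs_total, dtype=float) - np.asarray(rhet, dtype=float)
    n_neg = int(np.sum(raut < 0))
    if n_neg:
        warnings.warn(
            f"{n_neg} partitioned R_aut value(s) are negative (Rhet > Rs); "
            "likely measurement noise",
            stacklevel=2,
        )
    return float(raut) if raut.ndim == 0 else raut
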