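"""Random-intercept linear mixed models for the repeated-measures design.

Each animal is tested once at each temperature, so every response is modelled
with a per-animal random intercept: ``y ~ fixed terms + (1 | animal)``.  Fits
use restricted maximum likelihood (statsmodels ``MixedLM``) with Wald 95%
confidence intervals and normal-approximation p-values; Satterthwaite-type
degree-of-freedom corrections are deliberately not applied and reports say
so implicitly by calling the intervals Wald.

The analysis table has one row per animal x temperature with columns
``animal_id``, ``temperature`` (two-level, 17 as reference), ``median_vpd``,
``median_rh``, ``log_mb``, ``log_ewl``, ``log_rer``, ``total_distance_m``.
Four model presets mirror the study's families:

* ``vpd``:  median_vpd ~ temperature + log_mb
* ``rh``:   median_rh  ~ temperature + log_mb
* ``ewl``:  log_ewl    ~ median_vpd + temperature + log_mb + total_distance_m
* ``rer``:  log_rer    ~ log_ewl + temperature + log_mb

Repeatability is the intraclass correlation ICC = tau00 / (tau00 + sigma2);
explained variance is partitioned into marginal R^2 (fixed effects only) and
conditional R^2 (fixed + random), the variance-partition definitions of
Nakagawa & Schielzeth for a Gaussian response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning
from statsmodels.tsa.stattools import acf as _acf

__all__ = [
    "FixedEffect",
    "ModelFit",
    "DiagnosticsReport",
    "MODEL_PRESETS",
    "fit_random_intercept_lmm",
    "fit_preset",
    "icc",
    "r2_nakagawa",
    "marginal_means",
    "residual_diagnostics",
]

_Z975 = float(scipy.stats.norm.ppf(0.975))


@dataclass(frozen=True)
class FixedEffect:
    term: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass
class ModelFit:
    """Summary of one random-intercept LMM fit.

    Keeps a handle on the underlying statsmodels result so that marginal
    means and diagnostics can be computed on demand.
    """

    formula: str
    response: str
    fixed_effects: dict[str, FixedEffect]
    sigma2: float
    tau00: float
    icc: float
    r2_marginal: float
    r2_conditional: float
    n_obs: int
    n_groups: int
    converged: bool
    warnings_: list = dc_field(default_factory=list, repr=False)
    result: object = dc_field(default=None, repr=False, compare=False)
    data: pd.DataFrame = dc_field(default=None, repr=False, compare=False)

    def term(self, substring: str) -> FixedEffect:
        """The unique fixed effect whose term name contains ``substring``."""
        hits = [fe for name, fe in self.fixed_effects.items() if substring in name]
        if len(hits) != 1:
            raise KeyError(
                f"{substring!r} matches {len(hits)} fixed-effect terms "
                f"of {list(self.fixed_effects)}"
            )
        return hits[0]


#: (response, fixed terms, printed-formula label) per model family.
MODEL_PRESETS = {
    "vpd": (
        "median_vpd",
        ["C(temperature)", "log_mb"],
        "VPD~temperature+logMb+(1|ID)",
    ),
    "rh": (
        "median_rh",
        ["C(temperature)", "log_mb"],
        "RH~temperature+logMb+(1|ID)",
    ),
    "ewl": (
        "log_ewl",
        ["median_vpd", "C(temperature)", "log_mb", "total_distance_m"],
        "logEWL~VPD+temperature+logMb+Dt+(1|ID)",
    ),
    "rer": (
        "log_rer",
        ["log_ewl", "C(temperature)", "log_mb"],
        "logRER~logEWL+temperature+logMb+(1|ID)",
    ),
}


def icc(tau00: float, sigma2: float) -> float:
    """Intraclass correlation tau00 / (tau00 + sigma2); repeatability across trials."""
    if tau00 < 0.0 or sigma2 < 0.0:
        raise ValueError("variance components must be non-negative")
    if tau00 == 0.0 and sigma2 == 0.0:
        raise ValueError("ICC undefined when both variance components are zero")
    return tau00 / (tau00 + sigma2)


def _check_design(exog: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        # name a column whose removal does not lower the rank (it is redundant)
        for j, name in enumerate(names):
            reduced = np.delete(exog, j, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                raise ValueError(f"singular fixed-effect design: term {name!r} is redundant")
        raise ValueError("singular fixed-effect design")


def fit_random_intercept_lmm(
    table: pd.DataFrame,
    response: str,
    fixed_terms: list[str],
    group_col: str = "animal_id",
    reml: bool = True,
) -> ModelFit:
    """REML fit of ``response ~ fixed_terms`` with a per-animal random intercept.

    Wald 95% CIs and normal-approximation p-values for the fixed effects;
    ``sigma2`` is the residual variance and ``tau00`` the between-animal
    intercept variance.  A rank-deficient fixed-effect design is rejected
    with the redundant term named; non-convergence is reported in
    ``converged``/``warnings_`` rather than hidden.
    """
    missing = [c for c in [response, group_col] if c not in table.columns]
    if missing:
        raise ValueError(f"analysis table lacks columns {missing}")
    formula = f"{response} ~ " + " + ".join(fixed_terms)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = smf.mixedlm(formula, data=table, groups=table[group_col])
        _check_design(np.asarray(model.exog, dtype=float), list(model.exog_names))
        result = model.fit(reml=reml)
    messages = [str(w.message) for w in caught if issubclass(w.category, (ConvergenceWarning, UserWarning))]

    k_fe = model.k_fe
    fe_names = list(model.exog_names)
    fe = {}
    cov_fe = np.asarray(result.cov_params())[:k_fe, :k_fe]
    for j, name in enumerate(fe_names):
        est = float(result.fe_params.iloc[j])
        se = float(np.sqrt(cov_fe[j, j]))
        fe[name] = FixedEffect(
            term=name,
            estimate=est,
            se=se,
            ci_low=est - _Z975 * se,
            ci_high=est + _Z975 * se,
            p_value=float(2.0 * scipy.stats.norm.sf(abs(est) / se)) if se > 0 else float("nan"),
        )

    sigma2 = float(result.scale)
    tau00 = max(float(np.asarray(result.cov_re)[0, 0]), 0.0)
    fit = ModelFit(
        formula=formula + f" + (1|{group_col})",
        response=response,
        fixed_effects=fe,
        sigma2=sigma2,
        tau00=tau00,
        icc=icc(tau00, sigma2),
        r2_marginal=float("nan"),
        r2_conditional=float("nan"),
        n_obs=int(model.nobs),
        n_groups=int(model.n_groups),
        converged=bool(result.converged),
        warnings_=messages,
        result=result,
        data=table.reset_index(drop=True),
    )
    fit.r2_marginal, fit.r2_conditional = r2_nakagawa(fit)
    return fit


def fit_preset(table: pd.DataFrame, preset: str, **kwargs) -> ModelFit:
    """Fit one of the named model families (``vpd``, ``rh``, ``ewl``, ``rer``)."""
    if preset not in MODEL_PRESETS:
        raise KeyError(f"unknown preset {preset!r}; choose from {sorted(MODEL_PRESETS)}")
    response, terms, label = MODEL_PRESETS[preset]
    fit = fit_random_intercept_lmm(table, response, terms, **kwargs)
    fit.formula = label
    return fit


def r2_nakagawa(fit: ModelFit) -> tuple[float, float]:
    """Variance-partition (marginal, conditional) R^2 of a Gaussian LMM.

    marginal = var_fixed / (var_fixed + tau00 + sigma2);
    conditional adds tau00 to the numerator.  ``var_fixed`` is the variance of
    the fixed-effect linear predictor over the observed design.
    """
    result = fit.result
    model = result.model
    linpred = np.asarray(model.exog, dtype=float) @ np.asarray(result.fe_params, dtype=float)
    var_fixed = float(np.var(linpred, ddof=1)) if linpred.size > 1 else 0.0
    total = var_fixed + fit.tau00 + fit.sigma2
    if total <= 0.0:
        raise ValueError("zero total variance; R^2 undefined")
    return var_fixed / total, (var_fixed + fit.tau00) / total


def marginal_means(fit: ModelFit, term: str) -> pd.DataFrame:
    """Marginal (adjusted) mean response per level of a categorical predictor.

    Predicts at each level of ``term`` with every other covariate held at its
    sample mean (numeric) or mode (categorical), using the fixed-effect
    covariance for Wald 95% CIs.  ``term`` is the underlying column name,
    e.g. ``temperature`` for a ``C(temperature)`` model term.
    """
    data = fit.data
    if term not in data.columns:
        raise KeyError(f"term {term!r} is not a column of the analysis table")
    design_info = fit.result.model.data.design_info
    if not any(term in name for name in design_info.column_names):
        raise KeyError(f"term {term!r} was not a fitted fixed effect")
    levels = np.sort(data[term].unique())
    pred = {}
    for col in data.columns:
        if col == term:
            continue
        if pd.api.types.is_numeric_dtype(data[col]):
            pred[col] = float(data[col].mean())
        else:
            pred[col] = data[col].mode().iloc[0]
    rows = pd.DataFrame([{**pred, term: lev} for lev in levels])
    from patsy import build_design_matrices

    (X,) = build_design_matrices([design_info], rows)
    X = np.asarray(X, dtype=float)
    beta = np.asarray(fit.result.fe_params, dtype=float)
    k_fe = fit.result.model.k_fe
    cov_fe = np.asarray(fit.result.cov_params())[:k_fe, :k_fe]
    mean = X @ beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", X, cov_fe, X))
    return pd.DataFrame(
        {
            "level": levels,
            "mean": mean,
            "se": se,
            "ci_low": mean - _Z975 * se,
            "ci_high": mean + _Z975 * se,
        }
    )


@dataclass(frozen=True)
class DiagnosticsReport:
    """Residual autocorrelation and normality checks for one fit."""

    lags: np.ndarray
    autocorrelations: np.ndarray
    band: float
    n_lags_outside: int
    autocorrelation_flag: bool
    shapiro_statistic: float
    shapiro_p: float


def residual_diagnostics(residuals_or_fit, n_lags: int = 10) -> DiagnosticsReport:
    """Lag-1..10 residual autocorrelations with +-1.96/sqrt(n) bands and a
    Shapiro-Wilk normality statistic.

    The autocorrelation flag raises when more than one lag falls outside the
    white-noise band.  Accepts a :class:`ModelFit` or a residual vector in
    observation order; needs at least 10 residuals.
    """
    if isinstance(residuals_or_fit, ModelFit):
        resid = np.asarray(residuals_or_fit.result.resid, dtype=float)
    else:
        resid = np.asarray(residuals_or_fit, dtype=float)
    if resid.size < 10:
        raise ValueError(f"need >=10 residuals for diagnostics, got {resid.size}")
    n_lags = min(n_lags, resid.size - 1)
    rho = _acf(resid, nlags=n_lags, fft=False)[1:]
    band = _Z975 / np.sqrt(resid.size)
    outside = int(np.sum(np.abs(rho) > band))
    stat, p = scipy.stats.shapiro(resid)
    return DiagnosticsReport(
        lags=np.arange(1, n_lags + 1),
        autocorrelations=rho,
        band=float(band),
        n_lags_outside=outside,
        autocorrelation_flag=outside > 1,
        shapiro_statistic=float(stat),
        shapiro_p=float(p),
    )
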