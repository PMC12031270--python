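"""Common-slope trend regression of shape factors against exposure time.

The full ANCOVA model  β ~ group + time + group×time  is fitted first; the
interaction F-test judges slope equality.  The reported model is the
parallel-lines (common-slope) fit — one slope per feature, distinct
intercepts per treatment group — from which R²_adj, the standard error of the
estimate (SEE) and the intercept-difference test are taken.  Residuals are
screened against the four classical hypotheses: zero mean, homoscedasticity
(Breusch–Pagan), no autocorrelation (ACF with ±1.96/√n limits) and normality
(Shapiro–Wilk plus the probability-plot correlation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.diagnostic import het_breuschpagan
from statsmodels.tsa.stattools import acf as _acf

from pearbrowning.classify import SliceRecord, _ALIASES

__all__ = ["TrendModel", "ResidualDiagnostics", "fit_group_lines", "residual_diagnostics"]


@dataclass(frozen=True)
class TrendModel:
    """Parallel-lines fit of one shape factor against exposure time."""

    feature: str
    groups: tuple[str, str]
    slope: float                      # common slope, per minute
    slope_se: float
    intercepts: dict[str, float]      # per-group intercepts at t = 0
    intercept_ses: dict[str, float]
    r2_adj: float                     # percent
    see: float                        # residual standard deviation
    slope_equality_p: float           # interaction F-test from the full model
    intercept_difference_p: float
    fitted: np.ndarray = field(repr=False)
    residuals: np.ndarray = field(repr=False)
    n: int = 0


def fit_group_lines(records: list[SliceRecord], feature: str) -> TrendModel:
    """Fit value ~ group + time with a shared slope after testing the slopes.

    Raises on a singular design (any group observed at fewer than 2 distinct
    timepoints, or fewer than 3 timepoints overall per group as required for
    a meaningful line).
    """
    col = _ALIASES.get(feature, feature)
    groups = sorted({r.group for r in records})
    if len(groups) != 2:
        raise ValueError(f"expected exactly two groups, got {groups}")
    for g in groups:
        times = {r.time_min for r in records if r.group == g}
        if len(times) < 3:
            raise ValueError(f"group {g!r} has fewer than 3 distinct timepoints")
    y = np.array([getattr(r, col) for r in records], dtype=float)
    t = np.array([r.time_min for r in records], dtype=float)
    d = np.array([r.group == groups[1] for r in records], dtype=float)

    # full model with per-group slopes: interaction F-test for slope equality
    X_full = sm.add_constant(np.column_stack([d, t, d * t]))
    full = sm.OLS(y, X_full).fit()
    slope_equality_p = float(full.pvalues[3])

    # reported parallel-lines model
    X = sm.add_constant(np.column_stack([d, t]))
    fit = sm.OLS(y, X).fit()
    a0 = float(fit.params[0])
    a1 = float(fit.params[0] + fit.params[1])
    cov = fit.cov_params()
    a1_se = float(np.sqrt(cov[0, 0] + cov[1, 1] + 2 * cov[0, 1]))
    return TrendModel(
        feature=col,
        groups=(groups[0], groups[1]),
        slope=float(fit.params[2]),
        slope_se=float(fit.bse[2]),
        intercepts={groups[0]: a0, groups[1]: a1},
        intercept_ses={groups[0]: float(fit.bse[0]), groups[1]: a1_se},
        r2_adj=float(fit.rsquared_adj * 100.0),
        see=float(np.sqrt(fit.mse_resid)),
        slope_equality_p=slope_equality_p,
        intercept_difference_p=float(fit.pvalues[1]),
        fitted=np.asarray(fit.fittedvalues),
        residuals=np.asarray(fit.resid),
        n=len(records),
    )


@dataclass(frozen=True)
class ResidualDiagnostics:
    """The four residual hypothesis checks; reported, never gating."""

    residual_mean: float
    bp_statistic: float          # Breusch–Pagan LM statistic
    bp_p: float
    acf: np.ndarray              # lags 0..max_lag, acf[0] == 1
    acf_limit: float             # ±1.96/sqrt(n)
    shapiro_statistic: float
    shapiro_p: float
    probplot_r: float            # probability-plot correlation coefficient


def residual_diagnostics(model: TrendModel, *, max_lag: int = 24) -> ResidualDiagnostics:
    """Zero-mean, homoscedasticity, autocorrelation and normality checks."""
    e = model.residuals
    n = e.size
    exog = sm.add_constant(model.fitted)
    bp_stat, bp_p, _, _ = het_breuschpagan(e, exog)
    nlags = min(max_lag, n - 2)
    acf_vals = _acf(e, nlags=nlags, fft=True)
    sh = stats.shapiro(e)
    (osm, osr), _ = stats.probplot(e)
    r = float(np.corrcoef(osm, osr)[0, 1])
    return ResidualDiagnostics(
        residual_mean=float(e.mean()),
        bp_statistic=float(bp_stat),
        bp_p=float(bp_p),
        acf=acf_vals,
        acf_limit=1.96 / np.sqrt(n),
        shapiro_statistic=float(sh.statistic),
        shapiro_p=float(sh.pvalue),
        probplot_r=r,
    )
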