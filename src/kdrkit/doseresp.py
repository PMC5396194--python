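"""Probit concentration-mortality analysis.

Fits the classical probit dose-response model

    Phi^{-1}(p) = alpha + beta * log10(c)

by binomial maximum likelihood, reports lethal concentrations (LC50 and
arbitrary quantiles) with Fieller 95% confidence limits, a Pearson chi-square
goodness-of-fit test with heterogeneity correction, and resistance ratios
(LC50_resistant / LC50_susceptible) with confidence intervals obtained by the
delta method on log10 LC50, significant when the interval excludes 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "SeparationError",
    "NonMonotoneError",
    "ProbitRegressor",
    "ResistanceRatio",
    "abbott_correct",
    "fit_probit",
    "lc_at",
    "lc50_ratio",
    "resistance_ratio",
    "summary_table",
]

#: canonical column names of a concentration-mortality table
TABLE_COLUMNS = ("concentration", "n_exposed", "n_dead")


class SeparationError(ValueError):
    """All responses are 0% or 100%: the slope is not identifiable."""


class NonMonotoneError(ValueError):
    """The fitted slope is non-positive: mortality does not increase with dose."""


def abbott_correct(table: pd.DataFrame) -> pd.DataFrame:
    """Correct treated mortality for control (natural) mortality.

    The table must contain at least one control row (concentration == 0).
    Each treated mortality p is replaced by max(0, (p - p_c) / (1 - p_c))
    where p_c is the pooled control mortality; the corrected proportions are
    carried as effective (possibly non-integer) death counts and the control
    rows are dropped.  When the control mortality is exactly 0 the input is
    returned unchanged.
    """
    table = table.reset_index(drop=True)
    control = table["concentration"] == 0
    if not control.any():
        raise ValueError("no control row (concentration == 0) found")
    n_c = float(table.loc[control, "n_exposed"].sum())
    d_c = float(table.loc[control, "n_dead"].sum())
    p_c = d_c / n_c
    if p_c >= 1.0:
        raise ValueError("control mortality is 100%; correction undefined")
    if p_c == 0.0:
        return table.copy()
    out = table.loc[~control].copy()
    p = out["n_dead"].to_numpy(float) / out["n_exposed"].to_numpy(float)
    p_adj = np.maximum(0.0, (p - p_c) / (1.0 - p_c))
    out["n_dead"] = p_adj * out["n_exposed"].to_numpy(float)
    return out.reset_index(drop=True)


def _fieller_ratio_ci(a, b, v_aa, v_bb, v_ab, q):
    """Fieller confidence limits for the ratio a/b of jointly normal estimates.

    Returns (lo, hi); (nan, nan) when g >= 1 (the denominator is not
    significantly different from zero and the interval is unbounded).
    """
    theta = a / b
    g = q * q * v_bb / (b * b)
    if g >= 1.0:
        return (np.nan, np.nan)
    disc = v_aa - 2.0 * theta * v_ab + theta * theta * v_bb - g * (v_aa - v_ab * v_ab / v_bb)
    if disc < 0:
        disc = 0.0
    half = (q / abs(b)) * np.sqrt(disc)
    centre = theta - g * v_ab / v_bb
    lo = (centre - half) / (1.0 - g)
    hi = (centre + half) / (1.0 - g)
    return (lo, hi)


class ProbitRegressor(BaseEstimator):
    """Binomial probit dose-response model on log10 concentration.

    Parameters
    ----------
    ci_level : float
        Confidence level for lethal-concentration intervals (default 0.95).
    heterogeneity_alpha : float
        Lack-of-fit significance level below which the parameter covariance is
        inflated by chi2/df and the normal quantile replaced by a t quantile
        with k-2 degrees of freedom (default 0.05).

    Fitted attributes (trailing underscore) include ``alpha_``, ``beta_``,
    ``beta_se_``, ``vcov_``, ``lc50_``, ``lc50_ci_``, ``chi2_``, ``df_``,
    ``p_value_``, ``heterogeneity_`` and ``n_total_``.
    """

    def __init__(self, ci_level: float = 0.95, heterogeneity_alpha: float = 0.05):
        self.ci_level = ci_level
        self.heterogeneity_alpha = heterogeneity_alpha

    # ------------------------------------------------------------------ fit
    def fit(self, concentration, n_dead, n_exposed):
        c = np.asarray(concentration, dtype=float)
        d = np.asarray(n_dead, dtype=float)
        n = np.asarray(n_exposed, dtype=float)
        if c.shape != d.shape or c.shape != n.shape:
            raise ValueError("concentration, n_dead and n_exposed must have equal length")
        if np.any(c <= 0):
            bad = c[c <= 0][0]
            raise ValueError(
                f"non-positive concentration {bad!r}: apply abbott_correct first "
                "and pass treated rows only"
            )
        if np.any(d < 0) or np.any(d > n):
            raise ValueError("death counts must satisfy 0 <= n_dead <= n_exposed")

        # pool replicates at the same concentration
        df = (
            pd.DataFrame({"c": c, "d": d, "n": n})
            .groupby("c", as_index=False)
            .sum()
            .sort_values("c")
        )
        cg = df["c"].to_numpy()
        dg = df["d"].to_numpy()
        ng = df["n"].to_numpy()
        k = len(cg)
        if k < 3:
            raise ValueError(f"need >= 3 distinct positive concentrations, got {k}")
        pg = dg / ng
        if not np.any((pg > 0) & (pg < 1)):
            raise SeparationError(
                "complete separation: every concentration group responded 0% or "
                "100%; the probit slope has no finite maximum-likelihood estimate"
            )

        x = np.log10(cg)
        endog = np.column_stack([dg, ng - dg])
        exog = sm.add_constant(x)
        model = sm.GLM(endog, exog, family=sm.families.Binomial(sm.families.links.Probit()))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(tol=1e-10, maxiter=200)
        alpha, beta = res.params
        if not np.all(np.isfinite(res.params)):
            raise SeparationError("probit fit diverged: no finite estimates")
        if beta <= 0:
            raise NonMonotoneError(
                f"fitted slope {beta:.4g} <= 0: mortality does not increase with dose"
            )
        vcov = np.asarray(res.cov_params())

        # Pearson chi-square on pooled concentration groups
        phat = stats.norm.cdf(alpha + beta * x)
        phat = np.clip(phat, 1e-12, 1 - 1e-12)
        chi2 = float(np.sum((dg - ng * phat) ** 2 / (ng * phat * (1 - phat))))
        dof = k - 2
        p_value = float(stats.chi2.sf(chi2, dof)) if dof > 0 else np.nan

        heterogeneity = 1.0
        tail = (1.0 - self.ci_level) / 2.0
        quantile = stats.norm.ppf(1.0 - tail)
        if dof > 0 and p_value < self.heterogeneity_alpha:
            heterogeneity = chi2 / dof
            vcov = vcov * heterogeneity
            quantile = stats.t.ppf(1.0 - tail, dof)

        self.alpha_ = float(alpha)
        self.beta_ = float(beta)
        self.beta_se_ = float(np.sqrt(vcov[1, 1]))
        self.vcov_ = vcov
        self.quantile_ = float(quantile)
        self.chi2_ = chi2
        self.df_ = dof
        self.p_value_ = p_value
        self.heterogeneity_ = float(heterogeneity)
        self.n_total_ = float(ng.sum())
        self.loglik_ = float(res.llf)
        self.lc50_, self.lc50_ci_ = self.lc(0.5)
        return self

    # -------------------------------------------------------------- queries
    def predict(self, concentration):
        """Expected mortality proportion at each concentration."""
        c = np.asarray(concentration, dtype=float)
        return stats.norm.cdf(self.alpha_ + self.beta_ * np.log10(c))

    def lc(self, p: float):
        """Lethal concentration for mortality quantile p with Fieller CI."""
        if not 0.0 < p < 1.0:
            raise ValueError(f"mortality quantile must be in (0, 1), got {p}")
        z = stats.norm.ppf(p)
        a = z - self.alpha_
        b = self.beta_
        v_aa = self.vcov_[0, 0]
        v_bb = self.vcov_[1, 1]
        v_ab = -self.vcov_[0, 1]
        theta = a / b
        lo, hi = _fieller_ratio_ci(a, b, v_aa, v_bb, v_ab, self.quantile_)
        return 10.0 ** theta, (10.0 ** lo, 10.0 ** hi)

    def var_log10_lc(self, p: float = 0.5) -> float:
        """Delta-method variance of log10 LC_p from the parameter covariance."""
        z = stats.norm.ppf(p)
        theta = (z - self.alpha_) / self.beta_
        grad = np.array([-1.0 / self.beta_, -theta / self.beta_])
        return float(grad @ self.vcov_ @ grad)


@dataclass(frozen=True)
class ResistanceRatio:
    """LC50 ratio of a resistant over a susceptible strain."""

    rr: float
    ci95: tuple
    significant: bool
    se_log10: float


def fit_probit(table: pd.DataFrame, **kwargs) -> ProbitRegressor:
    """Fit the probit model to a concentration-mortality table.

    Control rows (concentration == 0) must be removed or corrected first
    (see :func:`abbott_correct`).
    """
    return ProbitRegressor(**kwargs).fit(
        table["concentration"], table["n_dead"], table["n_exposed"]
    )


def lc_at(fit: ProbitRegressor, p: float):
    """Lethal concentration at mortality quantile p, with Fieller 95% CI."""
    return fit.lc(p)


def lc50_ratio(lc50_resistant: float, lc50_susceptible: float) -> float:
    """Point resistance ratio from two LC50 values."""
    if lc50_resistant <= 0 or lc50_susceptible <= 0:
        raise ValueError("LC50 values must be positive")
    return lc50_resistant / lc50_susceptible


def resistance_ratio(
    fit_resistant: ProbitRegressor, fit_susceptible: ProbitRegressor
) -> ResistanceRatio:
    """Resistance ratio with 95% CI from two fitted probit models.

    The variance of log10 RR is the sum of the delta-method variances of the
    two log10 LC50s; the interval is 10**(log10 rr +- z * SE) and the ratio is
    significant when the interval excludes 1.
    """
    for f in (fit_resistant, fit_susceptible):
        if not np.isfinite(getattr(f, "lc50_", np.nan)):
            raise ValueError("resistance ratio undefined: a probit fit is not finite")
    rr = fit_resistant.lc50_ / fit_susceptible.lc50_
    var = fit_resistant.var_log10_lc(0.5) + fit_susceptible.var_log10_lc(0.5)
    se = float(np.sqrt(var))
    z = stats.norm.ppf(0.975)
    lo = 10.0 ** (np.log10(rr) - z * se)
    hi = 10.0 ** (np.log10(rr) + z * se)
    return ResistanceRatio(rr=float(rr), ci95=(float(lo), float(hi)),
                           significant=not (lo <= 1.0 <= hi), se_log10=se)


def summary_table(fits: dict) -> pd.DataFrame:
    """Table-1-shaped summary: one row per labelled fit.

    ``fits`` maps a label (e.g. "adults/deltamethrin/susceptible") to a fitted
    :class:`ProbitRegressor`.
    """
    rows = []
    for label, fit in fits.items():
        rows.append(
            {
                "label": label,
                "n": int(fit.n_total_),
                "slope": fit.beta_,
                "slope_se": fit.beta_se_,
                "lc50": fit.lc50_,
                "lc50_lo": fit.lc50_ci_[0],
                "lc50_hi": fit.lc50_ci_[1],
                "chi2": fit.chi2_,
                "df": fit.df_,
                "p_value": fit.p_value_,
            }
        )
    return pd.DataFrame(rows)
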