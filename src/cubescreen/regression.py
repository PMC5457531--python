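"""Ordinary least squares with the report layout used for instrument validation.

A thin wrapper over :mod:`statsmodels` OLS that adds the quantities the
validation tables report: standardized betas, the multiple correlation R, and
the standard error of the estimate (residual standard deviation in response
units), with exact handling of the degenerate constant-response case.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import SingularDesignError

__all__ = ["ols_regress", "RegressionResults"]


@dataclass
class RegressionResults:
    """OLS estimates with validation-report extras.

    ``coefficients``/``std_errors``/``t_values``/``p_values`` are indexed by
    term name with the intercept labelled "(Constant)"; ``betas`` are the
    standardized coefficients (undefined, NaN, for the intercept).
    """

    coefficients: pd.Series
    std_errors: pd.Series
    betas: pd.Series
    t_values: pd.Series
    p_values: pd.Series
    r: float
    r_squared: float
    adjusted_r_squared: float
    see: float
    df_resid: int
    n: int

    def to_dict(self) -> dict:
        terms = {}
        for name in self.coefficients.index:
            terms[str(name)] = {
                "B": float(self.coefficients[name]),
                "SE": float(self.std_errors[name]),
                "beta": None if pd.isna(self.betas[name]) else float(self.betas[name]),
                "t": float(self.t_values[name]),
                "p": float(self.p_values[name]),
            }
        return {
            "n": self.n,
            "df_resid": self.df_resid,
            "R": self.r,
            "R2": self.r_squared,
            "adjusted_R2": self.adjusted_r_squared,
            "SE_of_estimate": self.see,
            "coefficients": terms,
        }

    def summary(self) -> str:
        lines = [
            f"OLS summary: R={self.r:.3f}  R2={self.r_squared:.3f}  "
            f"adj R2={self.adjusted_r_squared:.3f}  SEE={self.see:.3f}  n={self.n}",
            f"{'term':<14}{'B':>10}{'SE':>10}{'beta':>10}{'t':>10}{'p':>12}",
        ]
        for name in self.coefficients.index:
            beta = self.betas[name]
            beta_s = f"{beta:>10.3f}" if pd.notna(beta) else " " * 10
            lines.append(
                f"{str(name):<14}{self.coefficients[name]:>10.3f}"
                f"{self.std_errors[name]:>10.3f}{beta_s}"
                f"{self.t_values[name]:>10.3f}{self.p_values[name]:>12.3g}"
            )
        return "\n".join(lines)


def ols_regress(y, X, names: list[str] | None = None) -> RegressionResults:
    """Fit ``y ~ intercept + X`` by least squares.

    Parameters
    ----------
    y : array-like, shape (n,)
        Response.
    X : array-like or DataFrame, shape (n, p)
        Predictors, without an intercept column (added internally).
    names : list of str, optional
        Predictor names; defaults to DataFrame columns or x1..xp.
    """
    y = np.asarray(y, dtype=float)
    if isinstance(X, pd.DataFrame):
        if names is None:
            names = [str(c) for c in X.columns]
        X = X.to_numpy(dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    n, p = X.shape
    if names is None:
        names = [f"x{i + 1}" for i in range(p)]
    if n <= p + 1:
        raise SingularDesignError("need n > p + 1 observations")
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < p + 1:
        raise SingularDesignError("rank-deficient design matrix")

    fit = sm.OLS(y, design).fit()
    index = ["(Constant)", *names]
    coefficients = pd.Series(fit.params, index=index)
    std_errors = pd.Series(fit.bse, index=index)
    t_values = pd.Series(fit.tvalues, index=index)
    p_values = pd.Series(fit.pvalues, index=index)

    sd_y = float(np.std(y, ddof=1))
    sd_x = np.std(X, axis=0, ddof=1)
    if np.ptp(y) > 0:
        betas = pd.Series(
            [np.nan, *(fit.params[1:] * sd_x / sd_y)], index=index
        )
        r_squared = float(fit.rsquared)
        adjusted = float(fit.rsquared_adj)
    else:
        # Constant response: perfect "fit" to the mean; define R^2 = 0.
        betas = pd.Series([np.nan] + [0.0] * p, index=index)
        r_squared = 0.0
        adjusted = 0.0
        t_values[:] = np.nan
        p_values[:] = np.nan
    see = float(np.sqrt(fit.ssr / fit.df_resid))
    return RegressionResults(
        coefficients=coefficients,
        std_errors=std_errors,
        betas=betas,
        t_values=t_values,
        p_values=p_values,
        r=float(np.sqrt(max(r_squared, 0.0))),
        r_squared=r_squared,
        adjusted_r_squared=adjusted,
        see=see,
        df_resid=int(fit.df_resid),
        n=n,
    )
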