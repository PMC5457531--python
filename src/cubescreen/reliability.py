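"""One-way random-effects intraclass correlation for interrater agreement.

The design matches the pilot validation of the instrument: each child is rated
by a different randomly drawn pair of experts, so the one-way random model
ICC(1) applies.  ``icc_single`` is the reliability of one rater,
``icc_average`` the reliability of the mean of ``k`` raters (the
Spearman-Brown step-up of the single-rater value).  Confidence intervals use
the F-quantile method for the one-way model.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateInputError

__all__ = ["InterraterReliability", "ICCResults"]


def _validate_ratings(ratings) -> np.ndarray:
    m = np.asarray(ratings, dtype=float)
    if m.ndim != 2:
        raise ValueError("ratings must be a 2-D (targets x raters) matrix")
    n, k = m.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 targets and 2 raters")
    if np.isnan(m).any():
        raise ValueError("ratings must have no missing cells")
    return m


@dataclass
class ICCResults:
    """Results of a one-way random-effects ICC analysis."""

    icc_single: float
    icc_average: float
    ci_single: tuple[float, float]
    ci_average: tuple[float, float]
    f_stat: float
    df1: int
    df2: int
    p_value: float
    n: int
    k: int
    msb: float
    msw: float
    confidence: float = 0.95

    @property
    def df2_alt(self) -> int:
        """Alternative residual df convention ``(n-1)(k-1)``.

        The one-way ANOVA residual df is ``n(k-1)``; some statistical packages
        print ``(n-1)(k-1)`` with the same F value.  Both are exposed so
        reports can be compared against either convention.
        """
        return (self.n - 1) * (self.k - 1)

    def conf_int(self, alt_df: bool = False) -> dict[str, tuple[float, float]]:
        """F-quantile confidence intervals, optionally under the alt df."""
        df2 = self.df2_alt if alt_df else self.df2
        alpha = 1.0 - self.confidence
        fl = self.f_stat / stats.f.ppf(1.0 - alpha / 2.0, self.df1, df2)
        fu = self.f_stat * stats.f.ppf(1.0 - alpha / 2.0, df2, self.df1)
        k = self.k
        return {
            "single": ((fl - 1.0) / (fl + k - 1.0), (fu - 1.0) / (fu + k - 1.0)),
            "average": (1.0 - 1.0 / fl, 1.0 - 1.0 / fu),
        }

    def to_dict(self) -> dict:
        return {
            "model": "one-way random (ICC1)",
            "n": self.n,
            "k": self.k,
            "icc_single": self.icc_single,
            "icc_average": self.icc_average,
            "ci_single": list(self.ci_single),
            "ci_average": list(self.ci_average),
            "ci_single_alt_df": list(self.conf_int(alt_df=True)["single"]),
            "ci_average_alt_df": list(self.conf_int(alt_df=True)["average"]),
            "f": self.f_stat,
            "df1": self.df1,
            "df2": self.df2,
            "df2_alt": self.df2_alt,
            "p_value": self.p_value,
            "confidence": self.confidence,
        }

    def summary(self) -> str:
        lines = [
            "One-way random-effects intraclass correlation",
            f"  targets n = {self.n}, raters k = {self.k}",
            f"  ICC single  = {self.icc_single:.3f}  "
            f"({int(self.confidence * 100)}% CI {self.ci_single[0]:.3f}-{self.ci_single[1]:.3f})",
            f"  ICC average = {self.icc_average:.3f}  "
            f"({int(self.confidence * 100)}% CI {self.ci_average[0]:.3f}-{self.ci_average[1]:.3f})",
            f"  F({self.df1},{self.df2}) = {self.f_stat:.2f}, p = {self.p_value:.3g}",
        ]
        return "\n".join(lines)


class InterraterReliability:
    """One-way random ICC model built from an (n targets x k raters) matrix."""

    def __init__(self, ratings) -> None:
        self.ratings = _validate_ratings(ratings)
        self.n, self.k = self.ratings.shape

    def fit(self, confidence: float = 0.95) -> ICCResults:
        """One-way ANOVA decomposition and the derived ICC estimates."""
        if not 0.0 < confidence < 1.0:
            raise ValueError("confidence must lie in (0, 1)")
        m = self.ratings
        n, k = self.n, self.k
        grand = m.mean()
        row_means = m.mean(axis=1)
        msb = k * np.sum((row_means - grand) ** 2) / (n - 1)
        msw = np.sum((m - row_means[:, None]) ** 2) / (n * (k - 1))
        if msb <= 0 and msw <= 0:
            raise DegenerateInputError("all ratings identical: ICC undefined")
        if msw == 0:
            icc_single = icc_average = 1.0
            f = np.inf
        else:
            f = msb / msw
            icc_single = (msb - msw) / (msb + (k - 1) * msw)
            icc_average = (msb - msw) / msb
        df1, df2 = n - 1, n * (k - 1)
        p = float(stats.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
        res = ICCResults(
            icc_single=float(icc_single),
            icc_average=float(icc_average),
            ci_single=(np.nan, np.nan),
            ci_average=(np.nan, np.nan),
            f_stat=float(f),
            df1=df1,
            df2=df2,
            p_value=p,
            n=n,
            k=k,
            msb=float(msb),
            msw=float(msw),
            confidence=confidence,
        )
        if np.isfinite(f):
            ci = res.conf_int(alt_df=False)
            res.ci_single = tuple(float(x) for x in ci["single"])
            res.ci_average = tuple(float(x) for x in ci["average"])
        else:
            res.ci_single = (1.0, 1.0)
            res.ci_average = (1.0, 1.0)
        return res
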