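"""Between-group statistics: Welch's ANOVA and the chi-square goodness-of-fit.

Welch's ANOVA compares group means without assuming equal variances.
With groups :math:`i = 1..k` of size :math:`n_i`, mean :math:`m_i` and
variance :math:`s_i^2`, let :math:`w_i = n_i / s_i^2`, :math:`W = \\sum w_i`
and :math:`\\bar{x}_w = \\sum w_i m_i / W`. Then

.. math::

   F = \\frac{\\sum w_i (m_i - \\bar{x}_w)^2 / (k - 1)}
            {1 + \\frac{2(k-2)}{k^2-1} \\Lambda},
   \\qquad
   \\Lambda = \\sum_i \\frac{(1 - w_i/W)^2}{n_i - 1},

with numerator df :math:`k-1` and Welch-Satterthwaite denominator df
:math:`(k^2-1)/(3\\Lambda)`.

The goodness-of-fit test is the classical :math:`\\chi^2 = \\sum (O-E)^2/E`
with :math:`k-1` degrees of freedom; expected counts may be given as
counts or proportions (normalised to the observed total).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class WelchAnovaResult:
    statistic: float
    df_num: float
    df_den: float
    pvalue: float

    def as_dict(self) -> dict:
        return {
            "test": "welch_anova",
            "statistic": float(self.statistic),
            "df_num": float(self.df_num),
            "df_den": float(self.df_den),
            "p": round(float(self.pvalue), 3),
            "p_exact": float(self.pvalue),
        }


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    pvalue: float

    def as_dict(self) -> dict:
        return {
            "test": "chi_square_gof",
            "statistic": float(self.statistic),
            "df": int(self.df),
            "p": round(float(self.pvalue), 3),
            "p_exact": float(self.pvalue),
        }


def welch_anova(samples: Mapping[str, Sequence[float]]) -> WelchAnovaResult:
    """Welch's heteroscedastic one-way ANOVA over labelled groups.

    Requires at least two groups, each with at least two observations and
    positive variance.
    """
    groups = [np.asarray(v, dtype=float) for v in samples.values()]
    k = len(groups)
    if k < 2:
        raise ValueError("Welch's ANOVA needs at least two groups")
    n = np.array([len(g) for g in groups], dtype=float)
    if np.any(n < 2):
        raise ValueError("every group needs at least two observations")
    m = np.array([g.mean() for g in groups])
    s2 = np.array([g.var(ddof=1) for g in groups])
    if np.any(s2 <= 0):
        raise ValueError("degenerate group variance")
    w = n / s2
    W = w.sum()
    xw = (w * m).sum() / W
    lam = (((1.0 - w / W) ** 2) / (n - 1.0)).sum()
    num = (w * (m - xw) ** 2).sum() / (k - 1)
    den = 1.0 + (2.0 * (k - 2.0) / (k**2 - 1.0)) * lam
    f = num / den
    df_num = k - 1.0
    df_den = (k**2 - 1.0) / (3.0 * lam)
    p = float(sps.f.sf(f, df_num, df_den))
    return WelchAnovaResult(float(f), df_num, float(df_den), p)


def chi_square_gof(
    observed: Sequence[float], expected: Sequence[float] | None = None
) -> ChiSquareResult:
    """Chi-square goodness-of-fit of observed counts against expected.

    ``expected`` may be absolute counts or proportions; it is rescaled to
    the observed total. A uniform expectation is used when omitted. Every
    expected cell must be positive.
    """
    obs = np.asarray(observed, dtype=float)
    if expected is None:
        exp = np.full_like(obs, obs.sum() / len(obs))
    else:
        exp = np.asarray(expected, dtype=float)
        if np.any(exp <= 0):
            raise ValueError("expected counts must all be positive")
        exp = exp * (obs.sum() / exp.sum())
    stat, p = sps.chisquare(obs, exp)
    return ChiSquareResult(float(stat), len(obs) - 1, float(p))
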