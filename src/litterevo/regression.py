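"""Exhaustive best-subset OLS of ln(k) on ln-scale leaf traits.

Every non-empty subset of the K candidate predictors is fit by ordinary
least squares with intercept (2^K - 1 models; K = 7 traits is 127 fits) and
scored with the Gaussian maximum-likelihood AIC/AICc, counting the intercept
and the residual variance among the p = |predictors| + 2 parameters.  The
ranked models feed :mod:`litterevo.selection` for Akaike weights and the
95% confidence set.  Inputs are assumed already ln-transformed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .selection import aic as _aic, aicc as _aicc

__all__ = [
    "SubsetModel",
    "SimpleRegressionResult",
    "gaussian_ols_lnl",
    "all_subsets",
    "simple_regression",
    "subset_report",
]


def gaussian_ols_lnl(rss: float, n: int) -> float:
    """Maximized Gaussian log-likelihood of an OLS fit with residual sum of
    squares ``rss``: lnL = -(n/2) (ln(2 pi rss / n) + 1)."""
    if n < 2:
        raise ValueError("need n >= 2")
    if rss <= 0:
        raise ValueError("degenerate fit: RSS must be > 0")
    return -(n / 2.0) * (math.log(2.0 * math.pi * rss / n) + 1.0)


@dataclass
class SubsetModel:
    predictors: tuple[str, ...]
    coefficients: np.ndarray  # intercept first, then predictor order
    rss: float
    r_squared: float
    lnL: float
    p: int  # |predictors| + intercept + residual variance
    n: int
    aic: float
    aicc: float
    rank_deficient: bool = False

    @property
    def label(self) -> str:
        return " + ".join(self.predictors)


@dataclass
class SimpleRegressionResult:
    trait: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def _fit_subset(y: np.ndarray, X: np.ndarray, names: tuple[str, ...]) -> SubsetModel:
    n = len(y)
    design = np.column_stack([np.ones(n), X])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    deficient = rank < design.shape[1]
    resid = y - design @ coef
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    p = len(names) + 2
    if deficient or rss <= 0:
        return SubsetModel(
            predictors=names, coefficients=coef, rss=rss, r_squared=r2,
            lnL=math.nan, p=p, n=n, aic=math.nan, aicc=math.nan,
            rank_deficient=True,
        )
    lnl = gaussian_ols_lnl(rss, n)
    return SubsetModel(
        predictors=names, coefficients=coef, rss=rss, r_squared=r2,
        lnL=lnl, p=p, n=n, aic=_aic(lnl, p), aicc=_aicc(lnl, p, n),
    )


def all_subsets(response: np.ndarray, predictors: pd.DataFrame) -> list[SubsetModel]:
    """Fit one OLS model per non-empty predictor subset.

    ``predictors`` is a species-by-trait DataFrame aligned to ``response``;
    rank-deficient subsets are returned flagged (NaN scores) so callers can
    exclude them from ranking.
    """
    y = np.asarray(response, dtype=float)
    if len(y) != len(predictors):
        raise ValueError("response and predictor table lengths differ")
    names = list(predictors.columns)
    k = len(names)
    if len(y) <= k + 2:
        raise ValueError(
            f"need n > K + 2 (n={len(y)}, K={k}) for the full model"
        )
    X = predictors.to_numpy(dtype=float)
    out = []
    for size in range(1, k + 1):
        for combo in combinations(range(k), size):
            out.append(
                _fit_subset(y, X[:, combo], tuple(names[i] for i in combo))
            )
    return out


def simple_regression(
    response: np.ndarray, trait: np.ndarray, name: str = ""
) -> SimpleRegressionResult:
    """Single-predictor OLS with a two-sided t test on the slope."""
    y = np.asarray(response, dtype=float)
    x = np.asarray(trait, dtype=float)
    if len(y) != len(x) or len(y) < 3:
        raise ValueError("need aligned vectors with n >= 3")
    if np.allclose(x, x[0]):
        raise ValueError("predictor has zero variance")
    res = stats.linregress(x, y)
    return SimpleRegressionResult(
        trait=name,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=len(y),
    )


def subset_report(models: list[SubsetModel]) -> pd.DataFrame:
    """Tidy frame of all (non-deficient) subset fits for ranking/export."""
    rows = [
        {
            "label": m.label,
            "n_predictors": len(m.predictors),
            "R2": m.r_squared,
            "lnL": m.lnL,
            "p": m.p,
            "n": m.n,
            "AIC": m.aic,
            "AICc": m.aicc,
        }
        for m in models
        if not m.rank_deficient
    ]
    return pd.DataFrame(rows).sort_values("AICc", kind="stable").reset_index(drop=True)
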