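"""Regression and causal mediation inference on condition tables.

The scaling experiment yields one row per (krec, kext, seed) with the
relative γ-power change Δγ.  Its dependence on the scaling factors is
summarized by OLS (Δγ ~ kext + krec).  Whether an effect of a scaling
factor on γ power acts through pyramidal firing rate is assessed with a
linear mediation model: mediator fit M ~ X, outcome fit Y ~ X + M, average
causally mediated effect ACME = a·b, average direct effect ADE = c′, total
effect TE = ACME + ADE, with percentile-bootstrap confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "RegressionResult",
    "MediationResult",
    "standardize",
    "fit_delta_gamma_regression",
    "mediation_analysis",
]


@dataclass
class RegressionResult:
    params: pd.Series  # coefficient point estimates (incl. intercept)
    conf_int: pd.DataFrame  # 95% bounds, columns [lower, upper]
    pvalues: pd.Series
    r_squared: float
    r_squared_adj: float
    n_obs: int

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.params,
                "ci_low": self.conf_int["lower"],
                "ci_high": self.conf_int["upper"],
                "p": self.pvalues,
            }
        )


@dataclass
class MediationResult:
    acme: float
    ade: float
    total_effect: float
    prop_mediated: float
    ci: dict[str, tuple[float, float]]
    pvalues: dict[str, float]
    n_boot: int


def standardize(table: pd.DataFrame, columns=None) -> pd.DataFrame:
    """z-score each (selected) column; raises on constant columns."""
    out = table.copy()
    cols = columns if columns is not None else table.columns
    for c in cols:
        sd = table[c].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"column {c!r} is constant; cannot standardize")
        out[c] = (table[c] - table[c].mean()) / sd
    return out


def fit_delta_gamma_regression(table: pd.DataFrame,
                               y: str = "delta_gamma",
                               predictors=("kext", "krec")) -> RegressionResult:
    """OLS of Δγ on the scaling factors with classical standard errors."""
    for p in predictors:
        if table[p].nunique() < 2:
            raise ValueError(f"predictor {p!r} has fewer than 2 levels")
    X = sm.add_constant(table[list(predictors)].astype(float))
    fit = sm.OLS(table[y].astype(float), X).fit()
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    ci = fit.conf_int(alpha=0.05)
    ci.columns = ["lower", "upper"]
    return RegressionResult(
        params=fit.params,
        conf_int=ci,
        pvalues=fit.pvalues,
        r_squared=float(fit.rsquared),
        r_squared_adj=float(fit.rsquared_adj),
        n_obs=int(fit.nobs),
    )


def _mediation_point(x: np.ndarray, m: np.ndarray, y: np.ndarray):
    """(ACME, ADE, TE) from the two linear fits."""
    xm = np.column_stack([np.ones_like(x), x])
    a = np.linalg.lstsq(xm, m, rcond=None)[0][1]
    xym = np.column_stack([np.ones_like(x), x, m])
    coef = np.linalg.lstsq(xym, y, rcond=None)[0]
    c_prime, b = coef[1], coef[2]
    acme = a * b
    return acme, c_prime, acme + c_prime


def mediation_analysis(x, m, y, n_boot: int = 1000,
                       rng: np.random.Generator | int | None = None,
                       alpha: float = 0.05) -> MediationResult:
    """Linear-model mediation with nonparametric bootstrap intervals.

    Inputs are (typically standardized) 1-d arrays of equal length.
    Bootstrap p-values are two-sided sign-inversion probabilities
    (2·min(P(θ*<0), P(θ*>0)), floored at 1/n_boot).
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (x.size == m.size == y.size):
        raise ValueError("X, M, Y must have equal length")
    for name, col in (("X", x), ("M", m), ("Y", y)):
        if np.std(col) == 0:
            raise ValueError(f"{name} has zero variance")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    acme, ade, te = _mediation_point(x, m, y)
    prop = acme / te if te != 0 else np.nan

    n = x.size
    draws = np.empty((n_boot, 4))
    for i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        a_i, d_i, t_i = _mediation_point(x[idx], m[idx], y[idx])
        draws[i] = (a_i, d_i, t_i, a_i / t_i if t_i != 0 else np.nan)

    names = ("acme", "ade", "total_effect", "prop_mediated")
    ci = {}
    pvals = {}
    for j, name in enumerate(names):
        col = draws[:, j]
        col = col[np.isfinite(col)]
        lo, hi = np.percentile(col, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        ci[name] = (float(lo), float(hi))
        p = 2.0 * min(np.mean(col < 0), np.mean(col > 0))
        pvals[name] = float(max(p, 1.0 / n_boot))

    return MediationResult(
        acme=float(acme), ade=float(ade), total_effect=float(te),
        prop_mediated=float(prop), ci=ci, pvalues=pvals, n_boot=n_boot,
    )
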