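"""Allometric power-law fits in log10 space.

The allometric model is BMR = a * m**b, fitted as the linear regression
log10(BMR) = log10(a) + b*log10(m). ``AllometricModel`` wraps the design;
``fit`` / ``fit_wls`` return an :class:`AllometricFit` results object with
coefficients, classical standard errors, R^2 and the delta-method standard
error of the back-transformed intercept a = 10**log10_a.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .io import CladeTable

__all__ = [
    "AllometricModel",
    "AllometricFit",
    "fit_ols",
    "fit_wls",
    "refit_intercept_fixed_slope",
    "slope_ttest",
    "delta_se_a",
    "filter_by_mass",
]

LN10 = math.log(10.0)


@dataclass(frozen=True)
class AllometricFit:
    """Results of one log-log allometric regression.

    ``a`` is the metabolic rate predicted at 1 g (mL O2/h); ``b`` is the
    dimensionless scaling exponent. ``se_a_natural`` is the delta-method
    standard error of ``a`` on the natural (antilog) scale.
    """

    log10_a: float
    b: float
    se_log10_a: float
    se_b: float
    r2: float
    n: int
    residual_sd: float
    x_mean: float
    ssx: float
    method: str = "OLS"

    @property
    def a(self) -> float:
        return 10.0 ** self.log10_a

    @property
    def se_a_natural(self) -> float:
        return delta_se_a(self)

    @property
    def df_resid(self) -> int:
        return self.n - 2

    def slope_ttest(self, b0: float) -> tuple[float, float]:
        return slope_ttest(self, b0)

    def predict_log10(self, log10_mass: np.ndarray) -> np.ndarray:
        return self.log10_a + self.b * np.asarray(log10_mass, dtype=float)

    def predict(self, mass_g: np.ndarray) -> np.ndarray:
        return self.a * np.asarray(mass_g, dtype=float) ** self.b

    def summary(self) -> str:
        lines = [
            f"Allometric {self.method} fit: log10(BMR) = log10(a) + b*log10(m)",
            f"  n = {self.n}, R^2 = {self.r2:.4f}, residual SD = {self.residual_sd:.4f}",
            f"  a = {self.a:.4g} mL O2/h at 1 g  (SE natural scale {self.se_a_natural:.4g})",
            f"  log10(a) = {self.log10_a:.4f} +/- {self.se_log10_a:.4f}",
            f"  b = {self.b:.4f} +/- {self.se_b:.4f}",
        ]
        return "\n".join(lines)


class AllometricModel:
    """Simple/weighted linear regression of log10 BMR on log10 mass.

    Parameters are arrays already on the log10 scale; use
    :meth:`from_table` to build from a :class:`~allomet.io.CladeTable`
    in natural units.
    """

    def __init__(self, x: np.ndarray, y: np.ndarray, weights: np.ndarray | None = None):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be 1-d arrays of equal length")
        if len(x) < 2:
            raise ValueError("need at least 2 observations")
        if np.ptp(x) == 0:
            raise ValueError("degenerate design: all x values equal")
        if weights is not None:
            weights = np.asarray(weights, dtype=float)
            if weights.shape != x.shape:
                raise ValueError("weights must match x in length")
            if np.any(weights <= 0):
                raise ValueError("weights must be strictly positive")
        self.x = x
        self.y = y
        self.weights = weights

    @classmethod
    def from_table(cls, table: CladeTable, clade: str | None = None,
                   response: str = "bmr") -> "AllometricModel":
        df = table.by_clade(clade) if clade is not None else table.data
        x = np.log10(df["mass_g"].to_numpy(dtype=float))
        y = np.log10(df[response].to_numpy(dtype=float))
        return cls(x, y)

    def fit(self) -> AllometricFit:
        x, y, w = self.x, self.y, self.weights
        X = sm.add_constant(x)
        if w is None:
            res = sm.OLS(y, X).fit()
            method = "OLS"
            xbar = float(np.mean(x))
            ssx = float(np.sum((x - xbar) ** 2))
        else:
            res = sm.WLS(y, X, weights=w).fit()
            method = "WLS"
            xbar = float(np.average(x, weights=w))
            ssx = float(np.sum(w * (x - xbar) ** 2))
        n = len(x)
        df_resid = n - 2
        rss = float(res.ssr)
        resid_sd = math.sqrt(rss / df_resid) if df_resid > 0 else float("nan")
        se = res.bse if df_resid > 0 else np.full(2, np.nan)
        return AllometricFit(
            log10_a=float(res.params[0]),
            b=float(res.params[1]),
            se_log10_a=float(se[0]),
            se_b=float(se[1]),
            r2=float(res.rsquared),
            n=n,
            residual_sd=resid_sd,
            x_mean=xbar,
            ssx=ssx,
            method=method,
        )

    def fit_fixed_slope(self, b_fixed: float) -> AllometricFit:
        """Least-squares intercept with the slope held at ``b_fixed``.

        The intercept solving the fixed-slope normal equation is
        log10_a = mean(y) - b_fixed*mean(x); R^2 is computed against the
        fixed-slope line and can be lower than the free fit's.
        """
        x, y, w = self.x, self.y, self.weights
        if w is None:
            w = np.ones_like(x)
        xbar = float(np.average(x, weights=w))
        ybar = float(np.average(y, weights=w))
        log10_a = ybar - b_fixed * xbar
        resid = y - (log10_a + b_fixed * x)
        rss = float(np.sum(w * resid**2))
        tss = float(np.sum(w * (y - ybar) ** 2))
        r2 = 1.0 - rss / tss if tss > 0 else float("nan")
        n = len(x)
        df_resid = n - 1  # only the intercept is estimated
        resid_sd = math.sqrt(rss / df_resid) if df_resid > 0 else float("nan")
        se_int = resid_sd / math.sqrt(float(np.sum(w))) if df_resid > 0 else float("nan")
        ssx = float(np.sum(w * (x - xbar) ** 2))
        return AllometricFit(
            log10_a=log10_a,
            b=b_fixed,
            se_log10_a=se_int,
            se_b=0.0,
            r2=r2,
            n=n,
            residual_sd=resid_sd,
            x_mean=xbar,
            ssx=ssx,
            method="fixed-slope",
        )


def fit_ols(x: np.ndarray, y: np.ndarray) -> AllometricFit:
    """OLS fit of log10 BMR (y) on log10 mass (x)."""
    return AllometricModel(x, y).fit()


def fit_wls(x: np.ndarray, y: np.ndarray, weights: np.ndarray) -> AllometricFit:
    """Weighted least-squares fit; equals :func:`fit_ols` when weights are equal."""
    if weights is None:
        raise ValueError("weights required; use fit_ols for the unweighted fit")
    return AllometricModel(x, y, weights=weights).fit()


def refit_intercept_fixed_slope(
    x: np.ndarray, y: np.ndarray, b_fixed: float
) -> tuple[float, float, float]:
    """Intercept refit at a fixed (common) slope.

    Returns ``(log10_a, a, r2)``. Accepts a single point (the slope is
    not estimated, so one observation suffices).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0:
        raise ValueError("empty input")
    if len(x) == 1:
        log10_a = float(y[0] - b_fixed * x[0])
        return log10_a, 10.0**log10_a, float("nan")
    fit = AllometricModel(x, y) if np.ptp(x) > 0 else None
    if fit is None:
        xbar, ybar = float(np.mean(x)), float(np.mean(y))
        log10_a = ybar - b_fixed * xbar
        return log10_a, 10.0**log10_a, float("nan")
    res = fit.fit_fixed_slope(b_fixed)
    return res.log10_a, res.a, res.r2


def slope_ttest(fit: AllometricFit, b0: float) -> tuple[float, float]:
    """Two-sided Student t-test of the slope against a theoretical value.

    Classical test against e.g. 3/4 (Kleiber) or 2/3 (Rubner), with
    n - 2 degrees of freedom.
    """
    if fit.n < 3:
        raise ValueError("slope t-test needs n >= 3")
    t = (fit.b - b0) / fit.se_b
    p = 2.0 * stats.t.sf(abs(t), df=fit.df_resid)
    return float(t), float(p)


def delta_se_a(fit: AllometricFit) -> float:
    """Delta-method SE of a = 10**log10_a: a * ln(10) * SE(log10_a)."""
    return fit.a * LN10 * fit.se_log10_a


def filter_by_mass(table: CladeTable, max_mass_g: float) -> CladeTable:
    """Keep species with body mass <= ``max_mass_g`` (inclusive), preserving order."""
    if max_mass_g <= 0:
        raise ValueError("max_mass_g must be positive")
    keep = table.data["mass_g"] <= max_mass_g
    return CladeTable(table.data[keep].reset_index(drop=True), table.clade_order)
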