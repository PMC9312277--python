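"""Nested ANCOVA models for clade-structured allometry.

Three models of log10(BMR) on log10(mass) across clades:

1. one line (common slope, common intercept);
2. common slope, separate intercept per clade;
3. separate slope and intercept per clade.

Model 2 is the classical size-correction device: its per-clade intercepts
are the size-independent BMR levels. The slope-homogeneity F test compares
models 2 and 3; AIC/BIC use the Gaussian likelihood at the ML variance
(RSS/n) with the parameter count including sigma^2, matching the
convention of R's AIC for ``lm`` objects so model comparisons carry over.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .io import CladeTable

__all__ = [
    "ModelStats",
    "ModelComparison",
    "CladeAncova",
    "fit_three_models",
    "slope_homogeneity_test",
    "two_group_ancova",
    "CommonSlopeFit",
    "TwoGroupAncova",
]


@dataclass(frozen=True)
class ModelStats:
    name: str
    k_params: int  # regression coefficients + 1 for sigma^2
    rss: float
    r2: float
    adj_r2: float
    aic: float
    bic: float
    residual_sd: float  # sqrt(RSS / (n - p)), the regression table convention
    df_resid: int


@dataclass(frozen=True)
class ModelComparison:
    """Results object for the three-model comparison."""

    n: int
    models: tuple[ModelStats, ModelStats, ModelStats]
    b_common_indicator: float
    se_b_common: float
    intercepts_model2: dict[str, float]  # per-clade log10 a at the common slope
    slopes_model3: dict[str, float]
    intercepts_model3: dict[str, float]
    f_slope_homogeneity: float
    df1: int
    df2: int
    p_slope_homogeneity: float

    def __post_init__(self) -> None:
        m1, m2, m3 = self.models
        assert m1.rss >= m2.rss - 1e-9 and m2.rss >= m3.rss - 1e-9, "RSS must nest"

    @property
    def best_by_bic(self) -> str:
        return min(self.models, key=lambda m: m.bic).name

    @property
    def best_by_aic(self) -> str:
        return min(self.models, key=lambda m: m.aic).name

    def summary(self) -> str:
        lines = [f"ANCOVA model comparison (n = {self.n})"]
        for m in self.models:
            lines.append(
                f"  {m.name}: k={m.k_params}  R^2={m.r2:.4f}  adjR^2={m.adj_r2:.4f}"
                f"  resid SD={m.residual_sd:.4f}  AIC={m.aic:.2f}  BIC={m.bic:.2f}"
            )
        lines.append(
            f"  common slope (model 2): b = {self.b_common_indicator:.4f}"
            f" +/- {self.se_b_common:.4f}"
        )
        lines.append(
            "  slope homogeneity: F({},{}) = {:.3f}, p = {:.4g}".format(
                self.df1, self.df2, self.f_slope_homogeneity, self.p_slope_homogeneity
            )
        )
        lines.append(f"  lowest BIC: {self.best_by_bic}; lowest AIC: {self.best_by_aic}")
        return "\n".join(lines)


def _gaussian_ic(rss: float, n: int, p: int) -> tuple[float, float, float]:
    """(lnL at ML variance, AIC, BIC) with k = p + 1 counting sigma^2."""
    sigma2 = rss / n
    llf = -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0)
    k = p + 1
    return llf, 2 * k - 2 * llf, k * math.log(n) - 2 * llf


class CladeAncova:
    """Model object for the three nested ANCOVA fits on a CladeTable."""

    def __init__(self, table: CladeTable):
        df = table.data
        clades = [c for c in table.clade_order if c in set(df["clade"])]
        if len(clades) < 2:
            raise ValueError("need at least 2 clades")
        counts = df["clade"].value_counts()
        small = [c for c in clades if counts[c] < 2]
        if small:
            raise ValueError(f"clade(s) with n < 2 cannot support per-clade fits: {small}")
        x = np.log10(df["mass_g"].to_numpy(dtype=float))
        if len(np.unique(x)) < 3:
            raise ValueError("need at least 3 distinct masses overall")
        self.x = x
        self.y = np.log10(df["bmr"].to_numpy(dtype=float))
        self.clades = clades
        self.codes = df["clade"].to_numpy()
        self.n = len(df)

    def _designs(self):
        n, G = self.n, len(self.clades)
        ones = np.ones(n)
        X1 = np.column_stack([ones, self.x])
        # model 2/3: baseline = first clade in clade_order; indicator columns
        D = np.column_stack(
            [(self.codes == c).astype(float) for c in self.clades[1:]]
        ) if G > 1 else np.empty((n, 0))
        X2 = np.column_stack([ones, D, self.x])
        X3 = np.column_stack([ones, D, self.x, D * self.x[:, None]])
        return X1, X2, X3

    def fit(self) -> ModelComparison:
        X1, X2, X3 = self._designs()
        names = ("single line", "common slope", "separate slopes")
        res = [sm.OLS(self.y, X).fit() for X in (X1, X2, X3)]
        stats_out = []
        for name, r, X in zip(names, res, (X1, X2, X3)):
            p = X.shape[1]
            rss = float(r.ssr)
            llf, aic, bic = _gaussian_ic(rss, self.n, p)
            dfres = self.n - p
            stats_out.append(
                ModelStats(
                    name=name,
                    k_params=p + 1,
                    rss=rss,
                    r2=float(r.rsquared),
                    adj_r2=float(r.rsquared_adj),
                    aic=aic,
                    bic=bic,
                    residual_sd=math.sqrt(rss / dfres) if dfres > 0 else float("nan"),
                    df_resid=dfres,
                )
            )
        m1, m2, m3 = stats_out
        G = len(self.clades)
        r2m = res[1]
        b_common = float(r2m.params[G])  # columns: const, G-1 indicators, slope
        se_b = float(r2m.bse[G])
        base_int = float(r2m.params[0])
        intercepts2 = {self.clades[0]: base_int}
        for i, c in enumerate(self.clades[1:]):
            intercepts2[c] = base_int + float(r2m.params[1 + i])
        r3m = res[2]
        base_int3 = float(r3m.params[0])
        base_b3 = float(r3m.params[G])
        intercepts3 = {self.clades[0]: base_int3}
        slopes3 = {self.clades[0]: base_b3}
        for i, c in enumerate(self.clades[1:]):
            intercepts3[c] = base_int3 + float(r3m.params[1 + i])
            slopes3[c] = base_b3 + float(r3m.params[G + 1 + i])
        df1 = m2.df_resid - m3.df_resid
        df2 = m3.df_resid
        if df2 <= 0:
            raise ValueError("no residual degrees of freedom under model 3")
        F = ((m2.rss - m3.rss) / df1) / (m3.rss / df2)
        F = max(F, 0.0)
        p_F = float(stats.f.sf(F, df1, df2))
        return ModelComparison(
            n=self.n,
            models=(m1, m2, m3),
            b_common_indicator=b_common,
            se_b_common=se_b,
            intercepts_model2=intercepts2,
            slopes_model3=slopes3,
            intercepts_model3=intercepts3,
            f_slope_homogeneity=float(F),
            df1=df1,
            df2=df2,
            p_slope_homogeneity=p_F,
        )


def fit_three_models(table: CladeTable) -> ModelComparison:
    """Fit the three nested ANCOVA models and their comparison statistics."""
    return CladeAncova(table).fit()


def slope_homogeneity_test(table: CladeTable) -> tuple[float, int, int, float]:
    """F test of H0: all clades share one slope (model 2 vs model 3)."""
    cmp_ = fit_three_models(table)
    return (
        cmp_.f_slope_homogeneity,
        cmp_.df1,
        cmp_.df2,
        cmp_.p_slope_homogeneity,
    )


@dataclass(frozen=True)
class CommonSlopeFit:
    b: float
    se_b: float
    intercepts_log10: dict[str, float]

    def intercept_a(self, label: str) -> float:
        return 10.0 ** self.intercepts_log10[label]


class TwoGroupAncova(NamedTuple):
    t_slope: float
    t_intercept: float
    df: int
    p_slope: float
    p_intercept: float
    common_slope_fit: CommonSlopeFit


def two_group_ancova(tableA: CladeTable, tableB: CladeTable) -> TwoGroupAncova:
    """Slope- and intercept-difference tests for two groups.

    The slope-difference t comes from the interaction model (separate
    slopes); the intercept-difference t from the common-slope model.
    Degrees of freedom are n - k of the respective model.
    """
    for t in (tableA, tableB):
        if len(t) < 3:
            raise ValueError("each group needs n >= 3")
    dfA, dfB = tableA.data.copy(), tableB.data.copy()
    dfA["__g"], dfB["__g"] = "A", "B"
    df = pd.concat([dfA, dfB], ignore_index=True)
    x = np.log10(df["mass_g"].to_numpy(dtype=float))
    y = np.log10(df["bmr"].to_numpy(dtype=float))
    g = (df["__g"] == "B").to_numpy(dtype=float)
    n = len(df)
    X_int = np.column_stack([np.ones(n), g, x, g * x])
    r_int = sm.OLS(y, X_int).fit()
    t_slope = float(r_int.tvalues[3])
    df_int = n - 4
    p_slope = 2.0 * float(stats.t.sf(abs(t_slope), df_int))
    X_com = np.column_stack([np.ones(n), g, x])
    r_com = sm.OLS(y, X_com).fit()
    t_int = float(r_com.tvalues[1])
    df_com = n - 3
    p_int = 2.0 * float(stats.t.sf(abs(t_int), df_com))
    fit = CommonSlopeFit(
        b=float(r_com.params[2]),
        se_b=float(r_com.bse[2]),
        intercepts_log10={
            "A": float(r_com.params[0]),
            "B": float(r_com.params[0] + r_com.params[1]),
        },
    )
    return TwoGroupAncova(t_slope, t_int, df_int, p_slope, p_int, fit)
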