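"""Cross-clade trend regressions.

Each clade contributes one observation: metabolic level (a_common, BMR
ratio, or L) against divergence time, the scaling exponent b against the
level metrics, and mass-corrected FMR against mass-corrected BMR. The
fits share the allometry module's least-squares path, so a trend fit is
exactly an ordinary (or n-weighted) regression on the group pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .allometry import AllometricModel, slope_ttest
from .scaling_metrics import GroupScalingSummary

__all__ = ["TrendFit", "trend_fit", "trend_vs_time", "slope_vs_level", "fmr_vs_bmr"]


@dataclass(frozen=True)
class TrendFit:
    slope: float
    intercept: float
    r2: float
    p_slope: float
    n_groups: int
    method: str
    x_name: str
    y_name: str

    def summary(self) -> str:
        return (
            f"{self.y_name} ~ {self.x_name} ({self.method}, {self.n_groups} groups): "
            f"slope = {self.slope:.4g}, intercept = {self.intercept:.4g}, "
            f"R^2 = {self.r2:.4f}, p(slope) = {self.p_slope:.4g}"
        )


def trend_fit(
    x: Sequence[float],
    y: Sequence[float],
    x_name: str = "x",
    y_name: str = "y",
    weights: Sequence[float] | None = None,
) -> TrendFit:
    """One-observation-per-group regression of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 groups")
    fit = AllometricModel(x, y, weights=None if weights is None else np.asarray(weights, float)).fit()
    _, p = slope_ttest(fit, 0.0)
    return TrendFit(
        slope=fit.b,
        intercept=fit.log10_a,
        r2=fit.r2,
        p_slope=p,
        n_groups=len(x),
        method=fit.method,
        x_name=x_name,
        y_name=y_name,
    )


def trend_vs_time(
    summaries: Sequence[GroupScalingSummary],
    y_field: str = "bmr_ratio",
    method: str = "OLS",
) -> TrendFit:
    """Regression of a level metric (or slope) on clade divergence time.

    ``y_field`` is any numeric GroupScalingSummary field: "a_common",
    "bmr_ratio", "L", "b", "fmr_a_common". ``method="WLS"`` weights each
    clade by its sample size.
    """
    pairs = [
        (s.divergence_time_mya, getattr(s, y_field), s.n)
        for s in summaries
        if getattr(s, y_field) is not None and np.isfinite(getattr(s, y_field))
    ]
    if len(pairs) < 3:
        raise ValueError("need at least 3 groups with finite y and T")
    T, y, n = map(np.asarray, zip(*pairs))
    w = n.astype(float) if method == "WLS" else None
    return trend_fit(T, y, "divergence_time_mya", y_field, weights=w)


def slope_vs_level(
    b_values: Sequence[float],
    level_values: Sequence[float],
    level_name: str = "a_common",
) -> TrendFit:
    """Regression of scaling exponents on a metabolic-level metric.

    The caller chooses which clades enter (the canonical analysis drops
    Monotremata, whose slope rests on three species).
    """
    return trend_fit(level_values, b_values, level_name, "b")


def fmr_vs_bmr(summaries: Sequence[GroupScalingSummary]) -> TrendFit:
    """Mass-corrected FMR level against mass-corrected BMR level."""
    pairs = [
        (s.a_common, s.fmr_a_common)
        for s in summaries
        if s.fmr_a_common is not None and np.isfinite(s.fmr_a_common)
    ]
    if len(pairs) < 3:
        raise ValueError("need at least 3 groups with both intercepts")
    a_bmr, a_fmr = map(np.asarray, zip(*pairs))
    return trend_fit(a_bmr, a_fmr, "a_common", "fmr_a_common")
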