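"""Size-independent BMR-level criteria and BMR/FMR efficiency.

Three ways to compare metabolic level across clades of very different body
sizes, all built on a common scaling exponent:

* ``a_common`` — the allometric coefficient re-fitted with the slope held
  at the common value (mL O2/h at 1 g);
* the dimensionless BMR ratio — each clade's ``a_common`` divided by the
  reference clade's (Passeriformes, the highest);
* the scaling elevation L = log10(BMR/m) evaluated at the pivotal
  midpoint of the clade's log-log relationship.

BMR/FMR efficiency alpha = a_bmr_common / a_fmr_common is the share of
field energy expenditure devoted to self-maintenance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .allometry import AllometricFit, refit_intercept_fixed_slope
from .io import CladeConfig, CladeTable
from . import reference_data as ref

__all__ = [
    "GroupScalingSummary",
    "weighted_common_slope",
    "weighted_mean_slope",
    "group_summaries",
    "elevation_L",
    "bmr_fmr_ratio",
]


@dataclass(frozen=True)
class GroupScalingSummary:
    """Per-clade size-independent BMR level metrics."""

    clade: str
    n: int
    a_common: float  # mL O2/h at 1 g, slope held at b_common
    log10_a_common: float
    bmr_ratio: float  # a_common / a_common(reference)
    L: float  # log10(BMR/m) at the pivotal midpoint
    divergence_time_mya: float
    r2_at_common: float = float("nan")
    b: float | None = None  # the clade's free-fit slope, when attached
    fmr_a_common: float | None = None
    alpha: float | None = None  # BMR/FMR


def weighted_mean_slope(slopes: Sequence[float], weights: Sequence[float]) -> float:
    """Weighted average slope: sum(w*b) / sum(w)."""
    slopes = np.asarray(slopes, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if slopes.size == 0:
        raise ValueError("empty input")
    if np.any(weights <= 0):
        raise ValueError("weights must be positive")
    return float(np.sum(weights * slopes) / np.sum(weights))


def weighted_common_slope(
    per_group_fits: Sequence[AllometricFit], weighting: str = "n"
) -> float:
    """Common slope as the weighted average of per-group slopes.

    ``weighting="n"`` uses group sample sizes; ``"ssx"`` uses each group's
    sum of squared deviations of log10 mass, proportional to the inverse
    variance of the slope estimate under a shared residual variance.
    """
    if weighting not in ("n", "ssx"):
        raise ValueError("weighting must be 'n' or 'ssx'")
    slopes = [f.b for f in per_group_fits]
    weights = [f.n if weighting == "n" else f.ssx for f in per_group_fits]
    return weighted_mean_slope(slopes, weights)


def elevation_L(log10_a: float, b: float, x_mid: float) -> float:
    """Scaling elevation: log10(predicted BMR / mass) at log10 mass ``x_mid``.

    log10(y/m) = log10_a + (b - 1) * x_mid for the line y-hat = a * m**b.
    """
    return float(log10_a + (b - 1.0) * x_mid)


def bmr_fmr_ratio(a_bmr_common: float, a_fmr_common: float) -> float:
    """alpha = BMR/FMR: both intercepts must sit at their respective
    common slopes for the ratio to be size-independent."""
    if a_bmr_common <= 0 or a_fmr_common <= 0:
        raise ValueError("intercepts must be positive")
    return float(a_bmr_common / a_fmr_common)


def group_summaries(
    table: CladeTable,
    b_common: float,
    clade_config: CladeConfig,
    fmr_a_common: Mapping[str, float] | None = None,
    fmr_b_common: float = ref.FMR_COMMON_SLOPE,
    x_mid_mode: str = "mean",
    free_slopes: Mapping[str, float] | None = None,
) -> list[GroupScalingSummary]:
    """All three level metrics per clade at a given common slope.

    ``x_mid_mode``: "mean" uses the clade's mean log10 mass as the pivotal
    midpoint of L; "range" uses the midpoint of the clade's log10 mass
    span. FMR intercepts (already at ``fmr_b_common``) may be supplied as
    a mapping, or are re-fitted from the table's ``fmr`` column when
    present.
    """
    if x_mid_mode not in ("mean", "range"):
        raise ValueError("x_mid_mode must be 'mean' or 'range'")
    labels = [c for c in table.clade_order if c in set(table.data["clade"])]
    refclade = clade_config.reference
    if refclade not in labels:
        raise ValueError(f"reference clade {refclade!r} absent from table")
    per: dict[str, dict] = {}
    for label in labels:
        sub = table.by_clade(label)
        x = np.log10(sub["mass_g"].to_numpy(dtype=float))
        y = np.log10(sub["bmr"].to_numpy(dtype=float))
        log10_a, a, r2 = refit_intercept_fixed_slope(x, y, b_common)
        x_mid = float(np.mean(x)) if x_mid_mode == "mean" else float(
            0.5 * (np.min(x) + np.max(x))
        )
        fmr_a = None
        if fmr_a_common is not None and label in fmr_a_common:
            fmr_a = float(fmr_a_common[label])
        elif "fmr" in sub.columns and sub["fmr"].notna().all():
            yf = np.log10(sub["fmr"].to_numpy(dtype=float))
            _, fmr_a, _ = refit_intercept_fixed_slope(x, yf, fmr_b_common)
        per[label] = dict(
            n=len(sub), log10_a=log10_a, a=a, r2=r2, x_mid=x_mid, fmr_a=fmr_a
        )
    a_ref = per[refclade]["a"]
    out = []
    for label in labels:
        d = per[label]
        alpha = bmr_fmr_ratio(d["a"], d["fmr_a"]) if d["fmr_a"] else None
        out.append(
            GroupScalingSummary(
                clade=label,
                n=d["n"],
                a_common=d["a"],
                log10_a_common=d["log10_a"],
                bmr_ratio=d["a"] / a_ref,
                L=elevation_L(d["log10_a"], b_common, d["x_mid"]),
                divergence_time_mya=clade_config.divergence_time(label),
                r2_at_common=d["r2"],
                b=None if free_slopes is None else float(free_slopes[label]),
                fmr_a_common=d["fmr_a"],
                alpha=alpha,
            )
        )
    return out
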