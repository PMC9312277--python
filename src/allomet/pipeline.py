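"""End-to-end analysis pipeline.

From one configuration: per-clade OLS (and, with trees, PGLS + Pagel's
lambda) allometric fits, the three-model ANCOVA comparison, size-
independent level metrics at a common slope, BMR/FMR efficiency, and the
cross-clade trend regressions. Reports are TSV at full precision with a
companion rounded view; every setting used is recorded in the run log.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import reference_data as ref
from .allometry import AllometricModel, filter_by_mass
from .io import (
    CladeConfig,
    CladeTable,
    match_tree_to_table,
    read_clade_config,
    read_species_table,
    read_tree,
)
from .model_selection import fit_three_models
from .pgls import PGLSModel, tree_covariance
from .scaling_metrics import group_summaries, weighted_common_slope
from .trends import fmr_vs_bmr, slope_vs_level, trend_vs_time

__all__ = ["RunConfig", "run_pipeline", "load_run_config"]

MIN_N_FOR_SLOPE_TRENDS = 5  # slopes from fewer species are not meaningful


@dataclass
class RunConfig:
    table_path: str
    clade_config_path: str
    out_dir: str
    tree_paths: dict[str, str] = field(default_factory=dict)  # clade -> newick
    fmr_table_path: str | None = None  # TSV: clade, fmr_a (at the FMR common slope)
    common_slope: str | float = "indicator"  # "indicator" | "wn" | "wssx" | number
    max_mass_g: float | None = None
    x_mid_mode: str = "mean"
    seed: int = 0

    def __post_init__(self) -> None:
        for p in [self.table_path, self.clade_config_path, *self.tree_paths.values()]:
            if not os.path.exists(p):
                raise FileNotFoundError(p)
        if self.fmr_table_path and not os.path.exists(self.fmr_table_path):
            raise FileNotFoundError(self.fmr_table_path)


def load_run_config(path: str) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    base = os.path.dirname(os.path.abspath(path))

    def _abs(p):
        return p if os.path.isabs(p) else os.path.join(base, p)

    return RunConfig(
        table_path=_abs(raw["table"]),
        clade_config_path=_abs(raw["clades"]),
        out_dir=_abs(raw.get("out_dir", "results")),
        tree_paths={k: _abs(v) for k, v in (raw.get("trees") or {}).items()},
        fmr_table_path=_abs(raw["fmr_intercepts"]) if raw.get("fmr_intercepts") else None,
        common_slope=raw.get("common_slope", "indicator"),
        max_mass_g=raw.get("max_mass_g"),
        x_mid_mode=raw.get("x_mid_mode", "mean"),
        seed=int(raw.get("seed", 0)),
    )


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


@_stage("per-clade fits")
def _clade_fits(table: CladeTable, config: CladeConfig,
                tree_paths: dict[str, str]) -> tuple[pd.DataFrame, dict]:
    rows = []
    fits = {}
    for clade in table.clade_order:
        sub = table.by_clade(clade)
        if len(sub) < 2:
            continue
        fit = AllometricModel.from_table(table, clade=clade).fit()
        fits[clade] = fit
        row = {
            "clade": clade,
            "n": fit.n,
            "mass_min_g": float(sub["mass_g"].min()),
            "mass_max_g": float(sub["mass_g"].max()),
            "ols_a": fit.a,
            "ols_se_a": fit.se_a_natural,
            "ols_b": fit.b,
            "ols_se_b": fit.se_b,
            "ols_r2": fit.r2,
        }
        if clade in tree_paths:
            tree = read_tree(tree_paths[clade])
            matched = match_tree_to_table(tree, CladeTable(sub.reset_index(drop=True),
                                                           (clade,)))
            cov = tree_covariance(matched.tree)
            dfm = matched.table.data.set_index("species").loc[list(cov.labels)]
            x = np.log10(dfm["mass_g"].to_numpy(float))
            y = np.log10(dfm["bmr"].to_numpy(float))
            model = PGLSModel(x, y, cov)
            # lambda cannot be profiled on fewer than 4 tips; report the
            # no-signal boundary instead (matches how tiny clades print 0.000)
            pfit = model.fit(lam=0.0) if len(y) < 4 else model.fit()
            row.update(
                lambda_hat=pfit.lambda_hat,
                pgls_a=pfit.a,
                pgls_se_a=pfit.se_a_natural,
                pgls_b=pfit.b,
                pgls_se_b=pfit.se_b,
                pgls_r2=pfit.r2,
            )
            fits[clade + ":pgls"] = pfit
        rows.append(row)
    return pd.DataFrame(rows), fits


def run_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run every stage; writes the report bundle to ``config.out_dir``."""
    os.makedirs(config.out_dir, exist_ok=True)
    log: list[str] = [f"seed = {config.seed}"]

    clade_config = read_clade_config(config.clade_config_path)
    table = read_species_table(config.table_path, clade_config)
    if config.max_mass_g is not None:
        before = len(table)
        table = filter_by_mass(table, config.max_mass_g)
        log.append(
            f"mass threshold {config.max_mass_g} g (inclusive): "
            f"{before} -> {len(table)} species"
        )

    fits_df, fits = _clade_fits(table, clade_config, config.tree_paths)

    try:
        comparison = fit_three_models(table)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'model comparison' failed: {exc}") from exc
    m_rows = [
        {
            "model": m.name,
            "k_params": m.k_params,
            "rss": m.rss,
            "r2": m.r2,
            "adj_r2": m.adj_r2,
            "residual_sd": m.residual_sd,
            "aic": m.aic,
            "bic": m.bic,
        }
        for m in comparison.models
    ]
    models_df = pd.DataFrame(m_rows)
    log.append(
        f"slope homogeneity: F({comparison.df1},{comparison.df2}) = "
        f"{comparison.f_slope_homogeneity:.4f}, p = {comparison.p_slope_homogeneity:.4g}"
    )
    log.append(f"model with lowest BIC: {comparison.best_by_bic}")

    ols_fits = [fits[c] for c in table.clade_order if c in fits]
    if isinstance(config.common_slope, (int, float)):
        b_common = float(config.common_slope)
        mode = "fixed"
    elif config.common_slope == "indicator":
        b_common = comparison.b_common_indicator
        mode = "indicator"
    elif config.common_slope in ("wn", "wssx"):
        b_common = weighted_common_slope(
            ols_fits, "n" if config.common_slope == "wn" else "ssx"
        )
        mode = config.common_slope
    else:
        raise ValueError(f"unknown common_slope mode {config.common_slope!r}")
    log.append(f"common slope mode = {mode}; b_common = {b_common:.6f}")
    log.append(f"x_mid convention for L = {config.x_mid_mode}")

    fmr_map = None
    if config.fmr_table_path:
        fdf = pd.read_csv(config.fmr_table_path, sep="\t")
        fmr_map = dict(zip(fdf["clade"].astype(str), fdf["fmr_a"].astype(float)))
        log.append(f"FMR intercepts supplied for {sorted(fmr_map)}")

    free_slopes = {c: fits[c].b for c in table.clade_order if c in fits}
    summaries = group_summaries(
        table,
        b_common,
        clade_config,
        fmr_a_common=fmr_map,
        x_mid_mode=config.x_mid_mode,
        free_slopes=free_slopes,
    )
    summary_df = pd.DataFrame(
        {
            "clade": s.clade,
            "n": s.n,
            "a_common": s.a_common,
            "log10_a_common": s.log10_a_common,
            "bmr_ratio": s.bmr_ratio,
            "L": s.L,
            "divergence_time_mya": s.divergence_time_mya,
            "r2_at_common": s.r2_at_common,
            "b_free": s.b,
        }
        for s in summaries
    )

    fmr_df = pd.DataFrame(
        {
            "clade": s.clade,
            "bmr_a_common": s.a_common,
            "fmr_a_common": s.fmr_a_common,
            "alpha": s.alpha,
        }
        for s in summaries
        if s.fmr_a_common is not None
    )

    trend_rows = []
    for y_field in ("a_common", "bmr_ratio", "L", "b"):
        try:
            tf = trend_vs_time(summaries, y_field)
        except ValueError:
            continue
        trend_rows.append(tf)
    big = [s for s in summaries if s.n >= MIN_N_FOR_SLOPE_TRENDS and s.b is not None]
    if len(big) >= 3:
        for level in ("a_common", "bmr_ratio", "L"):
            tf = slope_vs_level(
                [s.b for s in big], [getattr(s, level) for s in big], level
            )
            trend_rows.append(tf)
        log.append(
            "slope-vs-level trends exclude clades with n < "
            f"{MIN_N_FOR_SLOPE_TRENDS}: "
            f"{sorted(s.clade for s in summaries if s.n < MIN_N_FOR_SLOPE_TRENDS)}"
        )
    if len(fmr_df) >= 3:
        trend_rows.append(fmr_vs_bmr(summaries))
    trends_df = pd.DataFrame(
        {
            "y": t.y_name,
            "x": t.x_name,
            "method": t.method,
            "slope": t.slope,
            "intercept": t.intercept,
            "r2": t.r2,
            "p_slope": t.p_slope,
            "n_groups": t.n_groups,
        }
        for t in trend_rows
    )

    reports = {
        "fits": fits_df,
        "models": models_df,
        "summary": summary_df,
        "fmr": fmr_df,
        "trends": trends_df,
    }
    for name, df in reports.items():
        df.to_csv(os.path.join(config.out_dir, f"{name}.tsv"), sep="\t", index=False)
        rounded = df.copy()
        for col in rounded.columns:
            if rounded[col].dtype.kind == "f":
                digits = 2 if col == "alpha" else 3
                rounded[col] = rounded[col].round(digits)
        rounded.to_csv(
            os.path.join(config.out_dir, f"{name}_rounded.tsv"), sep="\t", index=False
        )
    with open(os.path.join(config.out_dir, "run_log.txt"), "w") as fh:
        fh.write("\n".join(log) + "\n")
    return reports
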