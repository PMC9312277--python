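"""Published group-level summaries for the six endotherm clades.

These are the study conditions the package emulates and the worked-example
inputs: per-clade sample sizes, body-mass ranges, free-fit OLS/PGLS scaling
exponents, Pagel's lambda estimates, intercepts re-fitted at the common
slope b = 0.7248 (BMR, mL O2/h at 1 g) and at b = 0.6851 (FMR), and clade
divergence times in Mya. The Passeriformes free-fit intercept and mass
range were not published at clade level; the values used here are derived
from the common-slope intercept and a typical passerine size span (see
docs/methods.md).
"""

from __future__ import annotations

import math

from .io import CladeConfig, CladeInfo

CLADES = (
    "Monotremata",
    "Marsupialia",
    "Eutheria",
    "Paleognathae",
    "Non-Passeriformes",
    "Passeriformes",
)

#: Divergence from the main vertebrate stem, million years ago.
DIVERGENCE_MYA = {
    "Monotremata": 271.0,
    "Marsupialia": 193.0,
    "Eutheria": 115.0,
    "Paleognathae": 110.0,
    "Non-Passeriformes": 90.0,
    "Passeriformes": 50.0,
}

N_SPECIES = {
    "Monotremata": 3,
    "Marsupialia": 84,
    "Eutheria": 730,
    "Paleognathae": 9,
    "Non-Passeriformes": 404,
    "Passeriformes": 587,
}

#: Body-mass span (g). The Passeriformes span is a package choice.
MASS_RANGE_G = {
    "Monotremata": (1284.0, 10300.0),
    "Marsupialia": (5.4, 32490.0),
    "Eutheria": (2.2, 4037500.0),
    "Paleognathae": (220.8, 92400.0),
    "Non-Passeriformes": (3.2, 23370.0),
    "Passeriformes": (5.0, 1400.0),
}

#: Free-fit scaling exponents per clade.
OLS_B = {
    "Monotremata": 0.565,
    "Marsupialia": 0.753,
    "Eutheria": 0.736,
    "Paleognathae": 0.727,
    "Non-Passeriformes": 0.691,
    "Passeriformes": 0.668,
}

PGLS_B = {
    "Monotremata": 0.565,
    "Marsupialia": 0.746,
    "Eutheria": 0.733,
    "Paleognathae": 0.727,
    "Non-Passeriformes": 0.708,
    "Passeriformes": 0.642,
}

#: Free-fit OLS allometric coefficients a (mL O2/h at 1 g); the
#: Passeriformes value is back-derived from A_COMMON at the clade's own
#: slope around the middle of its log-mass span.
OLS_A = {
    "Monotremata": 5.861,
    "Marsupialia": 2.300,
    "Eutheria": 3.326,
    "Paleognathae": 3.221,
    "Non-Passeriformes": 5.507,
    "Passeriformes": None,  # filled below
}

#: Pagel's lambda of mass-independent BMR per clade; the Passeriformes
#: value reuses the all-Aves estimate (not published at clade level).
LAMBDA = {
    "Monotremata": 0.0,
    "Marsupialia": 0.214,
    "Eutheria": 0.813,
    "Paleognathae": 0.0,
    "Non-Passeriformes": 0.630,
    "Passeriformes": 0.664,
}

#: The preferred common slope: single-slope / separate-intercept ANCOVA
#: estimate on the full dataset.
COMMON_SLOPE_INDICATOR = 0.7248
#: Weighted-average common slopes (weights = clade sample sizes).
COMMON_SLOPE_OLS_WEIGHTED = 0.704
COMMON_SLOPE_PGLS_WEIGHTED = 0.698
#: Common slope used for the FMR intercepts.
FMR_COMMON_SLOPE = 0.6851

#: Intercepts re-fitted at the common slope b = 0.7248 (BMR, mL O2/h).
A_COMMON = {
    "Monotremata": 1.63,
    "Marsupialia": 2.69,
    "Eutheria": 3.53,
    "Paleognathae": 3.29,
    "Non-Passeriformes": 4.65,
    "Passeriformes": 6.18,
}

#: Dimensionless BMR ratios a/a_Passeriformes computed at the weighted
#: common slopes (OLS b = 0.70449, PGLS b = 0.698337).
BMR_RATIO_OLS_W = {
    "Monotremata": 0.2915,
    "Marsupialia": 0.4600,
    "Eutheria": 0.5977,
    "Paleognathae": 0.5960,
    "Non-Passeriformes": 0.7833,
    "Passeriformes": 1.0000,
}

BMR_RATIO_PGLS_W = {
    "Monotremata": 0.3000,
    "Marsupialia": 0.4670,
    "Eutheria": 0.6054,
    "Paleognathae": 0.6153,
    "Non-Passeriformes": 0.7924,
    "Passeriformes": 1.0000,
}

#: FMR intercepts at b = 0.6851 (mL O2/h), from the literature compilation.
FMR_A_COMMON = {
    "Monotremata": 7.81,
    "Marsupialia": 11.48,
    "Eutheria": 12.52,
    "Paleognathae": 15.33,
    "Non-Passeriformes": 21.54,
    "Passeriformes": 21.32,
}

#: Residual SD of the common-slope ANCOVA model, log10 units.
RESIDUAL_SD = 0.146

REFERENCE_CLADE = "Passeriformes"


def _log_mid(label: str) -> float:
    lo, hi = MASS_RANGE_G[label]
    return 0.5 * (math.log10(lo) + math.log10(hi))


# Passeriformes free intercept: anchor the free-slope line to the
# common-slope line at the middle of the clade's log-mass span.
OLS_A["Passeriformes"] = 10.0 ** (
    math.log10(A_COMMON["Passeriformes"])
    + (COMMON_SLOPE_INDICATOR - OLS_B["Passeriformes"]) * _log_mid("Passeriformes")
)


def default_clade_config() -> CladeConfig:
    """The six-clade configuration with divergence times; Passeriformes
    is the reference clade for the dimensionless BMR ratio."""
    return CladeConfig(
        tuple(
            CladeInfo(
                label=c,
                divergence_time_mya=DIVERGENCE_MYA[c],
                reference=(c == REFERENCE_CLADE),
            )
            for c in CLADES
        )
    )
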