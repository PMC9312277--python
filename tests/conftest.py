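import numpy as np
import pandas as pd
import pytest

from allomet.io import CladeConfig, CladeInfo, CladeTable


@pytest.fixture
def two_clade_config() -> CladeConfig:
    return CladeConfig(
        (
            CladeInfo("A", 200.0, reference=False),
            CladeInfo("B", 100.0, reference=True),
        )
    )


@pytest.fixture
def small_table() -> CladeTable:
    df = pd.DataFrame(
        {
            "species": ["sp1", "sp2", "sp3", "sp4"],
            "clade": ["A", "A", "B", "B"],
            "mass_g": [10.0, 100.0, 20.0, 200.0],
            "bmr": [8.0, 40.0, 15.0, 90.0],
        }
    )
    return CladeTable(df, ("A", "B"))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_table(masses, bmrs, clades, fmr=None) -> CladeTable:
    n = len(masses)
    df = pd.DataFrame(
        {
            "species": [f"sp{i}" for i in range(n)],
            "clade": clades,
            "mass_g": masses,
            "bmr": bmrs,
        }
    )
    if fmr is not None:
        df["fmr"] = fmr
    return CladeTable(df)


def make_loglinear_table(rng, n_per_clade, intercepts, slopes, sigma,
                         mass_mean=2.0, mass_sd=1.0) -> CladeTable:
    """iid-noise clade table with known log-linear truth."""
    frames = []
    for i, (label, a) in enumerate(intercepts.items()):
        b = slopes[label]
        x = rng.normal(mass_mean, mass_sd, n_per_clade)
        y = a + b * x + rng.normal(0, sigma, n_per_clade)
        frames.append(
            pd.DataFrame(
                {
                    "species": [f"{label}_{j}" for j in range(n_per_clade)],
                    "clade": label,
                    "mass_g": 10.0**x,
                    "bmr": 10.0**y,
                }
            )
        )
    return CladeTable(pd.concat(frames, ignore_index=True), tuple(intercepts))
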