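"""Synthetic clade-structured allometry data with known truth.

Generates ultrametric pure-birth clade trees and species tables in which
log10(BMR) = log10(a) + b*log10(mass) + eps, with eps a mixture of a
Brownian-motion deviate on the clade tree (weight sqrt(lambda)) and
independent Gaussian noise (weight sqrt(1 - lambda)), both scaled so the
marginal SD equals ``residual_sd``. Tip covariance of the residuals is
then sigma^2 * [lambda * C_offdiag + diag], exactly the Pagel-lambda
covariance the PGLS module assumes, so recovery tests are well-posed.

All randomness flows from one integer seed through
``numpy.random.SeedSequence.spawn`` (one child stream per clade for the
tree and one for the traits), so per-clade output is reproducible and
independent of the order of generation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import dendropy
import numpy as np
import pandas as pd

from . import reference_data as ref
from .io import CladeTable

__all__ = [
    "CladeSimSpec",
    "SimulatedStudy",
    "simulate_clade_tree",
    "simulate_clade_data",
    "simulate_study",
    "default_study_specs",
]


@dataclass(frozen=True)
class CladeSimSpec:
    """Generating parameters for one clade."""

    label: str
    n_species: int
    log10_mass_mean: float
    log10_mass_sd: float
    true_log10_a: float
    true_b: float
    residual_sd: float = ref.RESIDUAL_SD
    lambda_true: float = 0.0
    fmr_over_bmr: float | None = None

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be positive")
        if not 0.0 <= self.lambda_true <= 1.0:
            raise ValueError("lambda_true must lie in [0, 1]")
        if self.fmr_over_bmr is not None and self.fmr_over_bmr <= 0:
            raise ValueError("fmr_over_bmr must be positive")


def simulate_clade_tree(
    n_tips: int, seed, label_prefix: str = "t"
) -> dendropy.Tree:
    """Ultrametric pure-birth (Yule) tree rescaled to unit root-to-tip depth.

    ``seed`` is an int or a ``numpy.random.Generator``. Lineages split at
    rate 1 per lineage; after the n-th tip appears the process runs for
    one more exponential waiting time so every terminal branch is
    strictly positive (keeps the tip covariance positive-definite at
    lambda = 1).
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    birth: dict[int, float] = {}
    a = dendropy.Node()
    b = dendropy.Node()
    root.add_child(a)
    root.add_child(b)
    active = [a, b]
    birth[id(a)] = birth[id(b)] = 0.0
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        i = int(rng.integers(len(active)))
        node = active[i]
        node.edge.length = t - birth[id(node)]
        c1, c2 = dendropy.Node(), dendropy.Node()
        node.add_child(c1)
        node.add_child(c2)
        birth[id(c1)] = birth[id(c2)] = t
        active[i] = c1
        active.append(c2)
    t_end = t + rng.exponential(1.0 / n_tips)
    for node in active:
        node.edge.length = t_end - birth[id(node)]
    # rescale to unit depth
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= t_end
    for i, leaf in enumerate(tree.leaf_node_iter()):
        taxon = taxa.new_taxon(f"{label_prefix}{i + 1}")
        leaf.taxon = taxon
    tree.is_rooted = True
    return tree


def _bm_deviates(tree: dendropy.Tree, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Brownian-motion tip deviates with marginal SD ``sd`` on a unit-depth tree.

    Returned in the order of ``tree.leaf_node_iter()``.
    """
    from .pgls import tree_covariance

    C = tree_covariance(tree).C
    L = np.linalg.cholesky(C)
    z = rng.standard_normal(C.shape[0])
    return sd * (L @ z)


def simulate_clade_data(
    spec: CladeSimSpec, tree: dendropy.Tree, seed
) -> pd.DataFrame:
    """Species rows (species, clade, mass_g, bmr[, fmr]) for one clade.

    Masses are lognormal (Normal in log10); the BMR residual mixes a
    tree-structured Brownian deviate and independent noise according to
    ``spec.lambda_true``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    leaves = list(tree.leaf_node_iter())
    if len(leaves) != spec.n_species:
        raise ValueError(
            f"tree has {len(leaves)} tips but spec.n_species = {spec.n_species}"
        )
    names = [lf.taxon.label for lf in leaves]
    log_m = rng.normal(spec.log10_mass_mean, spec.log10_mass_sd, spec.n_species)
    lam = spec.lambda_true
    eps = np.zeros(spec.n_species)
    if lam > 0:
        eps += math.sqrt(lam) * _bm_deviates(tree, spec.residual_sd, rng)
    if lam < 1:
        eps += math.sqrt(1.0 - lam) * rng.normal(0.0, spec.residual_sd, spec.n_species)
    log_bmr = spec.true_log10_a + spec.true_b * log_m + eps
    df = pd.DataFrame(
        {
            "species": names,
            "clade": spec.label,
            "mass_g": 10.0**log_m,
            "bmr": 10.0**log_bmr,
        }
    )
    if spec.fmr_over_bmr is not None:
        df["fmr"] = spec.fmr_over_bmr * df["bmr"]
    return df


class SimulatedStudy(NamedTuple):
    table: CladeTable
    trees: dict[str, dendropy.Tree]
    truth: dict[str, CladeSimSpec]


def simulate_study(specs: Sequence[CladeSimSpec], seed: int) -> SimulatedStudy:
    """Multi-clade study: concatenated table, per-clade trees, and the truth.

    Each clade consumes two independent child streams of the seed (tree,
    then traits), so adding a clade never perturbs the others.
    """
    specs = list(specs)
    if not specs:
        raise ValueError("empty spec list")
    labels = [s.label for s in specs]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate clade labels in specs")
    children = np.random.SeedSequence(seed).spawn(2 * len(specs))
    frames = []
    trees: dict[str, dendropy.Tree] = {}
    for i, spec in enumerate(specs):
        tree_rng = np.random.default_rng(children[2 * i])
        trait_rng = np.random.default_rng(children[2 * i + 1])
        tree = simulate_clade_tree(
            spec.n_species, tree_rng, label_prefix=f"{spec.label}_sp"
        )
        frames.append(simulate_clade_data(spec, tree, trait_rng))
        trees[spec.label] = tree
    table = CladeTable(pd.concat(frames, ignore_index=True), tuple(labels))
    return SimulatedStudy(table, trees, {s.label: s for s in specs})


def default_study_specs(
    common_b: float | None = None,
    residual_sd: float = ref.RESIDUAL_SD,
    lambdas: dict[str, float] | None = None,
    n_scale: float = 1.0,
    with_fmr: bool = False,
) -> list[CladeSimSpec]:
    """The six-clade study conditions.

    With ``common_b`` set, every clade shares that slope and uses its
    common-slope intercept; otherwise each clade gets its free-fit slope
    and intercept. ``n_scale`` shrinks sample sizes proportionally
    (minimum 3) for quick runs. Mass distributions are Normal in log10,
    centred on the midpoint of each clade's published span with SD a
    quarter of the span.
    """
    specs = []
    for label in ref.CLADES:
        lo, hi = ref.MASS_RANGE_G[label]
        mid = 0.5 * (math.log10(lo) + math.log10(hi))
        sd = 0.25 * (math.log10(hi) - math.log10(lo))
        if common_b is None:
            b = ref.OLS_B[label]
            log_a = math.log10(ref.OLS_A[label])
        else:
            b = common_b
            log_a = math.log10(ref.A_COMMON[label])
        lam = (lambdas or ref.LAMBDA)[label]
        n = max(3, round(ref.N_SPECIES[label] * n_scale))
        fmr_ratio = None
        if with_fmr:
            fmr_ratio = ref.FMR_A_COMMON[label] / ref.A_COMMON[label]
        specs.append(
            CladeSimSpec(
                label=label,
                n_species=n,
                log10_mass_mean=mid,
                log10_mass_sd=sd,
                true_log10_a=log_a,
                true_b=b,
                residual_sd=residual_sd,
                lambda_true=lam,
                fmr_over_bmr=fmr_ratio,
            )
        )
    return specs
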