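"""Reading and validation of species tables, Newick trees, and clade configuration.

Species tables are CSV/TSV files with columns ``species``, ``clade``,
``mass_g`` (grams), ``bmr`` (mL O2/h) and optionally ``fmr`` (mL O2/h).
Trees are Newick with branch lengths, handled through dendropy. Clade
configuration is YAML listing each clade's label, divergence time (Mya)
and whether it is the reference clade for the dimensionless BMR ratio.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import dendropy
import pandas as pd
import yaml

__all__ = [
    "SchemaError",
    "ValidationError",
    "CladeInfo",
    "CladeConfig",
    "CladeTable",
    "read_clade_config",
    "read_species_table",
    "write_species_table",
    "read_tree",
    "write_tree",
    "match_tree_to_table",
]

REQUIRED_COLUMNS = ("species", "clade", "mass_g", "bmr")
OPTIONAL_COLUMNS = ("fmr",)


class SchemaError(ValueError):
    """A required column is missing or the file layout is wrong."""


class ValidationError(ValueError):
    """A row violates an invariant (non-positive mass/BMR, unknown clade, ...)."""


@dataclass(frozen=True)
class CladeInfo:
    label: str
    divergence_time_mya: float
    reference: bool = False

    def __post_init__(self) -> None:
        if self.divergence_time_mya <= 0:
            raise ValidationError(
                f"clade {self.label!r}: divergence_time_mya must be positive"
            )


@dataclass(frozen=True)
class CladeConfig:
    """Ordered clade labels with divergence times and a single reference clade."""

    clades: tuple[CladeInfo, ...]

    def __post_init__(self) -> None:
        labels = [c.label for c in self.clades]
        if len(set(labels)) != len(labels):
            raise ValidationError("duplicate clade labels in configuration")
        n_ref = sum(c.reference for c in self.clades)
        if n_ref != 1:
            raise ValidationError(
                f"exactly one clade must be marked reference (found {n_ref})"
            )

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(c.label for c in self.clades)

    @property
    def reference(self) -> str:
        return next(c.label for c in self.clades if c.reference)

    def divergence_time(self, label: str) -> float:
        for c in self.clades:
            if c.label == label:
                return c.divergence_time_mya
        raise KeyError(label)


@dataclass
class CladeTable:
    """Validated species-level table plus the configured clade order.

    ``data`` keeps the input row order and has columns species, clade,
    mass_g, bmr and (optionally) fmr.
    """

    data: pd.DataFrame
    clade_order: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        df = self.data
        for col in REQUIRED_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"missing required column {col!r}")
        if not self.clade_order:
            self.clade_order = tuple(pd.unique(df["clade"]))
        dup = df["species"][df["species"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate species ids: {sorted(set(dup))}")
        bad_mass = df.index[~(df["mass_g"] > 0)]
        if len(bad_mass):
            raise ValidationError(
                f"non-positive mass_g in row(s) {list(bad_mass)} "
                f"(species {df.loc[bad_mass, 'species'].tolist()})"
            )
        bad_bmr = df.index[~(df["bmr"] > 0)]
        if len(bad_bmr):
            raise ValidationError(
                f"non-positive bmr in row(s) {list(bad_bmr)} "
                f"(species {df.loc[bad_bmr, 'species'].tolist()})"
            )
        if "fmr" in df.columns:
            fmr = df["fmr"]
            bad_fmr = df.index[fmr.notna() & ~(fmr > 0)]
            if len(bad_fmr):
                raise ValidationError(f"non-positive fmr in row(s) {list(bad_fmr)}")
        unknown = set(df["clade"]) - set(self.clade_order)
        if unknown:
            raise ValidationError(f"unknown clade label(s): {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def species(self) -> list[str]:
        return self.data["species"].tolist()

    @property
    def has_fmr(self) -> bool:
        return "fmr" in self.data.columns and self.data["fmr"].notna().any()

    def subset(self, species_ids: Sequence[str]) -> "CladeTable":
        keep = self.data["species"].isin(set(species_ids))
        return CladeTable(self.data[keep].reset_index(drop=True), self.clade_order)

    def by_clade(self, label: str) -> pd.DataFrame:
        return self.data[self.data["clade"] == label]


def _sep_for(path: str) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_clade_config(path: str) -> CladeConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        clades = tuple(
            CladeInfo(
                label=str(c["label"]),
                divergence_time_mya=float(c["divergence_time_mya"]),
                reference=bool(c.get("reference", False)),
            )
            for c in raw["clades"]
        )
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"malformed clade config {path}: {exc}") from exc
    return CladeConfig(clades)


def read_species_table(path: str, clade_config: CladeConfig | None = None) -> CladeTable:
    """Read and validate a species table; row order is preserved."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    cols = [c for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS if c in df.columns]
    df = df[cols].copy()
    df["species"] = df["species"].astype(str)
    df["clade"] = df["clade"].astype(str)
    order = clade_config.labels if clade_config is not None else ()
    return CladeTable(df.reset_index(drop=True), tuple(order))


def write_species_table(table: CladeTable, path: str) -> None:
    table.data.to_csv(path, sep=_sep_for(path), index=False)


def read_tree(path_or_string: str) -> dendropy.Tree:
    """Read a rooted Newick tree with branch lengths."""
    try:
        if os.path.exists(str(path_or_string)):
            tree = dendropy.Tree.get(path=path_or_string, schema="newick")
        else:
            tree = dendropy.Tree.get(data=path_or_string, schema="newick")
    except Exception as exc:  # dendropy raises several parser error types
        raise ValueError(f"unparseable Newick input: {exc}") from exc
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValueError("Newick tree has an edge with no branch length")
        if edge.length < 0:
            raise ValueError("Newick tree has a negative branch length")
    tree.is_rooted = True
    return tree


def write_tree(tree: dendropy.Tree, path: str) -> None:
    tree.write(path=path, schema="newick", suppress_rooting=True)


def _norm(label: str) -> str:
    return label.strip().replace(" ", "_")


class MatchResult(NamedTuple):
    tree: dendropy.Tree
    table: CladeTable
    dropped_tips: list[str]
    dropped_species: list[str]


def match_tree_to_table(tree: dendropy.Tree, table: CladeTable) -> MatchResult:
    """Prune tree and filter table to their common species set.

    Tip labels match species ids after space/underscore normalisation only.
    Raises ``ValueError`` when the intersection is empty.
    """
    tip_labels = [t.label for t in tree.taxon_namespace]
    tips_by_norm = {_norm(t): t for t in tip_labels}
    species_by_norm = {_norm(s): s for s in table.species}
    common = set(tips_by_norm) & set(species_by_norm)
    if not common:
        raise ValueError("tree tips and table species are disjoint")
    dropped_tips = sorted(t for k, t in tips_by_norm.items() if k not in common)
    dropped_species = sorted(s for k, s in species_by_norm.items() if k not in common)
    pruned = tree.clone(depth=1)
    if dropped_tips:
        keep = [tx for tx in pruned.taxon_namespace if _norm(tx.label) in common]
        pruned.retain_taxa(keep)
        pruned.purge_taxon_namespace()
    filtered = table.subset([species_by_norm[k] for k in common])
    return MatchResult(pruned, filtered, dropped_tips, dropped_species)
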