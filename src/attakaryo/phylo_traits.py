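"""Chromosome-number and genome-size trait mapping on time-calibrated trees.

Given an ultrametric phylogeny (branch lengths in Myr) and a table of
haploid chromosome numbers and 1C genome sizes per taxon, this module
finds the maximal clades whose sampled tips all share one haploid number
— the signature of clade-level karyotype stasis — reports their crown
and stem ages, and flags tips whose genome size departs from a reference
value by more than a multiplicative factor.

Tips without trait data are neutral by default: they neither support nor
break a clade's uniformity, because the analysis reasons over sampled
taxa only. A strict mode requiring every tip to carry a trait is
available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import dendropy
import pandas as pd

from .records import normalize_taxon

__all__ = [
    "Trait",
    "TraitTable",
    "AnnotatedTree",
    "MatchReport",
    "Clade",
    "CladeStasisReport",
    "GenomeSizeDeparture",
    "load_tree",
    "load_reference_tree",
    "read_trait_table",
    "attach_traits",
    "fixed_number_clades",
    "stasis_summary",
    "gs_departures_on_tree",
    "write_annotated_newick",
]


@dataclass(frozen=True)
class Trait:
    haploid_number: Optional[int] = None
    genome_size_1c: Optional[float] = None

    def __post_init__(self) -> None:
        if self.haploid_number is not None and self.haploid_number < 1:
            raise ValueError("haploid number must be positive")
        if self.genome_size_1c is not None and not self.genome_size_1c > 0:
            raise ValueError("genome size must be positive")


class TraitTable(dict):
    """Mapping of normalized taxon name -> Trait."""

    @classmethod
    def from_pairs(cls, pairs: dict) -> "TraitTable":
        """Build from ``{taxon: (n, gs)}`` as produced by
        records.records_to_traits."""
        table = cls()
        for taxon, (n, gs) in pairs.items():
            table[normalize_taxon(taxon)] = Trait(n, gs)
        return table


def load_tree(path: str | Path, ultrametricity_tol: float = 1e-6) -> dendropy.Tree:
    """Read a rooted Newick tree with branch lengths and validate it.

    Checks unique tip labels and ultrametricity (root-to-tip spans equal
    within ``ultrametricity_tol`` relative to tree depth).
    """
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick")
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as err:
        raise ValueError(f"duplicate tip labels in {path}: {err}") from err
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate tip labels: {dupes}")
    depths = tree.calc_node_root_distances(return_leaf_distances_only=True)
    depth = max(depths)
    if depth <= 0:
        raise ValueError("tree has no positive branch lengths")
    if (depth - min(depths)) / depth > ultrametricity_tol:
        raise ValueError(
            f"tree is not ultrametric: root-to-tip span {min(depths):g}..{depth:g}"
        )
    return tree


def load_reference_tree() -> dendropy.Tree:
    """The packaged genus-level Attina chronogram (approximate node ages)."""
    ref = resources.files("attakaryo.data").joinpath("attina_chronogram.nwk")
    with resources.as_file(ref) as path:
        return load_tree(path)


def read_trait_table(path: str | Path) -> TraitTable:
    """Read a trait TSV with columns taxon, n, gs_pg (blank = missing)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = {"taxon", "n", "gs_pg"} - set(df.columns)
    if missing:
        raise ValueError(f"trait table missing columns {sorted(missing)}")
    table = TraitTable()
    for row in df.itertuples(index=False):
        n = int(float(row.n)) if str(row.n).strip() else None
        gs = float(row.gs_pg) if str(row.gs_pg).strip() else None
        table[normalize_taxon(row.taxon)] = Trait(n, gs)
    return table


@dataclass(frozen=True)
class MatchReport:
    matched: tuple[str, ...]
    unmatched_tips: tuple[str, ...]
    unused_traits: tuple[str, ...]
    genus_matched: tuple[str, ...] = ()


@dataclass
class AnnotatedTree:
    """A tree plus the tip -> Trait assignment produced by attach_traits."""

    tree: dendropy.Tree
    tip_traits: dict[str, Trait]
    report: MatchReport

    def trait_for(self, leaf: dendropy.Node) -> Optional[Trait]:
        return self.tip_traits.get(leaf.taxon.label)


def attach_traits(
    tree: dendropy.Tree,
    traits: TraitTable,
    genus_fallback: bool = False,
) -> AnnotatedTree:
    """Match trait-table taxa to tree tips (case-insensitive, normalized).

    With ``genus_fallback``, a tip with no exact match takes the trait of
    its genus when all trait-table entries of that genus agree on the
    haploid number (genome size is averaged); ambiguous genera are left
    unmatched. Raises on duplicate tip labels or zero matches.
    """
    if not traits:
        raise ValueError("empty trait table")
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate tip labels in tree")

    by_key = {normalize_taxon(k).lower(): (k, v) for k, v in traits.items()}
    tip_traits: dict[str, Trait] = {}
    matched, unmatched, genus_matched = [], [], []
    used = set()
    for label in labels:
        key = normalize_taxon(label).lower()
        if key in by_key:
            name, trait = by_key[key]
            tip_traits[label] = trait
            matched.append(label)
            used.add(name)
            continue
        if genus_fallback:
            genus = key.split()[0]
            members = [
                (name, t)
                for k, (name, t) in by_key.items()
                if k.split()[0] == genus and t.haploid_number is not None
            ]
            ns = {t.haploid_number for _, t in members}
            if len(ns) == 1:
                gss = [
                    t.genome_size_1c
                    for _, t in members
                    if t.genome_size_1c is not None
                ]
                tip_traits[label] = Trait(
                    ns.pop(), sum(gss) / len(gss) if gss else None
                )
                genus_matched.append(label)
                continue
        unmatched.append(label)
    if not tip_traits:
        raise ValueError("no trait-table taxon matches any tip label")
    unused = tuple(sorted(set(traits) - used))
    return AnnotatedTree(
        tree=tree,
        tip_traits=tip_traits,
        report=MatchReport(
            matched=tuple(matched),
            unmatched_tips=tuple(unmatched),
            unused_traits=unused,
            genus_matched=tuple(genus_matched),
        ),
    )


@dataclass(frozen=True)
class Clade:
    """A monophyletic group uniform for one haploid number."""

    haploid_number: int
    tip_labels: tuple[str, ...]
    trait_bearing_tips: tuple[str, ...]
    crown_age: float
    stem_age: float

    def __post_init__(self) -> None:
        if self.crown_age < 0 or self.stem_age < self.crown_age:
            raise ValueError("need 0 <= crown age <= stem age")


def _node_age(node: dendropy.Node) -> float:
    """Maximum tip-to-node path length (= node age on an ultrametric tree)."""
    best = 0.0
    stack = [(node, 0.0)]
    while stack:
        nd, d = stack.pop()
        if nd.is_leaf():
            best = max(best, d)
        for child in nd.child_nodes():
            stack.append((child, d + (child.edge.length or 0.0)))
    return best


def _haploid_values_below(node, tip_traits) -> tuple[set, list]:
    values, bearing = set(), []
    for leaf in node.leaf_iter():
        trait = tip_traits.get(leaf.taxon.label)
        if trait is not None and trait.haploid_number is not None:
            values.add(trait.haploid_number)
            bearing.append(leaf.taxon.label)
    return values, bearing


def fixed_number_clades(
    atree: AnnotatedTree, haploid_number: int, strict: bool = False
) -> list[Clade]:
    """Maximal clades in which every sampled tip has the given n.

    A node qualifies when all trait-bearing tips below it carry
    ``haploid_number`` and at least one does; in strict mode trait-less
    tips also disqualify a clade. Maximality: the node's parent does not
    qualify. Polytomies are single clades. Sorted by crown age
    descending.
    """

    def qualifies(node) -> bool:
        values, bearing = _haploid_values_below(node, atree.tip_traits)
        if values != {haploid_number}:
            return False
        if strict:
            total_tips = sum(1 for _ in node.leaf_iter())
            if total_tips != len(bearing):
                return False
        return True

    clades = []
    for node in atree.tree.preorder_node_iter():
        if not qualifies(node):
            continue
        if node.parent_node is not None and qualifies(node.parent_node):
            continue
        values, bearing = _haploid_values_below(node, atree.tip_traits)
        crown = _node_age(node)
        stem = crown + (node.edge.length or 0.0) if node.parent_node else crown
        clades.append(
            Clade(
                haploid_number=haploid_number,
                tip_labels=tuple(l.taxon.label for l in node.leaf_iter()),
                trait_bearing_tips=tuple(bearing),
                crown_age=crown,
                stem_age=stem,
            )
        )
    clades.sort(key=lambda c: -c.crown_age)
    return clades


@dataclass(frozen=True)
class CladeStasisReport:
    haploid_number: int
    clades: tuple[Clade, ...]

    @property
    def independent_clade_count(self) -> int:
        return len(self.clades)

    @property
    def oldest_crown_age(self) -> float:
        return max(c.crown_age for c in self.clades)


@dataclass(frozen=True)
class StasisSummary:
    reports: tuple[CladeStasisReport, ...]
    modal_haploid_numbers: tuple[int, ...]

    def for_number(self, n: int) -> Optional[CladeStasisReport]:
        for report in self.reports:
            if report.haploid_number == n:
                return report
        return None


def stasis_summary(atree: AnnotatedTree, strict: bool = False) -> StasisSummary:
    """One CladeStasisReport per observed haploid number, plus the modal
    number(s) across trait-bearing tips."""
    counts: dict[int, int] = {}
    for trait in atree.tip_traits.values():
        if trait.haploid_number is not None:
            counts[trait.haploid_number] = counts.get(trait.haploid_number, 0) + 1
    if not counts:
        raise ValueError("no tip carries a haploid number")
    reports = tuple(
        CladeStasisReport(
            haploid_number=n,
            clades=tuple(fixed_number_clades(atree, n, strict=strict)),
        )
        for n in sorted(counts)
    )
    top = max(counts.values())
    modal = tuple(sorted(n for n, c in counts.items() if c == top))
    return StasisSummary(reports=reports, modal_haploid_numbers=modal)


@dataclass(frozen=True)
class GenomeSizeDeparture:
    taxon: str
    genome_size_1c: float
    direction: str  # "high" or "low"
    sister_context: tuple[str, ...]


def gs_departures_on_tree(
    atree: AnnotatedTree, center: float = 0.38, factor: float = 1.3
) -> list[GenomeSizeDeparture]:
    """Tips whose genome size lies outside [center/factor, center*factor].

    ``center`` defaults to the 0.38 pg compilation mean for fungus-farming
    ants. Each flagged tip carries its local clade context (the other
    tips under its parent node). Sorted by genome size descending.
    """
    if factor < 1.0:
        raise ValueError("factor must be >= 1")
    if not any(t.genome_size_1c is not None for t in atree.tip_traits.values()):
        raise ValueError("no tip carries a genome size")
    flagged = []
    for leaf in atree.tree.leaf_node_iter():
        trait = atree.tip_traits.get(leaf.taxon.label)
        if trait is None or trait.genome_size_1c is None:
            continue
        gs = trait.genome_size_1c
        if gs > center * factor:
            direction = "high"
        elif gs < center / factor:
            direction = "low"
        else:
            continue
        parent = leaf.parent_node
        context = tuple(
            l.taxon.label
            for l in (parent.leaf_iter() if parent else [leaf])
            if l is not leaf
        )
        flagged.append(
            GenomeSizeDeparture(
                taxon=leaf.taxon.label,
                genome_size_1c=gs,
                direction=direction,
                sister_context=context,
            )
        )
    flagged.sort(key=lambda d: -d.genome_size_1c)
    return flagged


def write_annotated_newick(atree: AnnotatedTree, path: str | Path) -> None:
    """Write the tree with trait annotations as bracket comments."""
    tree = atree.tree.clone(depth=1)
    for leaf in tree.leaf_node_iter():
        trait = atree.tip_traits.get(leaf.taxon.label)
        if trait is None:
            continue
        parts = []
        if trait.haploid_number is not None:
            parts.append(f"n={trait.haploid_number}")
        if trait.genome_size_1c is not None:
            parts.append(f"gs={trait.genome_size_1c:g}")
        if parts:
            leaf.annotations.add_new("traits", ",".join(parts))
    tree.write(path=str(path), schema="newick", suppress_annotations=False)
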