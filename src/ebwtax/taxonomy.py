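"""Taxonomic tree, genome-to-taxon map, and rank resolution.

The rank ladder is fixed to genome < species < genus < family < order < class
< phylum (most to least specific).  Genomes are modeled as leaf taxa of rank
"genome" under their species, so "classified to genome G" and "classified to
taxon T" are the same mechanism.  Nodes of rank "no_rank" are transparent:
lineage walks skip them.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

RANKS: tuple[str, ...] = ("genome", "species", "genus", "family", "order", "class", "phylum")
NO_RANK = "no_rank"
_RANK_INDEX = {rank: i for i, rank in enumerate(RANKS)}


class TaxonomyError(ValueError):
    """Raised for malformed taxonomy tables or genome maps."""


@dataclass(frozen=True)
class TaxonomyNode:
    taxid: int
    parent: int
    rank: str
    name: str

    def __post_init__(self) -> None:
        if self.rank not in RANKS and self.rank != NO_RANK:
            raise TaxonomyError(f"taxid {self.taxid}: unknown rank {self.rank!r}")


class TaxonomyTree:
    """Parent-pointer tree with exactly one root (parent == self) and no cycles."""

    def __init__(self, nodes: Iterable[TaxonomyNode]):
        self.nodes: dict[int, TaxonomyNode] = {}
        for node in nodes:
            if node.taxid in self.nodes:
                raise TaxonomyError(f"duplicate taxid {node.taxid}")
            self.nodes[node.taxid] = node
        roots = [t for t, n in self.nodes.items() if n.parent == t]
        if len(roots) != 1:
            raise TaxonomyError(f"expected exactly one root, found {len(roots)}")
        self.root = roots[0]
        for node in self.nodes.values():
            if node.parent not in self.nodes:
                raise TaxonomyError(f"taxid {node.taxid}: dangling parent {node.parent}")
        # cycle check by walking every lineage with a step budget
        for taxid in self.nodes:
            self.lineage(taxid)

    def lineage(self, taxid: int) -> list[int]:
        """Taxids from the node up to the root (inclusive)."""
        if taxid not in self.nodes:
            raise TaxonomyError(f"unknown taxid {taxid}")
        path, seen = [], set()
        cur = taxid
        while True:
            if cur in seen:
                raise TaxonomyError(f"cycle in taxonomy involving taxid {cur}")
            seen.add(cur)
            path.append(cur)
            parent = self.nodes[cur].parent
            if parent == cur:
                return path
            cur = parent


GenomeTaxonMap = dict[str, int]


def load_taxonomy(nodes_path: str | Path, map_path: str | Path) -> tuple[TaxonomyTree, GenomeTaxonMap]:
    """Load a nodes TSV (taxid, parent, rank, name) and a genome-map TSV (genome_id, taxid)."""
    nodes = []
    with open(nodes_path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header[:3] != ["taxid", "parent", "rank"]:
            raise TaxonomyError(f"{nodes_path}: expected header taxid/parent/rank/name")
        for row in reader:
            if not row:
                continue
            name = row[3] if len(row) > 3 else ""
            nodes.append(TaxonomyNode(int(row[0]), int(row[1]), row[2], name))
    tree = TaxonomyTree(nodes)

    gmap: GenomeTaxonMap = {}
    with open(map_path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        next(reader)  # header
        for row in reader:
            if not row:
                continue
            genome_id, taxid = row[0], int(row[1])
            if taxid not in tree.nodes:
                raise TaxonomyError(f"genome {genome_id!r} mapped to absent taxid {taxid}")
            gmap[genome_id] = taxid
    if not gmap:
        raise TaxonomyError(f"{map_path}: empty genome map")
    return tree, gmap


def taxon_at_rank(tree: TaxonomyTree, taxid: int, rank: str) -> int | None:
    """The unique ancestor (or self) of the given rank, or None if the lineage lacks it.

    no_rank nodes are skipped; the walk stops once it passes above the
    requested rank (rank order along a root path is non-increasing in
    specificity).
    """
    if rank not in _RANK_INDEX:
        raise TaxonomyError(f"unknown rank {rank!r}")
    target = _RANK_INDEX[rank]
    for cur in tree.lineage(taxid):
        node = tree.nodes[cur]
        if node.rank == NO_RANK:
            continue
        idx = _RANK_INDEX[node.rank]
        if idx == target:
            return cur
        if idx > target:
            return None
    return None


def common_taxon(tree: TaxonomyTree, taxids: set[int] | Iterable[int], min_rank: str,
                 fallback: bool = False) -> tuple[int, str] | None:
    """Shared taxon of a set of taxids at (fixed mode) or at-or-above (fallback) min_rank.

    Fixed mode asks whether all lineages meet at one taxon at exactly
    ``min_rank``.  Fallback mode walks the ladder upward from ``min_rank`` to
    phylum and returns the first (lowest) rank where all lineages agree, or
    None if they only meet above phylum.
    """
    taxids = set(taxids)
    if not taxids:
        raise TaxonomyError("empty taxid set")
    ranks_to_try = RANKS[_RANK_INDEX[min_rank]:] if fallback else (min_rank,)
    for rank in ranks_to_try:
        ancestors = {taxon_at_rank(tree, t, rank) for t in taxids}
        if None not in ancestors and len(ancestors) == 1:
            return next(iter(ancestors)), rank
    return None


def write_taxonomy_tsv(nodes: Iterable[TaxonomyNode], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("taxid\tparent\trank\tname\n")
        for n in nodes:
            fh.write(f"{n.taxid}\t{n.parent}\t{n.rank}\t{n.name}\n")


def write_genome_map_tsv(gmap: GenomeTaxonMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\ttaxid\n")
        for gid, taxid in gmap.items():
            fh.write(f"{gid}\t{taxid}\n")
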