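"""Taxonomic assignment by lowest common ancestor (LCA) and abundance rollup.

Each gene's reference-database hits are filtered to a top-score band
(hits within ``top_fraction`` of the best bit score) and the gene is
assigned to the lowest common ancestor of the retained hits' taxa —
the MEGAN-style rule. Taxon abundances are cumulative: a node's abundance
includes every gene assigned to it or to any descendant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import pandas as pd

from . import align
from .errors import TaxonomyIntegrityError

UNASSIGNED = "unassigned"

RANKS = ("root", "domain", "phylum", "class", "order", "family", "genus", "species")


@dataclass
class TaxNode:
    parent_id: str | None
    rank: str
    name: str


@dataclass
class TaxonomyTree:
    """Rooted taxonomy with parent pointers, NCBI-dump style."""

    nodes: dict[str, TaxNode]
    root: str

    def parent(self, node_id: str) -> str | None:
        return self.nodes[node_id].parent_id

    def rank(self, node_id: str) -> str:
        return self.nodes[node_id].rank

    def name(self, node_id: str) -> str:
        return self.nodes[node_id].name

    def path_to_root(self, node_id: str) -> list[str]:
        if node_id not in self.nodes:
            raise TaxonomyIntegrityError(f"unknown taxon {node_id!r}")
        path = [node_id]
        seen = {node_id}
        while (parent := self.nodes[path[-1]].parent_id) is not None:
            if parent in seen:
                raise TaxonomyIntegrityError(f"cycle at taxon {parent!r}")
            path.append(parent)
            seen.add(parent)
        if path[-1] != self.root:
            raise TaxonomyIntegrityError(f"taxon {node_id!r} does not reach the root")
        return path

    def lca(self, node_ids: Iterable[str]) -> str:
        """Lowest common ancestor of a non-empty set of nodes."""
        ids = list(node_ids)
        path0 = self.path_to_root(ids[0])
        candidates = set(path0)
        for node_id in ids[1:]:
            candidates &= set(self.path_to_root(node_id))
        for node in path0:  # path is deepest-first
            if node in candidates:
                return node
        raise TaxonomyIntegrityError("nodes share no ancestor")

    def ancestor_at_rank(self, node_id: str, rank: str) -> str | None:
        for node in self.path_to_root(node_id):
            if self.nodes[node].rank == rank:
                return node
        return None

    def descendants(self, node_id: str) -> set[str]:
        children: dict[str, list[str]] = {}
        for nid, node in self.nodes.items():
            if node.parent_id is not None:
                children.setdefault(node.parent_id, []).append(nid)
        out: set[str] = set()
        stack = [node_id]
        while stack:
            current = stack.pop()
            for child in children.get(current, ()):
                out.add(child)
                stack.append(child)
        return out

    # --- serialization ---

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "node_id": nid,
                "parent_id": "" if node.parent_id is None else node.parent_id,
                "rank": node.rank,
                "name": node.name,
            }
            for nid, node in sorted(self.nodes.items())
        ]
        return pd.DataFrame(rows, columns=["node_id", "parent_id", "rank", "name"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TaxonomyTree":
        nodes = {}
        root = None
        for r in frame.itertuples():
            parent = None if (pd.isna(r.parent_id) or r.parent_id == "") else str(r.parent_id)
            nodes[str(r.node_id)] = TaxNode(parent, str(r.rank), str(r.name))
            if parent is None:
                root = str(r.node_id)
        if root is None:
            raise TaxonomyIntegrityError("taxonomy has no root (node without parent)")
        return cls(nodes=nodes, root=root)


class RefHit(NamedTuple):
    reference_id: str
    taxon_id: str
    bit_score: float
    e_value: float


@dataclass
class HitSet:
    """Scored reference-database hits for one gene."""

    gene_id: str
    hits: list[RefHit] = field(default_factory=list)


def assign_lca(
    hitset: HitSet,
    tree: TaxonomyTree,
    top_fraction: float = 0.10,
    min_score: float = 50.0,
    best_hit_only: bool = False,
) -> str:
    """Assign a gene to the LCA of its near-best hits.

    Hits below ``min_score`` bits are ignored; of the rest, those within
    ``top_fraction`` of the best bit score are retained and their taxa
    reduced to a lowest common ancestor. With ``best_hit_only`` the single
    best hit wins outright. Returns ``"unassigned"`` if no hit survives.
    """
    scored = [h for h in hitset.hits if h.bit_score >= min_score]
    if not scored:
        return UNASSIGNED
    for h in scored:
        if h.taxon_id not in tree.nodes:
            raise TaxonomyIntegrityError(f"hit taxon {h.taxon_id!r} missing from tree")
    best = max(h.bit_score for h in scored)
    if best_hit_only:
        top = max(scored, key=lambda h: (h.bit_score, h.reference_id))
        return top.taxon_id
    retained = [h for h in scored if h.bit_score >= (1.0 - top_fraction) * best]
    return tree.lca([h.taxon_id for h in retained])


class TaxonAbundance(NamedTuple):
    by_node: dict[str, float]
    unassigned: float


def taxon_abundance(
    assignments: dict[str, str],
    table,
    sample: str,
    tree: TaxonomyTree,
) -> TaxonAbundance:
    """Cumulative taxon abundances for one sample.

    A node's abundance sums the abundances of genes assigned to it or any
    of its descendants; unassigned genes are totalled separately.
    """
    by_node: dict[str, float] = {}
    unassigned = 0.0
    for (gene_id, sample_id), abundance in table.entries.items():
        if sample_id != sample:
            continue
        node = assignments.get(gene_id, UNASSIGNED)
        if node == UNASSIGNED:
            unassigned += abundance
            continue
        for ancestor in tree.path_to_root(node):
            by_node[ancestor] = by_node.get(ancestor, 0.0) + abundance
    return TaxonAbundance(by_node=by_node, unassigned=unassigned)


def taxa_with_gene(
    family: str,
    verified: list,
    assignments: dict[str, str],
    table,
    sample: str,
    tree: TaxonomyTree,
) -> list[tuple[str, str, float]]:
    """Rank taxa carrying a gene family by summed abundance of its verified genes.

    Genes assigned at or below genus rank are reported under their genus;
    genes assigned above genus keep their assigned node, labelled with its
    own rank. Returns (taxon name, rank, abundance) sorted by decreasing
    abundance then name.
    """
    sums: dict[str, float] = {}
    for hit in verified:
        if hit.family_name != family or not hit.verified:
            continue
        abundance = table.abundance(hit.gene_id, sample)
        if abundance <= 0:
            continue
        node = assignments.get(hit.gene_id, UNASSIGNED)
        if node != UNASSIGNED:
            genus = tree.ancestor_at_rank(node, "genus")
            node = genus if genus is not None else node
        sums[node] = sums.get(node, 0.0) + abundance
    out = []
    for node, abundance in sums.items():
        if node == UNASSIGNED:
            out.append((UNASSIGNED, UNASSIGNED, abundance))
        else:
            out.append((tree.name(node), tree.rank(node), abundance))
    return sorted(out, key=lambda item: (-item[2], item[0]))


def build_hitsets(
    genes: list,
    references: list[tuple[str, str]],
    mapping: dict[str, str],
    max_hits: int = 25,
) -> list[HitSet]:
    """Score genes against a reference protein set with the local aligner.

    ``references`` is a list of (reference_id, protein sequence);
    ``mapping`` maps reference_id -> taxon node id. Scores are converted to
    bits and crude E-values via Karlin-Altschul statistics.
    """
    total_residues = sum(len(seq) for _, seq in references)
    hitsets = []
    for gene in genes:
        hits = []
        for ref_id, ref_seq in references:
            raw = align.local_score(gene.protein, ref_seq)
            if raw <= 0:
                continue
            hits.append(
                RefHit(
                    reference_id=ref_id,
                    taxon_id=mapping[ref_id],
                    bit_score=align.raw_to_bits(raw),
                    e_value=align.local_evalue(raw, len(gene.protein), total_residues),
                )
            )
        hits.sort(key=lambda h: (-h.bit_score, h.reference_id))
        hitsets.append(HitSet(gene_id=gene.gene_id, hits=hits[:max_hits]))
    return hitsets
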