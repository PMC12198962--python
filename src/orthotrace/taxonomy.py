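"""Ranked taxonomy: distances, traversal order and candidate-pool pruning.

The core-compilation phase of the ortholog search walks candidate species in
the order of increasing taxonomic distance to the seed species and shrinks
the candidate pool after every accepted core ortholog.  Taxonomic distance is
defined on a fixed eight-level rank ladder (species < genus < family < order
< class < phylum < kingdom < superkingdom): the distance between two species
is the ladder index of the rank of their lowest *ranked* common ancestor.
Unranked intermediate nodes (common in NCBI-style taxonomies) are skipped
upward; ranks below species count as species level.

Trees produced by the pruning operations remember their source taxonomy, so
distances to already-pruned leaves (the seed species, earlier primer taxa)
remain well defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

RANK_LADDER = (
    "species",
    "genus",
    "family",
    "order",
    "class",
    "phylum",
    "kingdom",
    "superkingdom",
)
RANK_INDEX = {rank: i for i, rank in enumerate(RANK_LADDER)}

#: ranks that sort below "species" on the ladder; they map to ladder index 0
BELOW_SPECIES = {
    "subspecies",
    "strain",
    "varietas",
    "forma",
    "forma specialis",
    "isolate",
    "serotype",
    "biotype",
    "genotype",
    "no rank species",
}


class TaxonomyError(ValueError):
    """Raised for structurally invalid taxonomies or unknown taxa."""


@dataclass(frozen=True)
class TaxonNode:
    id: int
    parent: Optional[int]  # None for the root
    rank: str
    name: str


def rank_ladder_index(rank: str) -> Optional[int]:
    """Ladder index of a rank name, 0 for below-species ranks, None if unranked."""
    if rank in RANK_INDEX:
        return RANK_INDEX[rank]
    if rank in BELOW_SPECIES:
        return 0
    return None


class TaxonomyTree:
    """A rooted, ranked taxonomy with parent pointers.

    Parameters
    ----------
    nodes:
        The node set.  Exactly one node must have ``parent=None``.
    source:
        The taxonomy this tree was derived from by pruning; used to resolve
        distances involving pruned leaves.  ``None`` for a freshly loaded tree.
    """

    def __init__(
        self,
        nodes: Iterable[TaxonNode],
        source: "TaxonomyTree | None" = None,
        leaf_whitelist: "set[int] | None" = None,
    ):
        self.nodes: dict[int, TaxonNode] = {}
        for node in nodes:
            if node.id in self.nodes:
                raise TaxonomyError(f"duplicate id {node.id}")
            self.nodes[node.id] = node
        roots = [n.id for n in self.nodes.values() if n.parent is None]
        if len(roots) != 1:
            raise TaxonomyError(
                "missing root" if not roots else f"multiple roots: {sorted(roots)}"
            )
        self.root: int = roots[0]
        self.children: dict[int, list[int]] = {nid: [] for nid in self.nodes}
        for node in self.nodes.values():
            if node.parent is not None:
                if node.parent not in self.nodes:
                    raise TaxonomyError(f"orphan node {node.id} (parent {node.parent} absent)")
                self.children[node.parent].append(node.id)
        for kids in self.children.values():
            kids.sort()
        # cycle check: every node must reach the root
        for nid in self.nodes:
            seen = set()
            cur: Optional[int] = nid
            while cur is not None:
                if cur in seen:
                    raise TaxonomyError(f"cycle detected at node {cur}")
                seen.add(cur)
                cur = self.nodes[cur].parent
        self.source: TaxonomyTree = source if source is not None else self
        # pruned trees remember which leaves were retained, so a tree pruned
        # down to nothing reports an empty leaf set (the root never becomes
        # a candidate species)
        self._leaf_whitelist = leaf_whitelist

    # ------------------------------------------------------------------ basics

    def __contains__(self, taxon: int) -> bool:
        return taxon in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def is_leaf(self, taxon: int) -> bool:
        return taxon in self.nodes and not self.children[taxon]

    def leaves(self) -> list[int]:
        structural = (nid for nid in self.nodes if not self.children[nid])
        if self._leaf_whitelist is None:
            return sorted(structural)
        return sorted(nid for nid in structural if nid in self._leaf_whitelist)

    def lineage(self, taxon: int) -> list[int]:
        """Node ids from ``taxon`` up to and including the root."""
        node = self._resolve(taxon)
        out = [node.id]
        src = self.source
        while node.parent is not None:
            node = src.nodes[node.parent]
            out.append(node.id)
        return out

    def _resolve(self, taxon: int) -> TaxonNode:
        if taxon in self.nodes:
            return self.nodes[taxon]
        if taxon in self.source.nodes:
            return self.source.nodes[taxon]
        raise TaxonomyError(f"taxon {taxon} not in tree")

    def lca(self, *taxa: int) -> int:
        """Lowest common ancestor of one or more taxa (by id)."""
        if not taxa:
            raise ValueError("lca of empty taxon set")
        common: Optional[list[int]] = None
        for t in taxa:
            lin = self.lineage(t)
            if common is None:
                common = lin
            else:
                anc = set(lin)
                common = [x for x in common if x in anc]
        assert common  # the root is always shared
        return common[0]

    def restrict(self, keep_leaves: Iterable[int]) -> "TaxonomyTree":
        """New tree containing the given leaves and their ancestors only."""
        keep = set(keep_leaves)
        for t in keep:
            if not self.is_leaf(t):
                raise TaxonomyError(f"taxon {t} not a leaf of tree")
        node_ids = {self.root}
        for t in keep:
            node_ids.update(self.lineage(t))
        nodes = [self.nodes[nid] for nid in node_ids]
        return TaxonomyTree(nodes, source=self.source, leaf_whitelist=keep)


# ---------------------------------------------------------------------- I/O


def load_taxonomy(path) -> TaxonomyTree:
    """Load a taxonomy from a 4-column tab-separated table.

    Columns (header required): ``id``, ``parent_id``, ``rank``, ``name``.
    The root row has an empty ``parent_id`` or one equal to its own id.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"id", "parent_id", "rank", "name"}
    if not required.issubset(df.columns):
        raise TaxonomyError(f"taxonomy table must have columns {sorted(required)}")
    nodes = []
    for row in df.itertuples(index=False):
        nid = int(row.id)
        parent = None if row.parent_id in ("", str(nid)) else int(row.parent_id)
        nodes.append(TaxonNode(nid, parent, row.rank, row.name))
    tree = TaxonomyTree(nodes)
    _validate_ranks(tree)
    return tree


def write_taxonomy(tree: TaxonomyTree, path) -> None:
    rows = []
    for nid in sorted(tree.nodes):
        n = tree.nodes[nid]
        rows.append((n.id, "" if n.parent is None else n.parent, n.rank, n.name))
    pd.DataFrame(rows, columns=["id", "parent_id", "rank", "name"]).to_csv(
        path, sep="\t", index=False
    )


def _validate_ranks(tree: TaxonomyTree) -> None:
    # leaves must sit at species level or below
    for leaf in tree.leaves():
        idx = rank_ladder_index(tree.nodes[leaf].rank)
        if idx is not None and idx > 0:
            raise TaxonomyError(f"leaf {leaf} carries supra-species rank {tree.nodes[leaf].rank!r}")
    # a node's rank must never lie below the rank of a descendant
    for nid, node in tree.nodes.items():
        idx = rank_ladder_index(node.rank)
        if idx is None or node.parent is None:
            continue
        cur = tree.nodes[node.parent]
        while True:
            pidx = rank_ladder_index(cur.rank)
            if pidx is not None and pidx < idx:
                raise TaxonomyError(
                    f"rank order violated: ancestor {cur.id} ({cur.rank}) below descendant {nid} ({node.rank})"
                )
            if cur.parent is None:
                break
            cur = tree.nodes[cur.parent]


# ---------------------------------------------------------------- operations


def taxonomic_distance(tree: TaxonomyTree, a: int, b: int) -> int:
    """Rank-ladder index of the lowest ranked common ancestor of two leaves.

    ``d(a, a) = 0``; symmetric.  Unranked LCA nodes are skipped upward to the
    nearest ranked ancestor; if none exists (an unranked root), the ladder top
    (superkingdom level, 7) is returned.
    """
    na, nb = tree._resolve(a), tree._resolve(b)
    src = tree.source
    if not (src.is_leaf(na.id) or tree.is_leaf(na.id)) or not (
        src.is_leaf(nb.id) or tree.is_leaf(nb.id)
    ):
        raise TaxonomyError("taxonomic_distance is defined between leaves")
    if a == b:
        return 0
    anc = tree.lca(a, b)
    node = src.nodes[anc]
    while True:
        idx = rank_ladder_index(node.rank)
        if idx is not None:
            return idx
        if node.parent is None:
            return len(RANK_LADDER) - 1
        node = src.nodes[node.parent]


def traversal_order(tree: TaxonomyTree, p0: int, rng_seed: int) -> list[int]:
    """Leaves of ``tree`` sorted by increasing taxonomic distance to ``p0``.

    Equidistant leaves are visited in a random order drawn from the seeded
    generator; ``p0`` itself is excluded.  ``p0`` may be a leaf that was
    already pruned from this tree, as long as the source taxonomy knows it.
    """
    tree._resolve(p0)  # raises for unknown taxa
    by_dist: dict[int, list[int]] = {}
    for leaf in tree.leaves():
        if leaf == p0:
            continue
        by_dist.setdefault(taxonomic_distance(tree, p0, leaf), []).append(leaf)
    rng = np.random.default_rng(rng_seed)
    order: list[int] = []
    for d in sorted(by_dist):
        group = sorted(by_dist[d])
        order.extend(np.array(group)[rng.permutation(len(group))].tolist())
    return order


def _rank_arg(rank) -> int:
    if isinstance(rank, str):
        idx = rank_ladder_index(rank)
        if idx is None:
            raise TaxonomyError(f"unknown rank {rank!r}")
        return idx
    return int(rank)


def prune_rank_bounds(tree: TaxonomyTree, p0: int, min_dist, max_dist) -> TaxonomyTree:
    """Remove leaves closer than ``min_dist`` or farther than ``max_dist`` from p0.

    Bounds are rank names (or ladder indices).  A leaf is *closer than*
    ``min_dist`` when its lowest ranked common ancestor with p0 sits at or
    below that rank — with the default lower bound "genus", the seed species
    itself and every species of its genus are removed from the candidate
    pool, so primer taxa must differ from p0 at least at the genus level.
    The upper bound removes leaves whose distance exceeds its ladder index.
    """
    lo, hi = _rank_arg(min_dist), _rank_arg(max_dist)
    if lo > hi:
        raise TaxonomyError("min_dist must not exceed max_dist on the rank ladder")
    keep = [
        leaf
        for leaf in tree.leaves()
        if lo < taxonomic_distance(tree, p0, leaf) <= hi
    ]
    return tree.restrict(keep)


def prune_after_iteration(tree: TaxonomyTree, p0: int, pi: int, min_dist) -> TaxonomyTree:
    """Prune the just-selected primer taxon ``pi`` and its taxonomic vicinity.

    Removes ``pi`` and every leaf closer than ``min_dist`` (lowest ranked
    common ancestor at or below that rank) to either ``p0`` or ``pi``: with
    ``min_dist`` "genus", all congeners of a selected primer taxon leave the
    pool.  Repeated application keeps the primer taxa pairwise more than
    ``min_dist`` apart, so the taxonomic diversity of the core group never
    decreases.
    """
    lo = _rank_arg(min_dist)
    keep = [
        leaf
        for leaf in tree.leaves()
        if leaf != pi
        and taxonomic_distance(tree, p0, leaf) > lo
        and taxonomic_distance(tree, pi, leaf) > lo
    ]
    return tree.restrict(keep)
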