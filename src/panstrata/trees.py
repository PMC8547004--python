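"""Dated phylogenies (chronograms) with node ages in million years.

A chronogram here is a rooted, ultrametric tree whose leaves are genome
identifiers and whose internal nodes carry absolute ages (MYA).  Ages are
derived from branch lengths: the root age is the root-to-leaf path length,
and every node's age is the root age minus its depth.  Trees that are not
ultrametric (within a relative tolerance of ``1e-6 * root_age``) are
rejected rather than repaired.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import dendropy
import numpy as np

__all__ = [
    "Chronogram",
    "ChronogramError",
    "chronogram_from_newick",
    "read_chronogram",
    "mrca",
    "simulate_chronogram",
]

ULTRAMETRIC_RTOL = 1e-6


class ChronogramError(ValueError):
    """Raised for invalid trees: non-ultrametric, unknown leaves, empty."""


@dataclass
class Chronogram:
    """A validated dated tree with stable node identifiers.

    Leaf nodes are identified by their taxon label; internal nodes by their
    Newick label when present, otherwise by ``N<k>`` in preorder.
    """

    tree: dendropy.Tree
    root_age: float
    ages: dict[str, float]
    leaf_sets: dict[str, frozenset[str]]
    parents: dict[str, str | None] = field(repr=False)
    children: dict[str, tuple[str, ...]] = field(repr=False)
    _nodes: dict[str, dendropy.Node] = field(repr=False, default_factory=dict)

    @property
    def leaves(self) -> frozenset[str]:
        return self.leaf_sets[self.root_id]

    @property
    def root_id(self) -> str:
        return self.tree.seed_node._panstrata_id  # type: ignore[attr-defined]

    @property
    def node_ids(self) -> list[str]:
        return list(self.ages)

    @property
    def internal_ids(self) -> list[str]:
        return [n for n in self.ages if len(self.leaf_sets[n]) > 1]

    def clade_leaves(self, node_id: str) -> frozenset[str]:
        return self.leaf_sets[node_id]

    def is_ancestor_or_equal(self, a: str, b: str) -> bool:
        """True iff node ``a`` lies on the path from the root to node ``b``."""
        while b is not None:
            if a == b:
                return True
            b = self.parents[b]  # type: ignore[assignment]
        return False

    def path_to_root(self, node_id: str) -> list[str]:
        out = []
        cur: str | None = node_id
        while cur is not None:
            out.append(cur)
            cur = self.parents[cur]
        return out

    def edges_below(self, node_id: str) -> list[tuple[str, str]]:
        """All (parent, child) edges in the subtree rooted at ``node_id``."""
        out: list[tuple[str, str]] = []
        stack = [node_id]
        while stack:
            n = stack.pop()
            for c in self.children[n]:
                out.append((n, c))
                stack.append(c)
        return out

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


def _label_nodes(tree: dendropy.Tree) -> None:
    k = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            node._panstrata_id = node.taxon.label
        elif node.label:
            node._panstrata_id = node.label
        else:
            k += 1
            node._panstrata_id = f"N{k}"


def _build(tree: dendropy.Tree, genome_universe: Iterable[str] | None) -> Chronogram:
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if not leaves:
        raise ChronogramError("tree has no leaves")
    if len(set(leaves)) != len(leaves):
        raise ChronogramError("duplicate leaf labels in tree")
    if genome_universe is not None:
        universe = set(genome_universe)
        extra = set(leaves) - universe
        missing = universe - set(leaves)
        if extra or missing:
            raise ChronogramError(
                "leaf labels do not match declared genome universe; "
                f"unexpected leaves: {sorted(extra)}; missing: {sorted(missing)}"
            )

    _label_nodes(tree)

    # depth of each node from the root, by branch lengths
    depth: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        nid = node._panstrata_id
        if node.parent_node is None:
            depth[nid] = 0.0
        else:
            bl = node.edge.length if node.edge.length is not None else 0.0
            if bl < 0:
                raise ChronogramError(f"negative branch length above node {nid!r}")
            depth[nid] = depth[node.parent_node._panstrata_id] + bl

    leaf_depths = {lf.taxon.label: depth[lf.taxon.label] for lf in tree.leaf_node_iter()}
    root_age = max(leaf_depths.values())
    if root_age <= 0:
        raise ChronogramError("root age must be positive (all branch lengths zero?)")
    tol = ULTRAMETRIC_RTOL * root_age
    for leaf, d in leaf_depths.items():
        if abs(d - root_age) > tol:
            raise ChronogramError(
                f"tree is not ultrametric: leaf {leaf!r} at depth {d:g} "
                f"differs from root age {root_age:g} by more than {tol:g}"
            )

    ages: dict[str, float] = {}
    leaf_sets: dict[str, frozenset[str]] = {}
    parents: dict[str, str | None] = {}
    children: dict[str, tuple[str, ...]] = {}
    nodes: dict[str, dendropy.Node] = {}
    for node in tree.postorder_node_iter():
        nid = node._panstrata_id
        nodes[nid] = node
        if node.is_leaf():
            leaf_sets[nid] = frozenset([nid])
            ages[nid] = 0.0
        else:
            kids = [c._panstrata_id for c in node.child_nodes()]
            leaf_sets[nid] = frozenset().union(*(leaf_sets[c] for c in kids))
            ages[nid] = root_age - depth[nid]
        children[nid] = tuple(c._panstrata_id for c in node.child_nodes())
        parents[nid] = (
            node.parent_node._panstrata_id if node.parent_node is not None else None
        )
    # preorder-stable ordering of the ages mapping
    ordered = [n._panstrata_id for n in tree.preorder_node_iter()]
    ages = {n: ages[n] for n in ordered}
    return Chronogram(tree, root_age, ages, leaf_sets, parents, children, nodes)


def chronogram_from_newick(
    newick: str, genome_universe: Iterable[str] | None = None
) -> Chronogram:
    """Parse a Newick string into a validated :class:`Chronogram`."""
    try:
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderError as e:
        raise ChronogramError(f"invalid Newick: {e}") from e
    return _build(tree, genome_universe)


def read_chronogram(path, genome_universe: Iterable[str] | None = None) -> Chronogram:
    """Read a Newick file and validate it against a declared genome universe."""
    with open(path) as fh:
        return chronogram_from_newick(fh.read(), genome_universe)


def mrca(chron: Chronogram, genomes: Iterable[str]) -> str:
    """Most recent common ancestor node id of a set of leaf labels."""
    genomes = list(genomes)
    if not genomes:
        raise ChronogramError("cannot take MRCA of an empty genome set")
    unknown = set(genomes) - chron.leaves
    if unknown:
        raise ChronogramError(f"unknown genomes in MRCA query: {sorted(unknown)}")
    # intersect root-to-node paths; the deepest shared node is the MRCA
    paths = [chron.path_to_root(g)[::-1] for g in set(genomes)]
    anc = None
    for step in zip(*paths):
        if len(set(step)) == 1:
            anc = step[0]
        else:
            break
    assert anc is not None
    return anc


def simulate_chronogram(
    n_leaves: int, root_age: float, rng: np.random.Generator
) -> Chronogram:
    """Draw a random ultrametric tree on ``n_leaves`` labelled g1..gN.

    Coalescent-style construction: lineages are merged in random pairs at
    strictly increasing ages, with the last merge pinned at ``root_age`` so
    that the requested root age is exact.
    """
    if n_leaves < 2:
        raise ChronogramError("need at least 2 leaves")
    if root_age <= 0:
        raise ChronogramError("root age must be positive")
    merge_ages = np.sort(rng.uniform(0.0, root_age, size=n_leaves - 2)).tolist()
    merge_ages.append(root_age)
    # each active lineage: (newick fragment, age of its top node)
    active: list[tuple[str, float]] = [(f"g{i + 1}", 0.0) for i in range(n_leaves)]
    for t in merge_ages:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        (na, aa), (nb, ab) = active[i], active[j]
        frag = f"({na}:{t - aa:.10g},{nb}:{t - ab:.10g})"
        active = [x for k, x in enumerate(active) if k not in (i, j)]
        active.append((frag, t))
    newick = active[0][0] + ";"
    return chronogram_from_newick(newick)
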