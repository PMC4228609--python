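"""Phylogeny I/O, preparation, and the shared-ancestry matrix.

All trait-evolution covariances in :mod:`litterevo.models` are built from the
pairwise root-to-MRCA path lengths among tips (the "shared ancestry" of each
species pair), so this module is the foundation of the pipeline.  Trees are
rooted, branch lengths are in millions of years (Myr).

Newick dialect: unquoted labels (underscores preserved verbatim), decimal
branch lengths, no support values; internal-node labels are read and kept —
they key the node-age table used for branch-length smoothing.
"""

from __future__ import annotations

import io
import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Phylogeny",
    "SharedAncestryMatrix",
    "NewickError",
    "TreeValidationError",
    "parse_newick",
    "write_newick",
    "read_newick_file",
    "resolve_polytomies",
    "smooth_branch_lengths",
    "shared_ancestry",
    "read_node_ages",
]


class NewickError(ValueError):
    """Malformed Newick input or invariant violation at parse time."""


class TreeValidationError(ValueError):
    """A structural invariant of a rooted time-tree is violated."""


@dataclass
class Phylogeny:
    """A rooted tree with branch lengths in Myr, wrapping a dendropy Tree.

    Invariants (checked on construction):

    * exactly one root; every non-root node has exactly one parent
      (guaranteed by the dendropy structure);
    * all branch lengths finite and >= 0 (a missing length is taken as 0
      for the root edge only);
    * tip labels unique and non-empty.
    """

    _tree: dendropy.Tree

    def __post_init__(self) -> None:
        self.validate()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "Phylogeny":
        return cls(_tree=tree)

    def copy(self) -> "Phylogeny":
        return Phylogeny(_tree=self._tree.clone(depth=1))

    # -- accessors --------------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    def node_depths(self) -> dict[dendropy.Node, float]:
        """Root-to-node path length for every node (root edge ignored)."""
        depths: dict[dendropy.Node, float] = {}
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None:
                depths[node] = 0.0
            else:
                depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
        return depths

    def tip_depths(self) -> dict[str, float]:
        depths = self.node_depths()
        return {leaf.taxon.label: depths[leaf] for leaf in self._tree.leaf_node_iter()}

    @property
    def depth(self) -> float:
        return max(self.tip_depths().values())

    def is_binary(self) -> bool:
        return all(
            len(n.child_nodes()) == 2
            for n in self._tree.preorder_internal_node_iter()
        )

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        d = np.array(list(self.tip_depths().values()))
        span = d.max() - d.min()
        return bool(span <= rel_tol * max(d.max(), 1.0))

    def prune_to(self, species: list[str]) -> "Phylogeny":
        """Subtree induced by ``species``; errors on unknown names."""
        missing = set(species) - set(self.tip_labels)
        if missing:
            raise TreeValidationError(
                f"species not in tree: {sorted(missing)}"
            )
        tree = self._tree.clone(depth=1)
        keep = [t for t in tree.taxon_namespace if t.label in set(species)]
        tree.retain_taxa(keep)
        return Phylogeny(_tree=tree)

    def drop(self, species: list[str]) -> "Phylogeny":
        keep = [s for s in self.tip_labels if s not in set(species)]
        return self.prune_to(keep)

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        if self._tree.seed_node is None:
            raise TreeValidationError("tree has no root")
        labels: list[str] = []
        for leaf in self._tree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise TreeValidationError("tip with empty label")
            labels.append(leaf.taxon.label)
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise TreeValidationError(f"duplicate tip labels: {sorted(dupes)}")
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            bl = node.edge.length
            if bl is None:
                raise TreeValidationError(
                    f"missing branch length above node {_node_name(node)!r}"
                )
            if not np.isfinite(bl) or bl < 0:
                raise TreeValidationError(
                    f"negative or non-finite branch length {bl!r} above node "
                    f"{_node_name(node)!r}"
                )


def _node_name(node: dendropy.Node) -> str:
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    return node.label or "<unnamed>"


@dataclass
class SharedAncestryMatrix:
    """Pairwise root-to-MRCA path lengths among tips.

    ``t_shared[i, j]`` is the path length (Myr) from the root down to the most
    recent common ancestor of tips i and j; the diagonal holds the root-to-tip
    distances ``tip_depth``.  Under Brownian motion this matrix *is* the trait
    covariance up to the rate constant.
    """

    species_order: list[str]
    t_shared: np.ndarray
    tip_depth: np.ndarray

    @property
    def n(self) -> int:
        return len(self.species_order)

    @property
    def depth(self) -> float:
        return float(self.tip_depth.max())

    def reorder(self, species: list[str]) -> "SharedAncestryMatrix":
        """Submatrix/permutation for the requested species order."""
        idx = {s: i for i, s in enumerate(self.species_order)}
        missing = [s for s in species if s not in idx]
        if missing:
            raise TreeValidationError(f"species not in matrix: {missing}")
        sel = np.array([idx[s] for s in species])
        return SharedAncestryMatrix(
            species_order=list(species),
            t_shared=self.t_shared[np.ix_(sel, sel)],
            tip_depth=self.tip_depth[sel],
        )


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------


def parse_newick(text: str) -> Phylogeny:
    """Parse a Newick string into a validated :class:`Phylogeny`."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickError(f"malformed Newick: {exc}") from None
    try:
        return Phylogeny(_tree=tree)
    except TreeValidationError as exc:
        raise NewickError(str(exc)) from None


def write_newick(tree: Phylogeny) -> str:
    return tree.dendropy_tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".10g",
    ).strip() + "\n"


def read_newick_file(path) -> Phylogeny:
    with open(path) as fh:
        return parse_newick(fh.read())


def write_newick_file(tree: Phylogeny, path) -> None:
    with open(path, "w") as fh:
        fh.write(write_newick(tree))


# ---------------------------------------------------------------------------
# Tree preparation
# ---------------------------------------------------------------------------


def resolve_polytomies(tree: Phylogeny, seed: int) -> Phylogeny:
    """Randomly resolve multifurcations into bifurcations with 0-length edges.

    Child groupings are drawn from a random stream seeded by ``seed``; the
    inserted edges have length 0, so every tip depth — and hence the
    shared-ancestry matrix — is unchanged.  A binary tree is returned as an
    identical copy.
    """
    out = tree.copy()
    out.dendropy_tree.resolve_polytomies(rng=random.Random(seed))
    for node in out.dendropy_tree.preorder_node_iter():
        if node.parent_node is not None and node.edge.length is None:
            node.edge.length = 0.0
    out.validate()
    return out


def read_node_ages(path) -> dict[str, float]:
    """Two-column CSV (node_label, age_myr) -> age table."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("node-age table needs columns (node_label, age_myr)")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(float)))


def smooth_branch_lengths(tree: Phylogeny, ages: dict[str, float]) -> Phylogeny:
    """Assign branch lengths from fixed node ages, interpolating undated nodes.

    Fixed nodes (the root, tips at age 0, and any internal node whose label
    appears in ``ages``) keep their ages; every chain of undated nodes between
    a dated ancestor and its nearest dated descendant is spaced evenly in age
    between the two.  This mirrors the age-interpolation smoothing used to
    time-calibrate supertree topologies.  The result is ultrametric with depth
    equal to the root age.
    """
    out = tree.copy()
    dt = out.dendropy_tree
    node_age: dict[dendropy.Node, float] = {}

    root = dt.seed_node
    root_name = _node_name(root)
    if root_name not in ages:
        raise TreeValidationError(
            f"root node {root_name!r} must have a fixed age"
        )
    for node in dt.preorder_node_iter():
        if node.is_leaf():
            node_age[node] = 0.0
        else:
            name = node.label
            if name is not None and name in ages:
                age = float(ages[name])
                if age < 0:
                    raise TreeValidationError(f"negative age for {name!r}")
                node_age[node] = age

    # ordering check: every dated node must be strictly younger than its
    # nearest dated ancestor
    for node, age in node_age.items():
        anc = node.parent_node
        while anc is not None:
            if anc in node_age:
                if age >= node_age[anc]:
                    raise TreeValidationError(
                        f"node {_node_name(node)!r} (age {age}) is not younger "
                        f"than dated ancestor {_node_name(anc)!r} "
                        f"(age {node_age[anc]})"
                    )
                break
            anc = anc.parent_node

    # interpolate: repeatedly take an undated node with a dated parent, find
    # its nearest dated descendant (min edge count; ties -> oldest), and space
    # the chain between the two evenly in age
    def nearest_dated_descendant(start: dendropy.Node):
        frontier = [(start, [start])]
        best = None  # (n_edges, -age, path)
        depth_steps = 0
        while frontier and best is None:
            nxt = []
            for node, path in frontier:
                for child in node.child_nodes():
                    cpath = path + [child]
                    if child in node_age:
                        cand = (depth_steps + 1, -node_age[child], cpath)
                        if best is None or cand[:2] < best[:2]:
                            best = cand
                    else:
                        nxt.append((child, cpath))
            frontier = nxt
            depth_steps += 1
        assert best is not None  # tips are always dated
        return best[2]

    changed = True
    while changed:
        changed = False
        for node in dt.preorder_node_iter():
            if node in node_age or node.parent_node not in node_age:
                continue
            if node.parent_node is None:
                continue
            path = nearest_dated_descendant(node)
            a = node_age[node.parent_node]
            b = node_age[path[-1]]
            chain = path[:-1]  # undated nodes, starting at `node`
            step = (a - b) / (len(chain) + 1)
            for i, u in enumerate(chain, start=1):
                node_age[u] = a - i * step
            changed = True

    for node in dt.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = node_age[node.parent_node] - node_age[node]
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Shared ancestry
# ---------------------------------------------------------------------------


def shared_ancestry(
    tree: Phylogeny, species_order: list[str] | None = None
) -> SharedAncestryMatrix:
    """Compute root-to-MRCA path lengths for every tip pair.

    ``species_order`` fixes the row/column order; default is the tree's own
    tip order.
    """
    dt = tree.dendropy_tree
    depths = tree.node_depths()
    leaves = {leaf.taxon.label: leaf for leaf in dt.leaf_node_iter()}
    if species_order is None:
        species_order = tree.tip_labels
    else:
        missing = set(species_order) - set(leaves)
        if missing:
            raise TreeValidationError(f"species not in tree: {sorted(missing)}")

    # ancestor chains from each tip up to the root
    chains: dict[str, list[dendropy.Node]] = {}
    for label in species_order:
        chain = []
        node = leaves[label]
        while node is not None:
            chain.append(node)
            node = node.parent_node
        chains[label] = chain

    n = len(species_order)
    t = np.zeros((n, n))
    tip_depth = np.array([depths[leaves[s]] for s in species_order])
    anc_sets = {s: set(id(x) for x in chains[s]) for s in species_order}
    for i, si in enumerate(species_order):
        t[i, i] = tip_depth[i]
        for j in range(i + 1, n):
            sj = species_order[j]
            # first node on i's root path that is also an ancestor of j = MRCA
            for node in chains[si]:
                if id(node) in anc_sets[sj]:
                    t[i, j] = t[j, i] = depths[node]
                    break
    return SharedAncestryMatrix(
        species_order=list(species_order), t_shared=t, tip_depth=tip_depth
    )
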