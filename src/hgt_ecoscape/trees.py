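"""Rooted phylogenetic trees with branch lengths and branch supports.

Thin wrapper around :mod:`dendropy` providing the handful of tree queries
the pipeline needs: patristic (path-length) distances between leaves,
minimum branch support along the path between two leaves, and leaf-set
lookups for named clades.  Both "supports as internal node labels" and
"supports as node comments" Newick dialects are accepted.
"""

from __future__ import annotations

import io
from typing import Iterable, Sequence

import dendropy
import numpy as np


class MissingTaxonError(KeyError):
    """A requested leaf name is not present in the tree."""


class PhyloTree:
    """Rooted tree with branch lengths, optional per-node supports.

    Leaf names must be unique.  Supports, where present, are real values in
    [0, 1] attached to internal nodes.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._leaf_by_name: dict[str, dendropy.Node] = {}
        for leaf in tree.leaf_node_iter():
            name = leaf.taxon.label if leaf.taxon is not None else leaf.label
            if name is None:
                raise ValueError("tree contains an unnamed leaf")
            if name in self._leaf_by_name:
                raise ValueError(f"duplicate leaf name {name!r}")
            self._leaf_by_name[name] = leaf
        self._dist_cache: dict[tuple[str, str], float] = {}
        self._depths: dict[int, float] | None = None

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", suppress_internal_node_taxa=True
        )
        _labels_to_supports(tree)
        return cls(tree)

    @classmethod
    def from_file(cls, path) -> "PhyloTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_newick(self) -> str:
        buf = io.StringIO()
        self._tree.write(
            file=buf,
            schema="newick",
            suppress_rooting=True,
            suppress_internal_node_labels=False,
        )
        return buf.getvalue().strip()

    # -- basic queries -----------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def leaf_names(self) -> list[str]:
        return sorted(self._leaf_by_name)

    def __contains__(self, name: str) -> bool:
        return name in self._leaf_by_name

    def _leaf(self, name: str) -> dendropy.Node:
        try:
            return self._leaf_by_name[name]
        except KeyError:
            raise MissingTaxonError(name) from None

    def _node_depths(self) -> dict[int, float]:
        """Distance of every node from the root, cached."""
        if self._depths is None:
            depths: dict[int, float] = {}
            for node in self._tree.preorder_node_iter():
                parent = node.parent_node
                edge = node.edge.length or 0.0
                depths[id(node)] = edge + (depths[id(parent)] if parent else 0.0)
            self._depths = depths
        return self._depths

    def _path_to_root(self, node: dendropy.Node) -> list[dendropy.Node]:
        path = []
        while node is not None:
            path.append(node)
            node = node.parent_node
        return path

    def _mrca(self, a: dendropy.Node, b: dendropy.Node) -> dendropy.Node:
        ancestors_a = {id(n) for n in self._path_to_root(a)}
        node = b
        while node is not None:
            if id(node) in ancestors_a:
                return node
            node = node.parent_node
        raise RuntimeError("disconnected tree")  # pragma: no cover

    def patristic_distance(self, leaf_a: str, leaf_b: str) -> float:
        """Sum of branch lengths on the path between two leaves."""
        if leaf_a == leaf_b:
            self._leaf(leaf_a)
            return 0.0
        key = (leaf_a, leaf_b) if leaf_a < leaf_b else (leaf_b, leaf_a)
        if key not in self._dist_cache:
            na, nb = self._leaf(leaf_a), self._leaf(leaf_b)
            depths = self._node_depths()
            mrca = self._mrca(na, nb)
            d = depths[id(na)] + depths[id(nb)] - 2.0 * depths[id(mrca)]
            self._dist_cache[key] = d
        return self._dist_cache[key]

    def distance_matrix(
        self, names: Sequence[str] | None = None
    ) -> tuple[list[str], np.ndarray]:
        """Dense patristic distance matrix over ``names`` (default: all leaves)."""
        if names is None:
            names = self.leaf_names
        names = list(names)
        n = len(names)
        mat = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                mat[i, j] = mat[j, i] = self.patristic_distance(names[i], names[j])
        return names, mat

    # -- supports ----------------------------------------------------------

    def min_support_on_path(self, leaf_a: str, leaf_b: str) -> float:
        """Minimum branch support over internal nodes on the leaf-to-leaf path.

        Nodes with no support value (including the root) are ignored; if no
        supported node lies on the path the result is 1.0.
        """
        na, nb = self._leaf(leaf_a), self._leaf(leaf_b)
        if na is nb:
            return 1.0
        mrca = self._mrca(na, nb)
        supports = []
        for start in (na, nb):
            node = start.parent_node
            while node is not None and node is not mrca:
                s = _node_support(node)
                if s is not None:
                    supports.append(s)
                node = node.parent_node
        s = _node_support(mrca)
        if s is not None:
            supports.append(s)
        return min(supports) if supports else 1.0

    # -- clades ------------------------------------------------------------

    def find_node(self, label: str) -> dendropy.Node | None:
        """Locate a node by leaf name or internal node label."""
        if label in self._leaf_by_name:
            return self._leaf_by_name[label]
        for node in self._tree.preorder_internal_node_iter():
            if node.label == label:
                return node
        return None

    def leaves_under(self, label: str) -> set[str]:
        """Leaf names descending from the named node (the node itself if a leaf)."""
        node = self.find_node(label)
        if node is None:
            raise MissingTaxonError(label)
        if node.is_leaf():
            return {label}
        return {
            lf.taxon.label if lf.taxon is not None else lf.label
            for lf in node.leaf_iter()
        }


def _node_support(node: dendropy.Node) -> float | None:
    sup = getattr(node, "support", None)
    if sup is not None:
        return float(sup)
    return None


def _labels_to_supports(tree: dendropy.Tree) -> None:
    """Interpret numeric internal-node labels (or comments) as supports."""
    for node in tree.preorder_internal_node_iter():
        value = None
        if node.label is not None:
            try:
                value = float(node.label)
            except ValueError:
                value = None
        if value is None:
            ann = node.annotations.get_value("support", None)
            if ann is not None:
                try:
                    value = float(ann)
                except (TypeError, ValueError):
                    value = None
        if value is None and node.comments:
            for comment in node.comments:
                text = comment.split("=")[-1]
                try:
                    value = float(text)
                    break
                except ValueError:
                    continue
        if value is not None and 0.0 <= value <= 1.0:
            node.support = value


def simulate_yule_tree(
    n_species: int,
    seed: int,
    birth_rate: float = 1.0,
    mean_pairwise_distance: float = 1.0,
    name_prefix: str = "S",
) -> PhyloTree:
    """Simulate a rooted binary tree under a Yule (pure-birth) process.

    Yule topology (a uniformly chosen lineage splits at each step) with
    i.i.d. exponential branch lengths, rescaled so the mean pairwise
    patristic distance equals ``mean_pairwise_distance``.  The exponential
    branch lengths (rather than ultrametric split times) spread the
    pairwise distances over a wide range, which the downstream
    distance-binned analyses rely on.  Deterministic given ``seed``.
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    rng = np.random.default_rng(seed)

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    active = []
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        active.append(child)
    while len(active) < n_species:
        idx = rng.integers(len(active))
        node = active.pop(idx)
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            active.append(child)
    width = len(str(n_species))
    leaf_idx = 0
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        node.edge.length = float(rng.exponential(1.0 / birth_rate))
        if node.is_leaf():
            node.taxon = taxa.new_taxon(f"{name_prefix}{leaf_idx:0{width}d}")
            leaf_idx += 1

    ptree = PhyloTree(tree)
    names, mat = ptree.distance_matrix()
    mean_d = mat[np.triu_indices(len(names), 1)].mean()
    scale = mean_pairwise_distance / mean_d
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale
    return PhyloTree(tree)
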