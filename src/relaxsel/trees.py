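"""Phylogenetic tree handling: Newick I/O with foreground-branch tags and
random tree generation.

Trees are dendropy objects throughout; the branch selected for its own
dN/dS ratio in the two-ratio model ("foreground", by convention the focal
species' terminal branch) is marked with a ``#1`` suffix on the tip label in
Newick, following the codeml convention, and carried internally as a
``foreground`` attribute on the node's subtending edge.

For the numerical routines trees are flattened to index arrays
(:class:`TreeArrays`): postorder traversal, parent pointers, branch lengths
and per-edge foreground flags.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import dendropy
import numpy as np

DEFAULT_FOREGROUND_TAG = "#1"


def random_tree(
    n_taxa: int,
    branch_length_mean: float,
    seed: int,
    taxon_labels: list[str] | None = None,
) -> dendropy.Tree:
    """Generate a random rooted bifurcating tree.

    Topology is built by uniformly joining random pairs of subtrees; every
    edge length is drawn i.i.d. exponential with mean ``branch_length_mean``
    (units: expected substitutions per codon site). The rooted convention
    means an ``n``-tip tree has ``2n - 2`` edges (a 3-tip tree has 4
    branches). Identical ``(n_taxa, branch_length_mean, seed)`` gives a
    byte-identical Newick string.
    """
    if n_taxa < 3:
        raise ValueError(f"n_taxa must be >= 3, got {n_taxa}")
    if branch_length_mean <= 0:
        raise ValueError("branch_length_mean must be positive")
    rng = np.random.default_rng(seed)
    if taxon_labels is None:
        taxon_labels = [f"t{i + 1}" for i in range(n_taxa)]
    elif len(taxon_labels) != n_taxa:
        raise ValueError("taxon_labels length must equal n_taxa")

    taxon_namespace = dendropy.TaxonNamespace(taxon_labels)
    nodes = []
    for label in taxon_labels:
        node = dendropy.Node()
        node.taxon = taxon_namespace.get_taxon(label)
        node.edge.length = float(rng.exponential(branch_length_mean))
        nodes.append(node)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = dendropy.Node()
        parent.add_child(left)
        parent.add_child(right)
        parent.edge.length = float(rng.exponential(branch_length_mean))
        nodes.append(parent)
    root = nodes[0]
    root.edge.length = None
    tree = dendropy.Tree(taxon_namespace=taxon_namespace)
    tree.seed_node = root
    tree.is_rooted = True
    for node in tree:
        node.edge.foreground = False
    return tree


def set_foreground(tree: dendropy.Tree, tip_label: str) -> None:
    """Flag the terminal branch subtending ``tip_label`` as foreground."""
    for node in tree:
        node.edge.foreground = False
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is not None and leaf.taxon.label == tip_label:
            leaf.edge.foreground = True
            return
    raise ValueError(f"tip {tip_label!r} not found in tree")


def foreground_tips(tree: dendropy.Tree) -> list[str]:
    return [
        leaf.taxon.label
        for leaf in tree.leaf_node_iter()
        if getattr(leaf.edge, "foreground", False)
    ]


def parse_newick(newick: str, foreground_tag: str = DEFAULT_FOREGROUND_TAG) -> dendropy.Tree:
    """Parse a Newick string, extracting foreground tags from tip labels.

    A label ``B#1`` marks B's terminal branch as foreground (tag
    configurable); the tag is stripped from the stored taxon label.
    """
    tag_re = re.compile(r"([^\s(),:;]+?)" + re.escape(foreground_tag) + r"(?=[\s(),:;])")
    flagged = tag_re.findall(newick)
    cleaned = tag_re.sub(r"\1", newick)
    tree = dendropy.Tree.get(
        data=cleaned, schema="newick", preserve_underscores=True
    )
    for node in tree:
        node.edge.foreground = False
    for label in flagged:
        set_foreground(tree, label)
    return tree


def write_newick(tree: dendropy.Tree, foreground_tag: str = DEFAULT_FOREGROUND_TAG) -> str:
    """Serialize to Newick, appending the foreground tag to flagged tips."""
    flagged = foreground_tips(tree)
    out = tree.as_string(schema="newick", suppress_rooting=True).strip()
    for label in flagged:
        out = re.sub(
            r"(?<=[(,])" + re.escape(label) + r"(?=[:,)])",
            label + foreground_tag,
            out,
        )
    return out + "\n" if not out.endswith("\n") else out


@dataclass
class TreeArrays:
    """Index-array view of a tree for the likelihood and simulation kernels.

    Nodes are numbered so that tips come first (in ``tip_labels`` order);
    ``postorder`` visits children before parents; ``parent[root] == -1`` and
    the root's ``length`` is 0.
    """

    parent: np.ndarray
    length: np.ndarray
    foreground: np.ndarray
    postorder: np.ndarray
    children: list[list[int]]
    tip_labels: list[str]
    n_nodes: int = field(init=False)
    n_tips: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_nodes = len(self.parent)
        self.n_tips = len(self.tip_labels)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent == -1)[0])


def tree_to_arrays(tree: dendropy.Tree) -> TreeArrays:
    leaves = list(tree.leaf_node_iter())
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    ordered = leaves + internals
    index = {id(n): i for i, n in enumerate(ordered)}
    n = len(ordered)
    parent = np.full(n, -1, dtype=np.int64)
    length = np.zeros(n, dtype=float)
    fg = np.zeros(n, dtype=bool)
    children: list[list[int]] = [[] for _ in range(n)]
    for node in ordered:
        i = index[id(node)]
        if node.parent_node is not None:
            parent[i] = index[id(node.parent_node)]
            children[parent[i]].append(i)
        if node.edge.length is not None and node.parent_node is not None:
            length[i] = float(node.edge.length)
        fg[i] = bool(getattr(node.edge, "foreground", False))
    post = []
    root = int(np.flatnonzero(parent == -1)[0])

    def _post(i: int) -> None:
        for c in children[i]:
            _post(c)
        post.append(i)

    _post(root)
    return TreeArrays(
        parent=parent,
        length=length,
        foreground=fg,
        postorder=np.asarray(post, dtype=np.int64),
        children=children,
        tip_labels=[leaf.taxon.label for leaf in leaves],
    )
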