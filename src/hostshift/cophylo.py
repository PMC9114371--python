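"""Distance trees, Newick round-tripping, and tree-incongruence quantification.

Symbiont and host phylogenies are compared with the Robinson-Foulds (RF)
bipartition distance; trees are built from 1 - identity distance matrices by
canonical neighbor joining. Maximum-likelihood inference is deliberately out
of scope: users with an ML tree supply it as Newick.

All trees are dendropy :class:`~dendropy.Tree` objects. Newick output is
canonicalized (children sorted by their smallest descendant leaf label,
branch lengths at 6 decimals) so serialization is deterministic.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
from dendropy.utility.error import DataParseError

from .alignment_io import StrainHostMap
from .errors import DataValidationError, LabelMismatchError, NewickError
from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Newick I/O

def parse_newick(text: str) -> dendropy.Tree:
    """Parse Newick text into a dendropy tree (underscores preserved)."""
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except DataParseError as exc:
        raise NewickError(f"malformed Newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon]
    if len(labels) != len(set(labels)):
        raise NewickError("duplicate leaf labels in Newick input")
    return tree


def read_newick(path: str | Path) -> dendropy.Tree:
    return parse_newick(Path(path).read_text())


def _min_leaf_label(node: dendropy.Node) -> str:
    return min(
        leaf.taxon.label if leaf.taxon else "" for leaf in node.leaf_iter()
    )


def canonicalize(tree: dendropy.Tree) -> dendropy.Tree:
    """Sort children at every node by smallest descendant leaf label (in place)."""
    for node in tree.postorder_node_iter():
        children = node.child_nodes()
        if len(children) > 1:
            node.set_child_nodes(sorted(children, key=_min_leaf_label))
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path | None = None) -> str:
    """Canonical Newick text (6-decimal branch lengths); optionally written to file."""
    canonicalize(tree)
    text = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".6f",
        unquoted_underscores=True,
    )
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# Tree utilities

def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())


def annotate_times(tree: dendropy.Tree) -> dendropy.Tree:
    """Attach ``node.time`` = distance from root, accumulated over edges."""
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            node.time = 0.0
        else:
            node.time = node.parent_node.time + (node.edge.length or 0.0)
    return tree


def leaf_distance_matrix(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Patristic (path-length) distances between all leaves, labels sorted."""
    annotate_times(tree)
    leaves = sorted(tree.leaf_node_iter(), key=lambda l: l.taxon.label)
    labels = [l.taxon.label for l in leaves]
    n = len(leaves)
    # path distance via times and MRCA depth: d = t_i + t_j - 2 * t_mrca
    ancestors = []
    for leaf in leaves:
        path = {}
        node = leaf
        while node is not None:
            path[id(node)] = node.time
            node = node.parent_node
        ancestors.append(path)
    dist = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            node = leaves[i]
            while id(node) not in ancestors[j]:
                node = node.parent_node
            t_mrca = node.time
            d = leaves[i].time + leaves[j].time - 2.0 * t_mrca
            dist[i, j] = dist[j, i] = d
    return labels, dist


# ---------------------------------------------------------------------------
# Neighbor joining

def nj_tree(ids: Sequence[str], distances: np.ndarray) -> dendropy.Tree:
    """Canonical neighbor-joining tree from a symmetric distance matrix.

    Q-criterion ties are broken by the smallest (i, j) index pair in the
    current agglomeration order (the joined cluster takes the smaller index).
    Negative branch-length estimates are clamped to zero and the total
    clamped deficit logged.
    """
    D = np.asarray(distances, dtype=float)
    n = len(ids)
    if len(set(ids)) != n:
        raise DataValidationError("duplicate ids in distance matrix")
    if D.shape != (n, n):
        raise DataValidationError("distance matrix shape does not match ids")
    if n < 3:
        raise DataValidationError("neighbor joining needs at least 3 taxa")
    if not np.allclose(D, D.T, atol=1e-12):
        raise DataValidationError("distance matrix is not symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-12):
        raise DataValidationError("distance matrix diagonal is not zero")
    if np.isnan(D).any():
        raise DataValidationError("distance matrix contains undefined entries")

    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    nodes: list[dendropy.Node] = []
    for label in ids:
        node = dendropy.Node()
        node.taxon = tns.require_taxon(label)
        nodes.append(node)
    D = D.copy()
    clamped = 0.0

    def _clamp(x: float) -> float:
        nonlocal clamped
        if x < 0.0:
            clamped += -x
            return 0.0
        return x

    m = n
    while m > 3:
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        iu = np.triu_indices(m, k=1)
        Qu = np.full((m, m), np.inf)
        Qu[iu] = Q[iu]
        i, j = np.unravel_index(int(np.argmin(Qu)), Qu.shape)
        d_ij = D[i, j]
        li = _clamp(0.5 * d_ij + (r[i] - r[j]) / (2.0 * (m - 2)))
        lj = _clamp(d_ij - (0.5 * d_ij + (r[i] - r[j]) / (2.0 * (m - 2))))
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        d_new = 0.5 * (D[:, i] + D[:, j] - d_ij)
        D[:, i] = d_new
        D[i, :] = d_new
        D[i, i] = 0.0
        keep = [k for k in range(m) if k != j]
        D = D[np.ix_(keep, keep)]
        nodes[i] = parent
        del nodes[j]
        m -= 1

    # closed-form star resolution for the last three clusters
    d_ab, d_ac, d_bc = D[0, 1], D[0, 2], D[1, 2]
    lengths = [
        _clamp(0.5 * (d_ab + d_ac - d_bc)),
        _clamp(0.5 * (d_ab + d_bc - d_ac)),
        _clamp(0.5 * (d_ac + d_bc - d_ab)),
    ]
    for node, length in zip(nodes, lengths):
        tree.seed_node.add_child(node)
        node.edge.length = length
    if clamped > 0.0:
        logger.info("NJ clamped negative branch lengths (total deficit %.3g)", clamped)
    tree.is_rooted = False
    return tree


def nj_tree_from_similarity(matrix: SimilarityMatrix) -> dendropy.Tree:
    """NJ tree on 1 - identity distances from a similarity matrix."""
    return nj_tree(matrix.ids, 1.0 - matrix.values)


# ---------------------------------------------------------------------------
# Robinson-Foulds

def _nontrivial_bipartitions(tree: dendropy.Tree, ref: str, all_leaves: frozenset[str]):
    splits = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if ref in side:
            side = all_leaves - side
        if 2 <= len(side) <= len(all_leaves) - 2:
            splits.add(side)
    return splits


def robinson_foulds(
    t1: dendropy.Tree, t2: dendropy.Tree
) -> tuple[int, float]:
    """Unrooted RF distance and its normalization by 2(n-3).

    Counts the symmetric difference of non-trivial bipartitions; trees are
    treated as unrooted regardless of their rooting state. Normalized RF is
    defined as 0 for n <= 3 leaves.
    """
    leaves1 = frozenset(l.taxon.label for l in t1.leaf_node_iter())
    leaves2 = frozenset(l.taxon.label for l in t2.leaf_node_iter())
    if leaves1 != leaves2:
        raise LabelMismatchError(
            f"leaf sets differ: only-in-first={sorted(leaves1 - leaves2)}, "
            f"only-in-second={sorted(leaves2 - leaves1)}"
        )
    n = len(leaves1)
    ref = min(leaves1)
    s1 = _nontrivial_bipartitions(t1, ref, leaves1)
    s2 = _nontrivial_bipartitions(t2, ref, leaves1)
    rf = len(s1 ^ s2)
    normalized = rf / (2.0 * (n - 3)) if n >= 4 else 0.0
    return rf, normalized


def relabel_leaves(tree: dendropy.Tree, mapping: dict[str, str]) -> dendropy.Tree:
    """Copy of a tree with leaf labels translated through ``mapping``."""
    copy = parse_newick(tree.as_string(schema="newick", suppress_rooting=True,
                                       unquoted_underscores=True))
    for leaf in copy.leaf_node_iter():
        old = leaf.taxon.label
        if old not in mapping:
            raise LabelMismatchError(f"no mapping for leaf {old!r}")
        leaf.taxon.label = mapping[old]
    labels = [l.taxon.label for l in copy.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise LabelMismatchError("mapping collapses distinct leaves to one label")
    return copy


def symbiont_vs_host_rf(
    symb_tree: dendropy.Tree,
    host_tree: dendropy.Tree,
    strain_map: StrainHostMap,
) -> tuple[int, float]:
    """RF between a symbiont tree (strain leaves) and its host tree.

    Strain leaves are translated to host species through the strain-host map;
    the host tree must carry exactly the mapped species as leaves.
    """
    mapping = {s: strain_map.host_of(s) for s in strain_map.strains}
    translated = relabel_leaves(symb_tree, mapping)
    return robinson_foulds(translated, host_tree)
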