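import numpy as np
import pytest
import dendropy

from hostshift.alignment_io import GeneAlignment


@pytest.fixture
def toy_genes():
    """Two complete genes plus one missing a strain."""
    g1 = GeneAlignment("g1", {"x": "AC", "y": "AG", "z": "AC"})
    g2 = GeneAlignment("g2", {"x": "TT", "y": "TA", "z": "TT"})
    g3 = GeneAlignment("g3", {"x": "GG", "z": "GG"})
    return [g1, g2, g3]


def random_binary_tree(n_leaves: int, rng: np.random.Generator) -> dendropy.Tree:
    """Random binary tree with positive branch lengths (labels T1..Tn)."""
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    roots = []
    for i in range(n_leaves):
        node = dendropy.Node()
        node.taxon = tns.require_taxon(f"T{i + 1}")
        node.edge.length = float(rng.uniform(0.05, 1.0))
        roots.append(node)
    while len(roots) > 2:
        i, j = sorted(rng.choice(len(roots), size=2, replace=False))
        parent = dendropy.Node()
        parent.add_child(roots[i])
        parent.add_child(roots[j])
        parent.edge.length = float(rng.uniform(0.05, 1.0))
        roots[i] = parent
        del roots[j]
    for node in roots:
        tree.seed_node.add_child(node)
    tree.is_rooted = False
    return tree


def random_alignment(rng: np.random.Generator, n_seqs: int, n_cols: int) -> dict:
    """Random gapped DNA alignment as an id -> string mapping."""
    alphabet = np.array(list("ACGTN-"))
    return {
        f"s{i}": "".join(rng.choice(alphabet, size=n_cols))
        for i in range(n_seqs)
    }
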