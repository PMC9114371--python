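"""Host-symbiont coevolution simulator with ground-truth host-shift events.

The generator produces everything the detection pipeline consumes, with known
truth: a Yule (pure-birth) host phylogeny normalized to height 1, a symbiont
tree that starts as an exact copy (strict codivergence) and is perturbed by
host-shift events, and per-gene DNA alignments evolved under Jukes-Cantor
without indels (so the true alignment is positional identity).

A host-shift event at time t transfers the donor host lineage's symbiont to
the recipient host lineage: in the symbiont tree the recipient's subtree is
cut at t and regrafted onto the donor's lineage at t, replacing the
recipient's prior symbiont ancestry. Symbiont substitution rate is
``clock_ratio_c`` times the host rate, the proportional molecular clock the
detection method assumes.

Default parameters emulate the study conditions: ~50 single-copy genes per
strain with occasional dropout (mean recovered ~49), host substitution depth
placing distant host pairs near ~50% identity, and a symbiont clock slow
enough that codiverging symbiont pairs stay below the host-shift call
threshold at every host depth.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np

from .alignment_io import (
    GeneAlignment,
    StrainHostMap,
    write_fasta,
    write_strain_host_map,
)
from .cophylo import annotate_times, write_newick
from .errors import DataValidationError
from .similarity import jc_expected_identity

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Parameters of one synthetic dataset.

    Rates are per unit host-tree height (the host tree is normalized to
    height 1). ``hs_rate_lambda`` is host-shift events per unit of (initial)
    symbiont tree length; the symbiont substitution rate is
    ``clock_ratio_c * host_subst_rate``.
    """

    n_hosts: int = 10
    birth_rate: float = 1.0
    hs_rate_lambda: float = 0.5
    n_genes: int = 50
    gene_length: int = 900
    host_subst_rate: float = 0.45
    clock_ratio_c: float = 0.5
    gene_dropout: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hosts < 3:
            raise DataValidationError("n_hosts must be >= 3")
        if self.n_genes < 1 or self.gene_length < 1:
            raise DataValidationError("n_genes and gene_length must be positive")
        for name in ("birth_rate", "hs_rate_lambda", "host_subst_rate",
                     "clock_ratio_c", "gene_dropout"):
            if getattr(self, name) < 0:
                raise DataValidationError(f"{name} must be non-negative")
        if self.birth_rate == 0:
            raise DataValidationError("birth_rate must be positive")

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2) + "\n")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class Event:
    """One host-shift event: the recipient host adopts the donor's symbiont."""

    time: float
    donor_host: str
    recipient_host: str


def _strain_label(host_label: str) -> str:
    if host_label.startswith("H"):
        return "S" + host_label[1:]
    return "S_" + host_label


def simulate_host_tree(
    n_hosts: int,
    birth_rate: float,
    seed,
    normalize: bool = True,
) -> dendropy.Tree:
    """Ultrametric Yule tree with leaves H1..Hn, root split at time 0.

    Waiting times between splits are exponential with rate k*birth_rate for k
    extant lineages; after the n-th lineage appears one further waiting time
    is drawn and the tips placed there. With ``normalize`` the height is
    rescaled to 1.
    """
    if n_hosts < 3:
        raise DataValidationError("n_hosts must be >= 3")
    if birth_rate <= 0:
        raise DataValidationError("birth_rate must be positive")
    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node
    root.time = 0.0
    active = [root.new_child(), root.new_child()]
    t = 0.0
    while len(active) < n_hosts:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        idx = int(rng.integers(k))
        node = active[idx]
        node.time = t
        active[idx] = node.new_child()
        active.append(node.new_child())
    height = t + rng.exponential(1.0 / (len(active) * birth_rate))
    for i, leaf in enumerate(active):
        leaf.time = height
        leaf.taxon = tns.require_taxon(f"H{i + 1}")
    if normalize:
        for node in tree.preorder_node_iter():
            node.time /= height
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = node.time - node.parent_node.time
    tree.is_rooted = True
    return tree


def _copy_as_symbiont(host_tree: dendropy.Tree) -> dendropy.Tree:
    """Structural copy with host leaf labels translated to strain labels."""
    annotate_times(host_tree)
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)

    def _copy(src: dendropy.Node, dst: dendropy.Node) -> None:
        dst.time = src.time
        for child in src.child_nodes():
            new = dst.new_child()
            _copy(child, new)
        if src.is_leaf():
            dst.taxon = tns.require_taxon(_strain_label(src.taxon.label))

    _copy(host_tree.seed_node, tree.seed_node)
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = node.time - node.parent_node.time
    tree.is_rooted = True
    return tree


def _host_edges(host_tree: dendropy.Tree):
    """(child_node, parent_time, child_time, representative_leaf) per edge."""
    annotate_times(host_tree)
    edges = []
    for node in host_tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        rep = min(l.taxon.label for l in node.leaf_iter())
        edges.append((node, node.parent_node.time, node.time, rep))
    return edges


def _lineage_edge_child(leaf: dendropy.Node, t: float) -> dendropy.Node:
    """Child node of the edge spanning time t on the path root -> leaf."""
    c = leaf
    while c.parent_node is not None and c.parent_node.time > t:
        c = c.parent_node
    return c


def simulate_cophylogeny(
    host_tree: dendropy.Tree,
    hs_rate_lambda: float,
    seed,
    forced_events: Sequence[Event] | None = None,
) -> tuple[dendropy.Tree, list[Event]]:
    """Symbiont tree under codivergence plus Poisson host-shift events.

    Random events arrive as a Poisson process with rate ``hs_rate_lambda``
    per unit branch length over the host tree (the initial symbiont tree);
    each event point selects its edge proportionally to length, and the donor
    is drawn uniformly among the other host lineages extant at that time.
    ``forced_events`` (host leaf labels) are merged in, enabling ground-truth
    scenarios. With rate 0 and no forced events the symbiont tree is an exact
    copy of the host tree.
    """
    annotate_times(host_tree)
    height = max(l.time for l in host_tree.leaf_node_iter())
    rng = np.random.default_rng(seed)
    edges = _host_edges(host_tree)
    total_length = sum(ct - pt for _, pt, ct, _ in edges)

    events: list[Event] = []
    if hs_rate_lambda > 0 and total_length > 0:
        n_events = int(rng.poisson(hs_rate_lambda * total_length))
        cum = np.cumsum([ct - pt for _, pt, ct, _ in edges])
        for _ in range(n_events):
            u = rng.uniform(0.0, total_length)
            k = int(np.searchsorted(cum, u, side="right"))
            node, pt, ct, rep = edges[k]
            t = ct - (cum[k] - u)
            donors = sorted(
                r for nd, p, c, r in edges
                if p < t < c and nd is not node
            )
            if not donors:
                continue
            donor = donors[int(rng.integers(len(donors)))]
            events.append(Event(time=float(t), donor_host=donor, recipient_host=rep))
    if forced_events:
        for ev in forced_events:
            if ev.donor_host == ev.recipient_host:
                raise DataValidationError("event donor and recipient must differ")
            if not (0.0 < ev.time < height):
                raise DataValidationError(
                    f"event time {ev.time} outside (0, {height})"
                )
            events.append(ev)
    events.sort(key=lambda e: (e.time, e.donor_host, e.recipient_host))

    symb = _copy_as_symbiont(host_tree)
    leaf_by_label = {l.taxon.label: l for l in symb.leaf_node_iter()}
    for ev in events:
        d_leaf = leaf_by_label.get(_strain_label(ev.donor_host))
        r_leaf = leaf_by_label.get(_strain_label(ev.recipient_host))
        if d_leaf is None or r_leaf is None:
            raise DataValidationError(
                f"event references unknown host: {ev.donor_host}/{ev.recipient_host}"
            )
        c_r = _lineage_edge_child(r_leaf, ev.time)
        c_d = _lineage_edge_child(d_leaf, ev.time)
        if c_r is c_d:
            # donor and recipient symbionts share their lineage at this time
            # with respect to the sampled leaves; the event stays in the log
            # but has no genealogical effect
            logger.info("host-shift at t=%.4f is a genealogical no-op", ev.time)
            continue
        parent = c_r.parent_node
        parent.remove_child(c_r)
        # prune ancestors left childless (possible when sibling lineages were
        # detached by earlier events) so no phantom leaves remain
        while parent.parent_node is not None and not parent.child_nodes():
            grand = parent.parent_node
            grand.remove_child(parent)
            parent = grand
        c_d = _lineage_edge_child(d_leaf, ev.time)
        p_d = c_d.parent_node
        graft = dendropy.Node()
        graft.time = ev.time
        p_d.remove_child(c_d)
        p_d.add_child(graft)
        graft.add_child(c_d)
        graft.add_child(c_r)
    for node in symb.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = node.time - node.parent_node.time
    symb.is_rooted = True
    return symb, events


def evolve_sequences(
    tree: dendropy.Tree,
    n_genes: int,
    gene_length: int,
    subst_rate: float,
    seed,
    gene_prefix: str = "gene",
) -> list[GeneAlignment]:
    """Independent Jukes-Cantor genes evolved along a tree (no indels).

    The root sequence is uniform over {A,C,G,T}; per branch, each site stays
    identical with probability 1/4 + (3/4)exp(-4*rate*length/3) and otherwise
    changes to one of the other three bases uniformly.
    """
    if n_genes < 1 or gene_length < 1:
        raise DataValidationError("n_genes and gene_length must be positive")
    if subst_rate < 0:
        raise DataValidationError("subst_rate must be non-negative")
    rng = np.random.default_rng(seed)
    nodes = list(tree.preorder_node_iter())
    p_same = {
        id(nd): jc_expected_identity(subst_rate * (nd.edge.length or 0.0))
        for nd in nodes
        if nd.parent_node is not None
    }
    genes: list[GeneAlignment] = []
    for g in range(n_genes):
        seqs: dict[int, np.ndarray] = {}
        for nd in nodes:
            if nd.parent_node is None:
                seqs[id(nd)] = rng.integers(0, 4, gene_length, dtype=np.int8)
                continue
            parent_seq = seqs[id(nd.parent_node)]
            seq = parent_seq.copy()
            changed = rng.random(gene_length) >= p_same[id(nd)]
            n_changed = int(changed.sum())
            if n_changed:
                seq[changed] = (
                    seq[changed] + rng.integers(1, 4, n_changed, dtype=np.int8)
                ) % 4
            seqs[id(nd)] = seq
        records = {
            leaf.taxon.label: _BASES[seqs[id(leaf)]].tobytes().decode("ascii")
            for leaf in sorted(tree.leaf_node_iter(), key=lambda l: l.taxon.label)
        }
        genes.append(
            GeneAlignment(gene_id=f"{gene_prefix}{g + 1:03d}", records=records)
        )
    return genes


def apply_gene_dropout(
    genes: list[GeneAlignment], dropout: float, seed
) -> list[GeneAlignment]:
    """Remove each (strain, gene) record with probability ``dropout``.

    Emulates incomplete single-copy ortholog recovery. A gene is never left
    empty: if every record of a gene would drop, the gene is kept intact.
    """
    if dropout <= 0:
        return genes
    rng = np.random.default_rng(seed)
    out = []
    for g in genes:
        keep = {rid: bool(rng.random() >= dropout) for rid in g.records}
        if not any(keep.values()):
            out.append(g)
            continue
        out.append(
            GeneAlignment(
                gene_id=g.gene_id,
                records={rid: s for rid, s in g.records.items() if keep[rid]},
            )
        )
    return out


def generate_dataset(
    config: SimulationConfig,
    out_dir: str | Path,
    forced_events: Sequence[Event] | None = None,
    host_tree: dendropy.Tree | None = None,
) -> dict[str, str]:
    """Write a complete labelled dataset; returns a name -> path manifest.

    Outputs: per-gene FASTAs for hosts and symbiont strains, both Newick
    trees, the ground-truth event log, the strain-host map, and a config
    echo. All randomness derives from ``config.seed``, so outputs are
    reproducible bit for bit.
    """
    out_dir = Path(out_dir)
    (out_dir / "host_genes").mkdir(parents=True, exist_ok=True)
    (out_dir / "symbiont_genes").mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    s_tree, s_cophylo, s_host, s_symb, s_drop = ss.spawn(5)

    if host_tree is None:
        host_tree = simulate_host_tree(config.n_hosts, config.birth_rate, s_tree)
    symb_tree, events = simulate_cophylogeny(
        host_tree, config.hs_rate_lambda, s_cophylo, forced_events=forced_events
    )
    host_genes = evolve_sequences(
        host_tree, config.n_genes, config.gene_length, config.host_subst_rate, s_host
    )
    symb_genes = evolve_sequences(
        symb_tree,
        config.n_genes,
        config.gene_length,
        config.clock_ratio_c * config.host_subst_rate,
        s_symb,
    )
    symb_genes = apply_gene_dropout(symb_genes, config.gene_dropout, s_drop)

    manifest: dict[str, str] = {}
    for sub, genes in (("host_genes", host_genes), ("symbiont_genes", symb_genes)):
        for g in genes:
            p = out_dir / sub / f"{g.gene_id}.fasta"
            write_fasta(g.records, p)
            manifest[f"{sub}/{g.gene_id}.fasta"] = str(p)
    write_newick(host_tree, out_dir / "host.nwk")
    manifest["host.nwk"] = str(out_dir / "host.nwk")
    write_newick(symb_tree, out_dir / "symbiont.nwk")
    manifest["symbiont.nwk"] = str(out_dir / "symbiont.nwk")

    with open(out_dir / "events.tsv", "w", newline="\n") as fh:
        fh.write("time\tdonor_host\trecipient_host\n")
        for ev in events:
            fh.write(f"{ev.time:.6f}\t{ev.donor_host}\t{ev.recipient_host}\n")
    manifest["events.tsv"] = str(out_dir / "events.tsv")

    strain_map = StrainHostMap(
        mapping={
            _strain_label(l.taxon.label): (l.taxon.label, l.taxon.label)
            for l in sorted(host_tree.leaf_node_iter(), key=lambda l: l.taxon.label)
        }
    )
    write_strain_host_map(strain_map, out_dir / "strain_host_map.tsv")
    manifest["strain_host_map.tsv"] = str(out_dir / "strain_host_map.tsv")
    config.to_json(out_dir / "config.json")
    manifest["config.json"] = str(out_dir / "config.json")
    return manifest


def forced_shift_scenario(
    seed,
    n_pairs: int = 3,
    n_hosts: int = 10,
    birth_rate: float = 1.0,
    shift_time: float = 0.95,
    max_pair_mrca: float = 0.5,
    max_parent_time: float = 0.75,
    max_tries: int = 500,
) -> tuple[dendropy.Tree, list[Event], list[tuple[str, str]]]:
    """Host tree plus forced recent shifts between mutually distant hosts.

    Searches seeded Yule trees until ``n_pairs`` disjoint donor/recipient
    pairs exist whose MRCA times are at most ``max_pair_mrca`` and whose
    pendant branches start no later than ``max_parent_time``. Under the
    generator's default rates the Jukes-Cantor closed form then guarantees
    host identity below the host-distance threshold for every forced pair
    and symbiont identity below the host-shift call threshold for every
    non-shifted pair. Returns (host tree, forced events, true host pairs).
    """
    rng = np.random.default_rng(seed)
    attempt_seeds = rng.integers(0, 2**31 - 1, size=max_tries)
    for attempt_seed in attempt_seeds:
        tree = simulate_host_tree(n_hosts, birth_rate, int(attempt_seed))
        annotate_times(tree)
        leaves = sorted(tree.leaf_node_iter(), key=lambda l: l.taxon.label)
        candidates = [
            l.taxon.label
            for l in leaves
            if l.parent_node.time <= max_parent_time
        ]
        mrca: dict[tuple[str, str], float] = {}
        by_label = {l.taxon.label: l for l in leaves}
        for i, a in enumerate(candidates):
            for b in candidates[i + 1:]:
                anc_a = set()
                node = by_label[a]
                while node is not None:
                    anc_a.add(id(node))
                    node = node.parent_node
                node = by_label[b]
                while id(node) not in anc_a:
                    node = node.parent_node
                mrca[(a, b)] = node.time
        ok_pairs = sorted(p for p, t in mrca.items() if t <= max_pair_mrca)

        def _match(pairs, used, acc):
            if len(acc) == n_pairs:
                return list(acc)
            for idx, (a, b) in enumerate(pairs):
                if a in used or b in used:
                    continue
                result = _match(pairs[idx + 1:], used | {a, b}, acc + [(a, b)])
                if result:
                    return result
            return None

        chosen = _match(ok_pairs, set(), [])
        if chosen:
            events = [
                Event(time=shift_time, donor_host=a, recipient_host=b)
                for a, b in chosen
            ]
            return tree, events, chosen
    raise RuntimeError(
        f"no host tree with {n_pairs} suitable shift pairs in {max_tries} tries"
    )
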