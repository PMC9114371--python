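"""Identical-sequence collapsing and divergence-threshold lineage clustering.

Concatenated supermatrices from closely related symbiont strains often
contain byte-identical sequences (resequenced populations of the same host
species); these are collapsed to one representative before phylogenetics.
Remaining strains are grouped into lineages: single-linkage connected
components of the graph whose edges join pairs with divergence
(1 - identity) strictly below a threshold (default 0.0002, i.e. 0.02%).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .alignment_io import ConcatAlignment
from .errors import DataValidationError
from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)

DEFAULT_MAX_DIVERGENCE = 0.0002


@dataclass
class IdenticalGroups:
    """Partition of ids into groups of byte-identical sequences."""

    groups: list[list[str]]
    representative: dict[int, str]

    @property
    def n_before(self) -> int:
        return sum(len(g) for g in self.groups)

    @property
    def n_after(self) -> int:
        return len(self.groups)

    @property
    def representatives(self) -> list[str]:
        return [self.representative[i] for i in range(len(self.groups))]


@dataclass
class LineageClustering:
    """Single-linkage clusters below a divergence threshold."""

    clusters: list[list[str]]
    max_divergence: float
    linkage: str = "single"

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def collapse_identical(concat: ConcatAlignment) -> IdenticalGroups:
    """Group ids whose concatenated sequences are exactly identical.

    The representative of each group is its lexicographically smallest id;
    groups are ordered by representative. Idempotent: re-collapsing the
    representatives yields only singletons.
    """
    by_seq: dict[str, list[str]] = {}
    for rid, seq in concat.records.items():
        by_seq.setdefault(seq, []).append(rid)
    groups = sorted((sorted(members) for members in by_seq.values()),
                    key=lambda g: g[0])
    representative = {i: g[0] for i, g in enumerate(groups)}
    return IdenticalGroups(groups=groups, representative=representative)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def cluster_lineages(
    matrix: SimilarityMatrix, max_divergence: float = DEFAULT_MAX_DIVERGENCE
) -> LineageClustering:
    """Single-linkage components with edges where 1 - similarity < threshold.

    Undefined similarities are treated as above-threshold (no edge) and
    logged. Clusters are sorted by their smallest member id.
    """
    if not (0.0 < max_divergence < 1.0):
        raise DataValidationError("max_divergence must lie in (0, 1)")
    ids = matrix.ids
    n = len(ids)
    uf = _UnionFind(n)
    n_undefined = 0
    for i in range(n):
        for j in range(i + 1, n):
            v = matrix.values[i, j]
            if np.isnan(v):
                n_undefined += 1
                continue
            if (1.0 - v) < max_divergence:
                uf.union(i, j)
    if n_undefined:
        logger.warning(
            "%d undefined similarities treated as above-threshold", n_undefined
        )
    members: dict[int, list[str]] = {}
    for i in range(n):
        members.setdefault(uf.find(i), []).append(ids[i])
    clusters = sorted((sorted(m) for m in members.values()), key=lambda c: c[0])
    return LineageClustering(clusters=clusters, max_divergence=max_divergence)


def select_representatives(
    clustering: LineageClustering, seed: int
) -> dict[int, str]:
    """Seeded uniform draw of one representative per cluster.

    The same seed always yields the same selection; clusters are visited in
    index order and members drawn from their sorted listing.
    """
    rng = np.random.default_rng(seed)
    out: dict[int, str] = {}
    for idx, cluster in enumerate(clustering.clusters):
        members = sorted(cluster)
        out[idx] = members[int(rng.integers(len(members)))]
    return out


def write_clusters_tsv(
    clusters: list[list[str]], representatives: dict[int, str], path: str | Path
) -> Path:
    path = Path(path)
    with open(path, "w", newline="\n") as fh:
        fh.write("cluster_index\tmember_id\tis_representative\n")
        for idx, cluster in enumerate(clusters):
            for member in cluster:
                flag = 1 if representatives.get(idx) == member else 0
                fh.write(f"{idx}\t{member}\t{flag}\n")
    return path
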