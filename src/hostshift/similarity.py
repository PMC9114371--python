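"""Pairwise sequence identity under explicit gap conventions, plus summaries.

Identity between two aligned sequences is the fraction of columns carrying
identical characters. Three gap conventions are supported:

``all``
    every column counts; a gap-gap column is a match and an N-N column is a
    match (pure character equality). This is the default and mirrors a
    keep-gaps similarity matrix.
``exclude_either``
    columns gapped in either sequence are dropped before counting.
``exclude_both``
    only columns gapped in both sequences are dropped.

Identities are stored as fractions in [0, 1]; rendering as percentages is a
reporting concern. An identity whose denominator is zero is undefined and
represented as NaN.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment_io import GeneAlignment
from .errors import AlignmentShapeError, DataValidationError, EmptyInputError

logger = logging.getLogger(__name__)

GAP_MODES = ("all", "exclude_either", "exclude_both")

_GAP = ord("-")


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def pairwise_identity(a: str, b: str, gap_mode: str = "all") -> float:
    """Fraction of identical columns between two equal-length aligned strings.

    Returns NaN when the chosen gap mode leaves no columns to compare.
    """
    if len(a) != len(b):
        raise AlignmentShapeError(f"length mismatch: {len(a)} vs {len(b)}")
    if len(a) == 0:
        raise EmptyInputError("empty sequences")
    if gap_mode not in GAP_MODES:
        raise DataValidationError(f"unknown gap_mode {gap_mode!r}")
    x, y = _encode(a), _encode(b)
    if gap_mode == "all":
        keep = np.ones(len(x), dtype=bool)
    elif gap_mode == "exclude_either":
        keep = (x != _GAP) & (y != _GAP)
    else:
        keep = ~((x == _GAP) & (y == _GAP))
    denom = int(keep.sum())
    if denom == 0:
        return math.nan
    return float((x[keep] == y[keep]).sum() / denom)


@dataclass
class SimilarityMatrix:
    """Symmetric matrix of pairwise identities (NaN = undefined)."""

    ids: list[str]
    values: np.ndarray
    gap_mode: str

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise DataValidationError("similarity matrix shape does not match ids")
        if len(set(self.ids)) != n:
            raise DataValidationError("duplicate ids in similarity matrix")

    def value(self, id_a: str, id_b: str) -> float:
        i, j = self.ids.index(id_a), self.ids.index(id_b)
        return float(self.values[i, j])

    def submatrix(self, ids: Sequence[str]) -> "SimilarityMatrix":
        idx = [self.ids.index(i) for i in ids]
        return SimilarityMatrix(
            ids=list(ids), values=self.values[np.ix_(idx, idx)], gap_mode=self.gap_mode
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_dataframe().to_csv(path, float_format="%.6f", na_rep="NA")
        return path

    @classmethod
    def from_csv(cls, path: str | Path, gap_mode: str = "all") -> "SimilarityMatrix":
        df = pd.read_csv(path, index_col=0, na_values=["NA"])
        return cls(ids=[str(c) for c in df.columns], values=df.to_numpy(dtype=float),
                   gap_mode=gap_mode)


def similarity_matrix(
    records: Mapping[str, str], gap_mode: str = "all"
) -> SimilarityMatrix:
    """All-pairs identity matrix over a mapping id -> aligned string.

    Input record order is preserved; each unordered pair is computed once.
    """
    ids = list(records)
    if len(ids) < 2:
        raise EmptyInputError("similarity matrix needs at least 2 records")
    lengths = {len(s) for s in records.values()}
    if len(lengths) != 1:
        raise AlignmentShapeError("records have unequal lengths")
    n = len(ids)
    values = np.ones((n, n), dtype=float)
    if gap_mode != "all":
        values[np.diag_indices(n)] = [
            pairwise_identity(records[i], records[i], gap_mode) for i in ids
        ]
    for i in range(n):
        for j in range(i + 1, n):
            v = pairwise_identity(records[ids[i]], records[ids[j]], gap_mode)
            values[i, j] = values[j, i] = v
    return SimilarityMatrix(ids=ids, values=values, gap_mode=gap_mode)


@dataclass
class GenePairSimilarity:
    """Per-gene identity vector for one pair of sequence ids."""

    id_a: str
    id_b: str
    gene_ids: list[str]
    values: np.ndarray
    n_skipped: int


def per_gene_pair_similarity(
    genes: Iterable[GeneAlignment], id_a: str, id_b: str, gap_mode: str = "all"
) -> GenePairSimilarity:
    """Identity between two ids in every gene where both are present.

    Genes missing either id, or where the identity is undefined under the gap
    mode, are skipped and counted in ``n_skipped``. Gene order is
    lexicographic by gene id.
    """
    if id_a == id_b:
        raise DataValidationError("per-gene similarity needs two distinct ids")
    genes = sorted(genes, key=lambda g: g.gene_id)
    used_genes: list[str] = []
    vals: list[float] = []
    n_skipped = 0
    for g in genes:
        if id_a not in g.records or id_b not in g.records:
            n_skipped += 1
            continue
        v = pairwise_identity(g.records[id_a], g.records[id_b], gap_mode)
        if math.isnan(v):
            n_skipped += 1
            continue
        used_genes.append(g.gene_id)
        vals.append(v)
    if not vals:
        raise EmptyInputError(
            f"no gene contains both {id_a!r} and {id_b!r} with a defined identity"
        )
    return GenePairSimilarity(
        id_a=id_a,
        id_b=id_b,
        gene_ids=used_genes,
        values=np.asarray(vals, dtype=float),
        n_skipped=n_skipped,
    )


@dataclass
class SummaryStats:
    """Descriptive statistics of a per-gene identity vector.

    ``std`` is the sample (n-1) standard deviation, NaN for n=1; quantiles use
    linear interpolation between order statistics.
    """

    n_genes: int
    mean: float
    std: float
    min: float
    q25: float
    q50: float
    q75: float
    max: float

    def as_row(self) -> dict[str, float]:
        return {
            "n_genes": self.n_genes,
            "mean": self.mean,
            "std": self.std,
            "min": self.min,
            "q25": self.q25,
            "q50": self.q50,
            "q75": self.q75,
            "max": self.max,
        }


def describe(values: Sequence[float] | np.ndarray) -> SummaryStats:
    """Pandas-style describe() of an identity vector."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise EmptyInputError("describe of an empty vector")
    d = pd.Series(arr).describe()
    return SummaryStats(
        n_genes=int(d["count"]),
        mean=float(d["mean"]),
        std=float(d["std"]),
        min=float(d["min"]),
        q25=float(d["25%"]),
        q50=float(d["50%"]),
        q75=float(d["75%"]),
        max=float(d["max"]),
    )


@dataclass
class CrossGroupStats:
    """Statistics of the cross-similarity block between two id groups.

    ``row_max_*`` are statistics over per-row maxima: for each member of group
    A, its best match in group B. The mode is taken after rounding to two
    decimal places in percent, ties broken by the smallest value.
    """

    overall_mean: float
    overall_min: float
    overall_max: float
    row_max_mean: float
    row_max_mode: float


def cross_group_stats(
    matrix: SimilarityMatrix, group_a: Iterable[str], group_b: Iterable[str]
) -> CrossGroupStats:
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise EmptyInputError("both groups must be non-empty")
    if set(group_a) & set(group_b):
        raise DataValidationError("groups overlap")
    missing = (set(group_a) | set(group_b)) - set(matrix.ids)
    if missing:
        raise DataValidationError(f"ids not in matrix: {sorted(missing)}")
    ia = [matrix.ids.index(i) for i in group_a]
    ib = [matrix.ids.index(i) for i in group_b]
    block = matrix.values[np.ix_(ia, ib)]
    if np.isnan(block).any():
        logger.warning("cross-group block contains undefined entries; ignored")
    row_max = np.nanmax(block, axis=1)
    rounded = np.round(row_max * 100.0, 2)
    counts = Counter(rounded.tolist())
    best = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))
    return CrossGroupStats(
        overall_mean=float(np.nanmean(block)),
        overall_min=float(np.nanmin(block)),
        overall_max=float(np.nanmax(block)),
        row_max_mean=float(np.mean(row_max)),
        row_max_mode=float(best[0] / 100.0),
    )


def jc_expected_identity(d: float) -> float:
    """Expected fraction of identical sites at Jukes-Cantor distance ``d``."""
    return 0.25 + 0.75 * math.exp(-4.0 * d / 3.0)


def jc_distance(identity: float) -> float:
    """Jukes-Cantor distance from an observed identity fraction.

    Returns NaN when the observed difference proportion reaches the JC
    saturation bound of 3/4.
    """
    p = 1.0 - identity
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)
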