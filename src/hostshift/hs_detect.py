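"""Host-shift classification from contrasted symbiont and host similarities.

The inference: under strict vertical transmission (codivergence) and a
proportional molecular clock, symbiont divergence scales with host
divergence. A symbiont pair far more similar than its host pair — symbiont
mean identity at or above ``symb_min_similarity`` while the hosts sit at or
below ``host_max_similarity`` — is evidence of a host shift, since no
vertical route can explain near-identical symbionts in long-diverged hosts.
Host pairs above ``host_max_similarity`` are labelled ``uninformative``:
recent vertical transmission or introgression cannot be excluded there.

Classification is a pure function of the two per-gene mean identities and
the thresholds; per-gene vectors and bootstrap confidence intervals are
reported alongside but never change the label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .alignment_io import GeneAlignment, StrainHostMap
from .errors import CalibrationError, DataValidationError, EmptyInputError
from .similarity import SummaryStats, describe, per_gene_pair_similarity

logger = logging.getLogger(__name__)

HOST_SHIFT = "host_shift"
CODIVERGENCE = "codivergence"
UNINFORMATIVE = "uninformative"


@dataclass
class ThresholdConfig:
    """Decision thresholds, both fractions in (0, 1)."""

    symb_min_similarity: float = 0.93
    host_max_similarity: float = 0.80

    def __post_init__(self) -> None:
        for name in ("symb_min_similarity", "host_max_similarity"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise DataValidationError(f"{name} must lie in (0, 1)")


@dataclass
class ClockModel:
    """Proportional clock: symbiont divergence per unit host divergence."""

    ratio_c: float

    def __post_init__(self) -> None:
        if self.ratio_c <= 0:
            raise DataValidationError("ratio_c must be positive")


@dataclass
class PairSummary:
    """Per-gene similarity evidence for one symbiont pair and its host pair."""

    symb_pair: tuple[str, str]
    host_pair: tuple[str, str]
    symb_stats: SummaryStats
    host_stats: SummaryStats
    symb_values: np.ndarray | None = None
    host_values: np.ndarray | None = None


@dataclass
class HSCall:
    """Classification of one pair with its evidence summaries."""

    symb_pair: tuple[str, str]
    host_pair: tuple[str, str]
    symb_stats: SummaryStats
    host_stats: SummaryStats
    label: str
    thresholds: ThresholdConfig
    expected_symb_similarity: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")


def classify_pair(
    symb_stats: SummaryStats,
    host_stats: SummaryStats,
    thresholds: ThresholdConfig | None = None,
) -> str:
    """Label one pair as host_shift, codivergence, or uninformative.

    Hosts more similar than ``host_max_similarity`` cannot discriminate
    transmission routes (uninformative); otherwise a symbiont mean at or
    above ``symb_min_similarity`` is a host shift, anything lower is
    consistent with codivergence.
    """
    thresholds = thresholds or ThresholdConfig()
    if host_stats.mean > thresholds.host_max_similarity:
        return UNINFORMATIVE
    if symb_stats.mean >= thresholds.symb_min_similarity:
        return HOST_SHIFT
    return CODIVERGENCE


def calibrate_clock_ratio(
    reference_pairs: Sequence[tuple[float, float]]
) -> ClockModel:
    """Median symbiont/host divergence ratio over reference codiverging pairs.

    Pairs with zero host divergence carry no rate information and are
    skipped; if none remain, calibration is impossible.
    """
    ratios = [s / h for h, s in reference_pairs if h > 0]
    if not ratios:
        raise CalibrationError("all reference host divergences are zero")
    return ClockModel(ratio_c=float(np.median(ratios)))


def expected_symb_similarity(host_divergence: float, clock: ClockModel) -> float:
    """Codivergence expectation: 1 - c * host_divergence, floored at 0."""
    if not (0.0 <= host_divergence <= 1.0):
        raise DataValidationError("host_divergence must lie in [0, 1]")
    return max(0.0, 1.0 - clock.ratio_c * host_divergence)


def bootstrap_mean_ci(
    values: Sequence[float] | np.ndarray,
    n_boot: int,
    seed,
    level: float = 0.95,
) -> tuple[float, float]:
    """Seeded percentile bootstrap interval for the mean of a vector."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise EmptyInputError("bootstrap of an empty vector")
    if n_boot < 100:
        raise DataValidationError("n_boot must be at least 100")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, arr.size, size=(n_boot, arr.size))
    means = arr[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    low, high = np.quantile(means, [alpha, 1.0 - alpha])
    return float(low), float(high)


def summarize_pairs(
    symb_genes: Iterable[GeneAlignment],
    host_genes: Iterable[GeneAlignment],
    strain_map: StrainHostMap,
    gap_mode: str = "all",
    strains: Sequence[str] | None = None,
) -> list[PairSummary]:
    """Per-gene similarity summaries for every strain pair with distinct hosts.

    Symbiont identities are computed between strain ids in the symbiont gene
    alignments, host identities between the mapped host species in the host
    gene alignments. Pairs of strains infecting the same host species are
    skipped (no host contrast exists).
    """
    symb_genes = list(symb_genes)
    host_genes = list(host_genes)
    strains = list(strains) if strains is not None else strain_map.strains
    out: list[PairSummary] = []
    for sa, sb in combinations(strains, 2):
        ha, hb = strain_map.host_of(sa), strain_map.host_of(sb)
        if ha == hb:
            continue
        symb = per_gene_pair_similarity(symb_genes, sa, sb, gap_mode)
        host = per_gene_pair_similarity(host_genes, ha, hb, gap_mode)
        out.append(
            PairSummary(
                symb_pair=(sa, sb),
                host_pair=(ha, hb),
                symb_stats=describe(symb.values),
                host_stats=describe(host.values),
                symb_values=symb.values,
                host_values=host.values,
            )
        )
    if not out:
        raise EmptyInputError("no strain pair with distinct host species")
    return out


def detect_all(
    per_pair: Sequence[PairSummary],
    thresholds: ThresholdConfig | None = None,
    clock: ClockModel | None = None,
    n_boot: int = 0,
    seed: int = 0,
) -> tuple[list[HSCall], float]:
    """Classify every pair; returns (calls, hs_host_fraction in percent).

    ``hs_host_fraction`` is the share of distinct host species appearing in
    at least one host_shift call, in percent rounded to one decimal. With
    ``n_boot`` > 0, a bootstrap CI of the symbiont mean accompanies each call.
    """
    if not per_pair:
        raise EmptyInputError("no pairs to classify")
    thresholds = thresholds or ThresholdConfig()
    calls: list[HSCall] = []
    rng = np.random.default_rng(seed)
    for ps in per_pair:
        label = classify_pair(ps.symb_stats, ps.host_stats, thresholds)
        expected = float("nan")
        if clock is not None:
            expected = expected_symb_similarity(1.0 - ps.host_stats.mean, clock)
        ci_low = ci_high = float("nan")
        if n_boot > 0 and ps.symb_values is not None:
            ci_low, ci_high = bootstrap_mean_ci(
                ps.symb_values, n_boot, rng.integers(2**31 - 1)
            )
        calls.append(
            HSCall(
                symb_pair=ps.symb_pair,
                host_pair=ps.host_pair,
                symb_stats=ps.symb_stats,
                host_stats=ps.host_stats,
                label=label,
                thresholds=thresholds,
                expected_symb_similarity=expected,
                ci_low=ci_low,
                ci_high=ci_high,
            )
        )
    all_hosts = {h for c in calls for h in c.host_pair}
    hs_hosts = {h for c in calls if c.label == HOST_SHIFT for h in c.host_pair}
    fraction = round(100.0 * len(hs_hosts) / len(all_hosts), 1)
    return calls, fraction


def calls_to_dataframe(calls: Sequence[HSCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "symb_id_a": c.symb_pair[0],
                "symb_id_b": c.symb_pair[1],
                "host_a": c.host_pair[0],
                "host_b": c.host_pair[1],
                "symb_mean": c.symb_stats.mean,
                "host_mean": c.host_stats.mean,
                "expected_symb_similarity": c.expected_symb_similarity,
                "label": c.label,
                "ci_low": c.ci_low,
                "ci_high": c.ci_high,
            }
        )
    return pd.DataFrame(rows)


def write_calls_tsv(calls: Sequence[HSCall], path: str | Path) -> Path:
    path = Path(path)
    calls_to_dataframe(calls).to_csv(
        path, sep="\t", index=False, float_format="%.6f", na_rep="NA",
        lineterminator="\n",
    )
    return path
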