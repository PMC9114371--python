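"""End-to-end pipeline: concatenate, compare, cluster, classify, report.

Stages: per-gene alignments -> supermatrix -> similarity matrices ->
identical-sequence collapse -> divergence-threshold lineages -> seeded
representative selection -> per-pair gene similarity summaries -> host-shift
classification -> NJ trees and symbiont/host RF -> report bundle.

Every artifact is written to the output directory and listed, with a SHA-256
checksum, in ``manifest.json`` alongside the seed and parameters, so a rerun
with the same configuration is byte-identical and verifiable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from contextlib import contextmanager
from dataclasses import dataclass, field
from importlib.metadata import version as _pkg_version
from pathlib import Path
from typing import Sequence

from . import alignment_io, cophylo, hs_detect, lineage, similarity
from .errors import ConfigurationError, HostShiftError
from .hs_detect import PairSummary, ThresholdConfig
from .similarity import SummaryStats

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    symb_dir: Path
    host_dir: Path
    strain_map_path: Path
    out_dir: Path
    gap_mode: str = "all"
    missing_policy: str = "pad_gaps"
    max_divergence: float = lineage.DEFAULT_MAX_DIVERGENCE
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    seed: int = 42
    n_boot: int = 1000

    def __post_init__(self) -> None:
        self.symb_dir = Path(self.symb_dir)
        self.host_dir = Path(self.host_dir)
        self.strain_map_path = Path(self.strain_map_path)
        self.out_dir = Path(self.out_dir)
        for p, what in (
            (self.symb_dir, "symbiont gene directory"),
            (self.host_dir, "host gene directory"),
            (self.strain_map_path, "strain-host map"),
        ):
            if not p.exists():
                raise ConfigurationError(f"{what} not found: {p}")


@contextmanager
def _stage(name: str):
    t0 = time.perf_counter()
    logger.info("stage %s: start", name)
    try:
        yield
    except HostShiftError as exc:
        raise type(exc)(f"[stage {name}] {exc}") from exc
    except Exception as exc:
        raise HostShiftError(f"[stage {name}] {exc}") from exc
    logger.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)


def _fmt_pct(x: float) -> str:
    import math

    return "NA" if math.isnan(x) else f"{100.0 * x:.2f}%"


def render_table1(
    summaries: Sequence[PairSummary | tuple[str, SummaryStats, SummaryStats]],
) -> str:
    """Descriptive-statistics table, one Host/Symbiont column block per pair.

    Rows are n_genes, Mean, Std, Min, 25%, 50%, 75%, Max; values render as
    percentages with two decimals (Std of a single gene is NA).
    """
    if not summaries:
        raise HostShiftError("no pair summaries to render")
    blocks: list[tuple[str, SummaryStats, SummaryStats]] = []
    for s in summaries:
        if isinstance(s, PairSummary):
            label = f"{s.host_pair[0]} vs {s.host_pair[1]}"
            blocks.append((label, s.host_stats, s.symb_stats))
        else:
            blocks.append(s)
    lines = []
    header1 = ["pair"]
    header2 = ["statistic"]
    for label, _, _ in blocks:
        header1 += [label, label]
        header2 += ["Host", "Symbiont"]
    lines.append("\t".join(header1))
    lines.append("\t".join(header2))
    rows = [
        ("n_genes", lambda st: str(st.n_genes)),
        ("Mean", lambda st: _fmt_pct(st.mean)),
        ("Std", lambda st: _fmt_pct(st.std)),
        ("Min", lambda st: _fmt_pct(st.min)),
        ("25%", lambda st: _fmt_pct(st.q25)),
        ("50%", lambda st: _fmt_pct(st.q50)),
        ("75%", lambda st: _fmt_pct(st.q75)),
        ("Max", lambda st: _fmt_pct(st.max)),
    ]
    for name, fmt in rows:
        cells = [name]
        for _, host_stats, symb_stats in blocks:
            cells += [fmt(host_stats), fmt(symb_stats)]
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"


def write_pair_stats_tsv(summaries: Sequence[PairSummary], path: str | Path) -> Path:
    """Long-format per-pair statistics (one row per pair and side)."""
    path = Path(path)
    cols = ["host_a", "host_b", "side", "n_genes", "mean", "std",
            "min", "q25", "q50", "q75", "max"]
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(cols) + "\n")
        for s in summaries:
            for side, st in (("host", s.host_stats), ("symbiont", s.symb_stats)):
                row = [s.host_pair[0], s.host_pair[1], side, str(st.n_genes)]
                row += [f"{v:.6f}" for v in
                        (st.mean, st.std, st.min, st.q25, st.q50, st.q75, st.max)]
                fh.write("\t".join(row).replace("nan", "NA") + "\n")
    return path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write the report bundle; returns the manifest."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []

    def _track(path: Path) -> Path:
        artifacts.append(Path(path))
        return Path(path)

    with _stage("load"):
        symb_genes = alignment_io.read_gene_directory(config.symb_dir)
        host_genes = alignment_io.read_gene_directory(config.host_dir)
        strain_map = alignment_io.read_strain_host_map(config.strain_map_path)

    with _stage("concat"):
        symb_concat = alignment_io.concatenate_by_id(
            symb_genes, config.missing_policy
        )
        host_concat = alignment_io.concatenate_by_id(
            host_genes, config.missing_policy
        )
        alignment_io.write_fasta(symb_concat.records, _track(out / "symbiont_concat.fasta"))
        alignment_io.write_partition_map(
            symb_concat.partitions, _track(out / "symbiont_partitions.tsv")
        )

    with _stage("simmatrix"):
        symb_matrix = similarity.similarity_matrix(symb_concat.records, config.gap_mode)
        host_matrix = similarity.similarity_matrix(host_concat.records, config.gap_mode)
        symb_matrix.to_csv(_track(out / "symbiont_similarity.csv"))
        host_matrix.to_csv(_track(out / "host_similarity.csv"))

    with _stage("collapse"):
        groups = lineage.collapse_identical(symb_concat)
        lineage.write_clusters_tsv(
            groups.groups,
            groups.representative,
            _track(out / "identical_groups.tsv"),
        )

    with _stage("lineages"):
        dedup_matrix = symb_matrix.submatrix(groups.representatives)
        clustering = lineage.cluster_lineages(dedup_matrix, config.max_divergence)
        reps = lineage.select_representatives(clustering, config.seed)
        lineage.write_clusters_tsv(
            clustering.clusters, reps, _track(out / "lineages.tsv")
        )
        rep_strains = sorted(reps.values())

    with _stage("detect"):
        summaries = hs_detect.summarize_pairs(
            symb_genes, host_genes, strain_map, config.gap_mode, strains=rep_strains
        )
        calls, hs_fraction = hs_detect.detect_all(
            summaries,
            config.thresholds,
            n_boot=config.n_boot,
            seed=config.seed,
        )
        hs_detect.write_calls_tsv(calls, _track(out / "calls.tsv"))
        write_pair_stats_tsv(summaries, _track(out / "pair_stats.tsv"))

    with _stage("trees"):
        rf_result = None
        rep_hosts = sorted({strain_map.host_of(s) for s in rep_strains})
        if len(rep_strains) >= 3 and len(rep_hosts) == len(rep_strains):
            symb_tree = cophylo.nj_tree_from_similarity(
                symb_matrix.submatrix(rep_strains)
            )
            host_tree = cophylo.nj_tree_from_similarity(
                host_matrix.submatrix(rep_hosts)
            )
            cophylo.write_newick(symb_tree, _track(out / "symbiont_nj.nwk"))
            cophylo.write_newick(host_tree, _track(out / "host_nj.nwk"))
            rf, rf_norm = cophylo.symbiont_vs_host_rf(symb_tree, host_tree, strain_map)
            with open(_track(out / "rf.tsv"), "w", newline="\n") as fh:
                fh.write("rf\tnormalized\tn_leaves\n")
                fh.write(f"{rf}\t{rf_norm:.6f}\t{len(rep_strains)}\n")
            rf_result = {"rf": rf, "normalized": rf_norm, "n_leaves": len(rep_strains)}
        else:
            logger.warning("fewer than 3 unique-host representatives; trees skipped")

    with _stage("report"):
        (_track(out / "report.tsv")).write_text(render_table1(summaries))
        summary = {
            "n_strains": len(strain_map.strains),
            "n_identical_groups": groups.n_after,
            "n_before_collapse": groups.n_before,
            "n_lineages": clustering.n_clusters,
            "n_pairs_classified": len(calls),
            "n_host_shift_calls": sum(
                1 for c in calls if c.label == hs_detect.HOST_SHIFT
            ),
            "hs_host_fraction_pct": hs_fraction,
            "rf": rf_result,
        }
        (_track(out / "summary.json")).write_text(
            json.dumps(summary, indent=2) + "\n"
        )
        try:
            pkg_version = _pkg_version("hostshift")
        except Exception:
            pkg_version = "unknown"
        manifest = {
            "version": pkg_version,
            "seed": config.seed,
            "parameters": {
                "gap_mode": config.gap_mode,
                "missing_policy": config.missing_policy,
                "max_divergence": config.max_divergence,
                "symb_min_similarity": config.thresholds.symb_min_similarity,
                "host_max_similarity": config.thresholds.host_max_similarity,
                "n_boot": config.n_boot,
            },
            "files": {
                str(p.relative_to(out)): _sha256(p) for p in sorted(artifacts)
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
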