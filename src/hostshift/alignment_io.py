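"""Aligned-FASTA I/O and concatenation of per-gene alignments into supermatrices.

Per-gene ortholog alignments (one FASTA per gene, DNA, already aligned) are
read into :class:`GeneAlignment` objects, then concatenated strain-by-strain
into a :class:`ConcatAlignment` carrying a partition map with 0-based
half-open gene coordinates. Gene order in the concatenation is lexicographic
by gene id so the supermatrix is independent of filesystem ordering.

The sequence alphabet is normalized to ``{A, C, G, T, N, -}``: input is
uppercased and any other symbol (U, IUPAC ambiguity codes, ...) becomes N,
with the number of replacements logged per file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

from .errors import (
    AlignmentShapeError,
    DataValidationError,
    DuplicateIdError,
    EmptyInputError,
)

logger = logging.getLogger(__name__)

ALPHABET = frozenset("ACGTN-")

STRAIN_MAP_HEADER = ("strain_id", "host_species", "host_taxon")


@dataclass
class GeneAlignment:
    """One gene's multiple sequence alignment.

    ``records`` is an insertion-ordered mapping sequence_id -> aligned string;
    all strings have equal length and use the normalized alphabet.
    """

    gene_id: str
    records: dict[str, str]

    def __post_init__(self) -> None:
        if not self.records:
            raise EmptyInputError(f"gene {self.gene_id!r}: alignment has no records")
        lengths = {len(s) for s in self.records.values()}
        if len(lengths) != 1:
            offender = next(
                rid
                for rid, s in self.records.items()
                if len(s) != len(next(iter(self.records.values())))
            )
            raise AlignmentShapeError(
                f"gene {self.gene_id!r}: unequal sequence lengths "
                f"(record {offender!r} differs)"
            )
        if lengths == {0}:
            raise EmptyInputError(f"gene {self.gene_id!r}: zero-column alignment")
        bad = set("".join(self.records.values())) - ALPHABET
        if bad:
            raise DataValidationError(
                f"gene {self.gene_id!r}: characters outside alphabet: {sorted(bad)}"
            )

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.records.values())))

    @property
    def ids(self) -> list[str]:
        return list(self.records)


@dataclass
class ConcatAlignment:
    """Per-strain concatenation of gene alignments with a partition map.

    ``partitions`` is an ordered list of ``(gene_id, start, end)`` tuples in
    0-based half-open coordinates, contiguous and covering ``[0, total_length)``.
    """

    records: dict[str, str]
    partitions: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        if not self.records:
            raise EmptyInputError("concatenation has no records")
        pos = 0
        for gene_id, start, end in self.partitions:
            if start != pos or end <= start:
                raise DataValidationError(
                    f"partition {gene_id!r} ({start},{end}) breaks contiguity at {pos}"
                )
            pos = end
        if pos != self.total_length:
            raise DataValidationError("partitions do not cover the concatenation")
        for rid, s in self.records.items():
            if len(s) != pos:
                raise AlignmentShapeError(
                    f"record {rid!r} has length {len(s)}, expected {pos}"
                )

    @property
    def total_length(self) -> int:
        return len(next(iter(self.records.values())))

    def gene_slice(self, gene_id: str) -> dict[str, str]:
        """Per-gene columns recovered from the concatenation."""
        for gid, start, end in self.partitions:
            if gid == gene_id:
                return {rid: s[start:end] for rid, s in self.records.items()}
        raise KeyError(gene_id)


@dataclass
class StrainHostMap:
    """Mapping symbiont strain id -> (host species, host taxon label)."""

    mapping: dict[str, tuple[str, str]] = field(default_factory=dict)

    def host_of(self, strain_id: str) -> str:
        return self.mapping[strain_id][0]

    @property
    def strains(self) -> list[str]:
        return list(self.mapping)

    @property
    def host_species(self) -> list[str]:
        seen: dict[str, None] = {}
        for species, _ in self.mapping.values():
            seen.setdefault(species)
        return list(seen)


def _normalize(seq: str) -> tuple[str, int]:
    up = seq.upper()
    cleaned = []
    n_replaced = 0
    for ch in up:
        if ch in ALPHABET:
            cleaned.append(ch)
        else:
            cleaned.append("N")
            n_replaced += 1
    return "".join(cleaned), n_replaced


def read_fasta_alignment(path: str | Path, gene_id: str | None = None) -> GeneAlignment:
    """Read one aligned FASTA file into a :class:`GeneAlignment`.

    Sequences are uppercased; characters outside the alphabet are replaced by
    N and the replacement count is logged as a warning.
    """
    path = Path(path)
    if gene_id is None:
        gene_id = path.stem
    records: dict[str, str] = {}
    total_replaced = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise DuplicateIdError(f"{path}: duplicate sequence id {rec.id!r}")
        seq, n_replaced = _normalize(str(rec.seq))
        total_replaced += n_replaced
        records[rec.id] = seq
    if not records:
        raise EmptyInputError(f"{path}: no FASTA records")
    if total_replaced:
        logger.warning(
            "%s: %d non-ACGTN- characters replaced by N", path, total_replaced
        )
    return GeneAlignment(gene_id=gene_id, records=records)


def read_gene_directory(directory: str | Path, pattern: str = "*.fasta") -> list[GeneAlignment]:
    """Read every per-gene FASTA in a directory (sorted by filename)."""
    directory = Path(directory)
    paths = sorted(directory.glob(pattern))
    if not paths:
        raise EmptyInputError(f"{directory}: no files matching {pattern!r}")
    return [read_fasta_alignment(p) for p in paths]


def concatenate_by_id(
    genes: Iterable[GeneAlignment], missing_policy: str = "pad_gaps"
) -> ConcatAlignment:
    """Concatenate gene alignments by sequence id into a supermatrix.

    Under ``pad_gaps`` (default), an id absent from a gene receives a run of
    gaps the width of that gene; under ``drop_strain``, ids absent from any
    gene are excluded entirely. Gene order is lexicographic by gene id.
    """
    genes = sorted(genes, key=lambda g: g.gene_id)
    if not genes:
        raise EmptyInputError("no gene alignments to concatenate")
    gene_ids = [g.gene_id for g in genes]
    if len(set(gene_ids)) != len(gene_ids):
        raise DuplicateIdError("duplicate gene ids in concatenation input")

    if missing_policy not in ("pad_gaps", "drop_strain"):
        raise DataValidationError(f"unknown missing_policy {missing_policy!r}")

    universe: dict[str, None] = {}
    for g in genes:
        for rid in g.records:
            universe.setdefault(rid)
    ids = sorted(universe)
    if missing_policy == "drop_strain":
        ids = [rid for rid in ids if all(rid in g.records for g in genes)]
        if not ids:
            raise EmptyInputError("drop_strain left no sequence present in every gene")

    partitions: list[tuple[str, int, int]] = []
    pos = 0
    pieces: dict[str, list[str]] = {rid: [] for rid in ids}
    for g in genes:
        width = g.n_columns
        partitions.append((g.gene_id, pos, pos + width))
        pos += width
        pad = "-" * width
        for rid in ids:
            pieces[rid].append(g.records.get(rid, pad))
    records = {rid: "".join(parts) for rid, parts in pieces.items()}
    return ConcatAlignment(records=records, partitions=partitions)


def write_fasta(
    records: Mapping[str, str], path: str | Path, line_width: int = 60
) -> Path:
    """Write records as FASTA (LF endings, wrapped at ``line_width``)."""
    if not records:
        raise EmptyInputError("no records to write")
    if line_width < 1:
        raise DataValidationError("line_width must be positive")
    path = Path(path)
    with open(path, "w", newline="\n") as fh:
        for rid, seq in records.items():
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")
    return path


def write_partition_map(partitions: list[tuple[str, int, int]], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="\n") as fh:
        fh.write("gene_id\tstart\tend\n")
        for gene_id, start, end in partitions:
            fh.write(f"{gene_id}\t{start}\t{end}\n")
    return path


def read_strain_host_map(path: str | Path) -> StrainHostMap:
    """Read the strain->host TSV (header: strain_id, host_species, host_taxon)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise EmptyInputError(f"{path}: empty strain-host map")
    header = tuple(lines[0].rstrip("\n").split("\t"))
    if header != STRAIN_MAP_HEADER:
        raise DataValidationError(
            f"{path}: expected header {STRAIN_MAP_HEADER}, found {header}"
        )
    mapping: dict[str, tuple[str, str]] = {}
    for line in lines[1:]:
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise DataValidationError(f"{path}: malformed line {line!r}")
        strain, species, taxon = fields
        if strain in mapping:
            raise DuplicateIdError(f"{path}: strain {strain!r} mapped twice")
        mapping[strain] = (species, taxon)
    if not mapping:
        raise EmptyInputError(f"{path}: no strain rows")
    return StrainHostMap(mapping=mapping)


def write_strain_host_map(strain_map: StrainHostMap, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(STRAIN_MAP_HEADER) + "\n")
        for strain, (species, taxon) in strain_map.mapping.items():
            fh.write(f"{strain}\t{species}\t{taxon}\n")
    return path
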