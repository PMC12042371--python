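"""Partitioned supermatrix concatenation for multi-locus datasets.

Per-locus alignments are concatenated taxon-wise into one rectangular
matrix; each input locus becomes one partition with 1-based inclusive
column coordinates in the RAxML partition-file dialect
(``DNA, <name> = <start>-<end>``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "Alignment",
    "Partition",
    "Supermatrix",
    "read_fasta_alignment",
    "write_fasta",
    "concatenate",
    "write_partition_file",
    "read_partition_file",
    "AlignmentError",
]

GAP = "-"


class AlignmentError(ValueError):
    """Raised for ragged alignments, duplicate labels or taxon mismatches."""


@dataclass
class Alignment:
    """One locus: a mapping taxon label -> aligned nucleotide string."""

    name: str
    sequences: dict[str, str]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise AlignmentError(f"alignment {self.name!r} has no sequences")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise AlignmentError(
                f"alignment {self.name!r} is ragged: lengths {sorted(lengths)}"
            )

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(self.sequences)


@dataclass(frozen=True)
class Partition:
    """1-based inclusive column span of one locus in the supermatrix."""

    name: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Supermatrix:
    """Concatenated alignment with an ordered partition table."""

    sequences: dict[str, str]
    partitions: tuple[Partition, ...]

    def __post_init__(self) -> None:
        total = self.total_length
        expected_start = 1
        for p in self.partitions:
            if p.start != expected_start:
                raise AlignmentError(
                    f"partitions do not tile the matrix at {p.name!r}"
                )
            expected_start = p.end + 1
        if self.partitions and expected_start != total + 1:
            raise AlignmentError("partition spans do not sum to the total length")
        for taxon, seq in self.sequences.items():
            if len(seq) != total:
                raise AlignmentError(f"sequence for {taxon!r} has the wrong length")

    @property
    def total_length(self) -> int:
        return sum(p.length for p in self.partitions)

    @property
    def n_partitions(self) -> int:
        return len(self.partitions)

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(self.sequences)


def read_fasta_alignment(path, name: str | None = None) -> Alignment:
    """Read one FASTA alignment; the locus name defaults to the file stem."""
    path = Path(path)
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise AlignmentError(f"duplicate taxon label {record.id!r} in {path.name}")
        sequences[record.id] = str(record.seq)
    if not sequences:
        raise AlignmentError(f"no FASTA records in {path}")
    return Alignment(name=name or path.stem, sequences=sequences)


def write_fasta(sequences: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for taxon, seq in sequences.items():
            fh.write(f">{taxon}\n{seq}\n")


def concatenate(alignments: Sequence[Alignment], fill_missing: bool = True) -> Supermatrix:
    """Concatenate loci in input order into a partitioned supermatrix.

    With ``fill_missing`` true, taxa absent from a locus are padded with
    gap characters; otherwise all loci must share one taxon set.
    """
    alignments = list(alignments)
    if not alignments:
        raise AlignmentError("at least one alignment is required")
    all_taxa: list[str] = []
    seen: set[str] = set()
    for aln in alignments:
        for taxon in aln.taxa:
            if taxon not in seen:
                seen.add(taxon)
                all_taxa.append(taxon)
    if not fill_missing:
        first = set(alignments[0].taxa)
        for aln in alignments:
            if set(aln.taxa) != first:
                raise AlignmentError(
                    f"taxon sets differ at locus {aln.name!r} and fill_missing is off"
                )
    parts: list[Partition] = []
    chunks: dict[str, list[str]] = {t: [] for t in all_taxa}
    pos = 1
    for i, aln in enumerate(alignments):
        name = aln.name.strip() or f"locus_{i + 1}"
        parts.append(Partition(name, pos, pos + aln.length - 1))
        pos += aln.length
        pad = GAP * aln.length
        for taxon in all_taxa:
            chunks[taxon].append(aln.sequences.get(taxon, pad))
    sequences = {t: "".join(c) for t, c in chunks.items()}
    return Supermatrix(sequences=sequences, partitions=tuple(parts))


def write_partition_file(sm: Supermatrix, path) -> None:
    """Write RAxML-style partition lines ``DNA, <name> = <start>-<end>``."""
    with open(path, "w") as fh:
        for i, p in enumerate(sm.partitions):
            name = p.name.strip() or f"locus_{i + 1}"
            fh.write(f"DNA, {name} = {p.start}-{p.end}\n")


def read_partition_file(path) -> tuple[Partition, ...]:
    """Read the dialect written by :func:`write_partition_file`."""
    parts: list[Partition] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            head, _, span = line.partition("=")
            dtype, _, name = head.partition(",")
            start_s, _, end_s = span.strip().partition("-")
            parts.append(Partition(name.strip(), int(start_s), int(end_s)))
    return tuple(parts)
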