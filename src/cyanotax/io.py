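"""Sequence and table I/O, genome summary statistics, and inclusion filters.

FASTA records are the universal currency of the pipeline: genome contigs,
predicted proteomes, 16S rRNA genes and marker alignments all enter as
:class:`SequenceRecord` collections.  Tables (genome statistics, taxonomy
labels, environmental parameters) are tab-separated with a header row, and
genome identifiers must match FASTA identifiers exactly (the identifier is
the first whitespace-delimited word of the header line).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

log = logging.getLogger(__name__)

#: Nucleotide residues stored after normalisation ("-" for aligned input).
NUCLEOTIDE_CHARS = frozenset("ACGTN-")
#: IUPAC ambiguity codes other than N are collapsed to N on input.
_AMBIGUITY_TO_N = str.maketrans({c: "N" for c in "RYSWKMBDHVU"})
#: The 20 standard amino acids plus X ("-" for aligned input).
PROTEIN_CHARS = frozenset("ACDEFGHIKLMNPQRSTVWYX-")


class Alphabet(str, Enum):
    """Residue alphabet of a sequence record."""

    nucleotide = "nucleotide"
    protein = "protein"


class AlphabetViolation(ValueError):
    """Raised when a record contains residues outside its declared alphabet."""


class DuplicateIdentifier(ValueError):
    """Raised when two records in one set share an identifier."""


@dataclass(frozen=True)
class SequenceRecord:
    """A single named sequence.

    Residues are stored uppercase.  Nucleotide ambiguity codes other than N
    are mapped to N (with a logged warning) before validation; anything else
    outside the alphabet raises :class:`AlphabetViolation`.
    """

    id: str
    residues: str
    alphabet: Alphabet

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record identifier must be non-empty")
        if not self.residues:
            raise ValueError(f"record {self.id!r}: residues must be non-empty")
        residues = self.residues.upper()
        alphabet = Alphabet(self.alphabet)
        if alphabet is Alphabet.nucleotide:
            mapped = residues.translate(_AMBIGUITY_TO_N)
            if mapped != residues:
                n_mapped = sum(a != b for a, b in zip(residues, mapped))
                log.warning(
                    "record %s: %d ambiguity code(s) mapped to N", self.id, n_mapped
                )
                residues = mapped
            allowed = NUCLEOTIDE_CHARS
        else:
            allowed = PROTEIN_CHARS
        bad = set(residues) - allowed
        if bad:
            raise AlphabetViolation(
                f"alphabet violation in record {self.id!r}: "
                f"illegal character(s) {sorted(bad)} for {alphabet.value} alphabet"
            )
        object.__setattr__(self, "residues", residues)
        object.__setattr__(self, "alphabet", alphabet)

    def __len__(self) -> int:
        return len(self.residues)


class SequenceSet:
    """An ordered collection of uniquely-identified sequence records."""

    def __init__(self, records: Iterable[SequenceRecord] = ()) -> None:
        self._records: dict[str, SequenceRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, record: SequenceRecord) -> None:
        if record.id in self._records:
            raise DuplicateIdentifier(f"duplicate identifier {record.id!r}")
        self._records[record.id] = record

    @property
    def ids(self) -> list[str]:
        return list(self._records)

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self._records.values())

    def __getitem__(self, record_id: str) -> SequenceRecord:
        return self._records[record_id]

    def __contains__(self, record_id: str) -> bool:
        return record_id in self._records

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SequenceSet):
            return NotImplemented
        return self._records == other._records

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"SequenceSet({len(self)} records)"


def read_fasta(path: str | Path, alphabet: Alphabet | str) -> SequenceSet:
    """Read a FASTA file into a :class:`SequenceSet`.

    Line wrapping is ignored; the record identifier is the first
    whitespace-delimited word of the header.  An empty file, a duplicated
    identifier or an illegal residue raises ``ValueError`` subclasses with
    messages naming the problem.
    """
    alphabet = Alphabet(alphabet)
    records = SequenceSet()
    for rec in SeqIO.parse(str(path), "fasta"):
        records.add(SequenceRecord(rec.id, str(rec.seq), alphabet))
    if len(records) == 0:
        raise ValueError(f"no records in FASTA file {path}")
    return records


def read_reads(path: str | Path) -> SequenceSet:
    """Read sequencing reads from FASTA or FASTQ (qualities are ignored)."""
    fmt = "fastq" if Path(path).suffix.lower() in (".fastq", ".fq") else "fasta"
    records = SequenceSet()
    for rec in SeqIO.parse(str(path), fmt):
        records.add(SequenceRecord(rec.id, str(rec.seq), Alphabet.nucleotide))
    if len(records) == 0:
        raise ValueError(f"no records in reads file {path}")
    return records


def write_fasta(records: SequenceSet | Iterable[SequenceRecord],
                path: str | Path, width: int = 60) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width`` columns."""
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                handle.write(rec.residues[i:i + width] + "\n")


@dataclass(frozen=True)
class GenomeStats:
    """Summary statistics for one genome assembly.

    ``completeness_percent`` is user-supplied (estimated by an external tool
    upstream); everything else is computed from the contigs.
    """

    genome_id: str
    length_bp: int
    gc_percent: float
    n_contigs: int
    completeness_percent: float

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise ValueError("length_bp must be >= 1")
        if self.n_contigs < 1:
            raise ValueError("n_contigs must be >= 1")
        if not 0.0 <= self.gc_percent <= 100.0:
            raise ValueError("gc_percent must lie in [0, 100]")
        if not 0.0 <= self.completeness_percent <= 100.0:
            raise ValueError("completeness_percent must lie in [0, 100]")


def genome_stats(genome_id: str, contigs: SequenceSet,
                 completeness: float) -> GenomeStats:
    """Compute length, GC content and contig count for one genome.

    GC% is computed over unambiguous bases only: N is excluded from both the
    numerator and the denominator.  A genome consisting entirely of N raises
    ``ValueError``.
    """
    if len(contigs) == 0:
        raise ValueError("genome has no contigs")
    length = 0
    gc = 0
    unambiguous = 0
    for rec in contigs:
        if rec.alphabet is not Alphabet.nucleotide:
            raise ValueError(f"contig {rec.id!r} is not nucleotide")
        s = rec.residues
        length += len(s)
        gc += s.count("G") + s.count("C")
        unambiguous += len(s) - s.count("N")
    if unambiguous == 0:
        raise ValueError(f"genome {genome_id!r}: no unambiguous bases")
    return GenomeStats(
        genome_id=genome_id,
        length_bp=length,
        gc_percent=100.0 * gc / unambiguous,
        n_contigs=len(contigs),
        completeness_percent=completeness,
    )


def apply_genome_filters(stats: GenomeStats, min_completeness: float = 90.0,
                         max_contigs: int = 500) -> bool:
    """Genome inclusion filter: at least ``min_completeness``% complete and
    assembled in strictly fewer than ``max_contigs`` contigs."""
    return (stats.completeness_percent >= min_completeness
            and stats.n_contigs < max_contigs)


_STATS_COLUMNS = ["genome_id", "length_bp", "gc_percent", "n_contigs",
                  "completeness_percent"]


def write_stats_table(stats: Iterable[GenomeStats], path: str | Path) -> None:
    rows = [[s.genome_id, s.length_bp, s.gc_percent, s.n_contigs,
             s.completeness_percent] for s in stats]
    pd.DataFrame(rows, columns=_STATS_COLUMNS).to_csv(path, sep="\t", index=False)


def read_stats_table(path: str | Path) -> list[GenomeStats]:
    df = pd.read_csv(path, sep="\t")
    missing = set(_STATS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"stats table missing column(s) {sorted(missing)}")
    return [
        GenomeStats(
            genome_id=str(row.genome_id),
            length_bp=int(row.length_bp),
            gc_percent=float(row.gc_percent),
            n_contigs=int(row.n_contigs),
            completeness_percent=float(row.completeness_percent),
        )
        for row in df.itertuples()
    ]


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a generic TSV table with a header row (index in first column)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")
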