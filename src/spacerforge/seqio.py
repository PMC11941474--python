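"""Sequence model, FASTA/BED/TSV I/O and synthetic-genome fixtures.

Coordinates are 0-based half-open everywhere inside the library. BED output
stays 0-based half-open; TSV reports additionally carry 1-based inclusive
columns for bench users.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

# Unambiguous + ambiguity letters of the IUPAC DNA alphabet. U is not DNA.
IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN")
UNAMBIGUOUS = frozenset("ACGT")


class SeqIOError(ValueError):
    """Base class for sequence-model errors."""


class EmptyFastaError(SeqIOError):
    pass


class DuplicateRecordIdError(SeqIOError):
    pass


class AlphabetError(SeqIOError):
    pass


class CoordinateError(SeqIOError):
    pass


class PlantingError(SeqIOError):
    pass


def _validate_dna(seq: str, context: str = "sequence") -> str:
    seq = seq.upper()
    bad = set(seq) - IUPAC_DNA
    if bad:
        raise AlphabetError(
            f"{context} contains non-IUPAC-DNA letters: {sorted(bad)} "
            "(note RNA 'U' is rejected)"
        )
    return seq


@dataclasses.dataclass(frozen=True)
class GenomeSequence:
    """A named DNA sequence; the universe every scan runs over.

    ``circular`` enables wrap-around slicing (plasmids); chromosomes of
    streptomycetes are linear, so it defaults to False.
    """

    id: str
    seq: str
    circular: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", _validate_dna(self.seq, f"record {self.id!r}"))
        if len(self.seq) < 1:
            raise SeqIOError(f"record {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.seq)


@dataclasses.dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval [start, end) on a named record."""

    record_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0:
            raise CoordinateError(f"negative start {self.start}")
        if self.end <= self.start:
            raise CoordinateError(f"empty/inverted interval [{self.start}, {self.end})")
        if self.strand not in {"+", "-", "both"}:
            raise CoordinateError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


def revcomp(seq: str) -> str:
    """IUPAC-aware reverse complement (N<->N, R<->Y, ...)."""
    return str(Seq(_validate_dna(seq)).reverse_complement())


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a (multi-)FASTA into GenomeSequence records, order preserved.

    Record ids are the first whitespace-delimited header token. Raises
    EmptyFastaError / DuplicateRecordIdError / AlphabetError.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise EmptyFastaError(f"no FASTA records in {path}")
    genomes: list[GenomeSequence] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise DuplicateRecordIdError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        genomes.append(GenomeSequence(id=rec.id, seq=str(rec.seq)))
    return genomes


def write_fasta(genomes: Iterable[GenomeSequence] | Iterable[tuple[str, str]],
                path: str | Path) -> None:
    """Write records (GenomeSequence or (name, seq) pairs) as FASTA."""
    records = []
    for g in genomes:
        if isinstance(g, GenomeSequence):
            records.append(SeqRecord(Seq(g.seq), id=g.id, description=""))
        else:
            name, seq = g
            records.append(SeqRecord(Seq(seq), id=name, description=""))
    SeqIO.write(records, str(path), "fasta")


def slice_interval(genome: GenomeSequence, iv: GenomicInterval) -> str:
    """Strand-aware substring; wraps the origin only on circular records."""
    n = len(genome)
    if iv.start >= n:
        raise CoordinateError(f"start {iv.start} beyond record length {n}")
    if iv.end > n:
        if not genome.circular:
            raise CoordinateError(
                f"interval [{iv.start}, {iv.end}) out of bounds on linear "
                f"record {genome.id!r} of length {n}"
            )
        if len(iv) > n:
            raise CoordinateError("interval longer than circular record")
        sub = genome.seq[iv.start:] + genome.seq[: iv.end - n]
    else:
        sub = genome.seq[iv.start : iv.end]
    if iv.strand == "-":
        return revcomp(sub)
    return sub


def generate_genome(length: int, gc: float = 0.72, seed: int = 0,
                    record_id: str = "synthetic") -> GenomeSequence:
    """I.i.d. random genome with P(G)=P(C)=gc/2, P(A)=P(T)=(1-gc)/2.

    Order-0 base model: no codon or dinucleotide structure, which is all the
    planted-site fixtures need. Bytewise reproducible for a fixed seed.
    """
    if length < 1:
        raise SeqIOError(f"length must be >= 1, got {length}")
    if not 0.0 <= gc <= 1.0:
        raise SeqIOError(f"gc must be in [0, 1], got {gc}")
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    draw = rng.choice(bases, size=length, p=p)
    return GenomeSequence(id=record_id, seq=draw.tobytes().decode("ascii"))


def plant_sites(genome: GenomeSequence, insert: str,
                positions: Sequence[tuple[int, str]]) -> GenomeSequence:
    """Overwrite the genome with ``insert`` at each (offset, strand).

    Minus-strand plants write the reverse complement on the + strand; planted
    copies must not overlap each other and must fit within the record.
    """
    insert = _validate_dna(insert, "insert")
    n, m = len(genome), len(insert)
    claimed: list[tuple[int, int]] = []
    for off, strand in positions:
        if strand not in {"+", "-"}:
            raise PlantingError(f"bad strand {strand!r}")
        if off < 0 or off + m > n:
            raise PlantingError(f"plant at {off} (+{m} bp) out of bounds (record length {n})")
        for s, e in claimed:
            if off < e and s < off + m:
                raise PlantingError(f"plants at {s} and {off} overlap")
        claimed.append((off, off + m))
    seq = bytearray(genome.seq, "ascii")
    for off, strand in positions:
        copy = insert if strand == "+" else revcomp(insert)
        seq[off : off + m] = copy.encode("ascii")
    return GenomeSequence(id=genome.id, seq=seq.decode("ascii"), circular=genome.circular)


def write_bed(rows: Iterable[tuple], path: str | Path) -> None:
    """Write BED6 rows (chrom, start, end, name, score, strand)."""
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_tsv(df, path: str | Path) -> None:
    """Write a pandas DataFrame report as TSV (no index)."""
    df.to_csv(path, sep="\t", index=False)
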