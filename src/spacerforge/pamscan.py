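"""PAM-motif scanning, genome-wide PAM census and protospacer extraction.

The type I-C CASCADE-Cas3 system recognizes a 5'-TTC-3' PAM with the 34-nt
protospacer immediately 3' of it; the same scanner run with pattern "NGG" and
``pam_side="3prime"`` reproduces the SpyCas9 geometry, which is how the
TTC-vs-NGG census comparison for high-GC genomes is produced.

Conventions (documented, test-pinned): overlapping motif occurrences all
count, and the two strands are counted independently, so a site matching on
both strands counts twice. Ambiguity letters in the *genome* never satisfy a
motif letter; ambiguity letters in the *motif* match their IUPAC class.
"""

from __future__ import annotations

import dataclasses
import re
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.SeqUtils import gc_fraction

from .seqio import (
    AlphabetError,
    GenomeSequence,
    GenomicInterval,
    IUPAC_DNA,
    revcomp,
    slice_interval,
)


@dataclasses.dataclass(frozen=True)
class PamMotif:
    """A PAM pattern and which side of the protospacer it sits on."""

    pattern: str = "TTC"
    pam_side: str = "5prime"

    def __post_init__(self) -> None:
        pat = self.pattern.upper()
        if not pat or set(pat) - IUPAC_DNA:
            raise AlphabetError(f"bad PAM pattern {self.pattern!r}")
        if self.pam_side not in {"5prime", "3prime"}:
            raise ValueError(f"pam_side must be 5prime or 3prime, got {self.pam_side!r}")
        object.__setattr__(self, "pattern", pat)

    def __len__(self) -> int:
        return len(self.pattern)


@dataclasses.dataclass(frozen=True)
class PamSite:
    """One motif occurrence; the interval is stored in + strand coordinates."""

    record_id: str
    strand: str
    pam_start: int
    pam_end: int
    pam_seq: str  # as read 5'->3' on the site's own strand

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.record_id, self.pam_start, self.pam_end, self.strand)


@dataclasses.dataclass(frozen=True)
class PamCensus:
    motif: PamMotif
    total_count: int
    forward_count: int
    reverse_count: int
    genome_length: int

    @property
    def mean_spacing_bp(self) -> Optional[float]:
        """genome_length / total_count to one decimal; None when no sites."""
        if self.total_count == 0:
            return None
        return round(self.genome_length / self.total_count, 1)


@dataclasses.dataclass
class SpacerCandidate:
    """A protospacer adjacent to a PAM, with annotations filled later."""

    pam: PamSite
    protospacer_iv: GenomicInterval
    protospacer_seq: str
    seed_seq: str
    gc_fraction: float
    annotations: dict = dataclasses.field(default_factory=dict)

    @property
    def strand(self) -> str:
        return self.pam.strand

    @property
    def record_id(self) -> str:
        return self.pam.record_id


def iupac_regex(pattern: str) -> re.Pattern:
    """Compile an IUPAC motif into an overlap-reporting regex.

    Each motif letter becomes a character class over plain A/C/G/T only, so
    an N (or any ambiguity code) in the genome can never be claimed as a PAM.
    """
    parts = []
    for letter in pattern.upper():
        klass = ambiguous_dna_values[letter]  # e.g. N -> "GATC", R -> "AG"
        parts.append(f"[{klass}]" if len(klass) > 1 else klass)
    return re.compile("(?=" + "".join(parts) + ")")


def _plus_strand_starts(seq: str, pattern: str) -> list[int]:
    rx = iupac_regex(pattern)
    return [m.start() for m in rx.finditer(seq)]


def scan_motif(genome: GenomeSequence, motif: PamMotif,
               strands: str = "both") -> list[PamSite]:
    """All (overlapping) motif occurrences on the requested strand(s).

    Minus-strand occurrences are located by scanning the reverse complement
    of the pattern on the + strand; their interval is reported in + strand
    coordinates with strand "-". Deterministic order: + coordinate, then
    strand (+ before -).
    """
    if strands not in {"+", "-", "both"}:
        raise ValueError(f"bad strands {strands!r}")
    m = len(motif)
    sites: list[PamSite] = []
    if strands in {"+", "both"}:
        for s in _plus_strand_starts(genome.seq, motif.pattern):
            sites.append(PamSite(genome.id, "+", s, s + m, genome.seq[s : s + m]))
    if strands in {"-", "both"}:
        for s in _plus_strand_starts(genome.seq, revcomp(motif.pattern)):
            sites.append(PamSite(genome.id, "-", s, s + m,
                                 revcomp(genome.seq[s : s + m])))
    sites.sort(key=lambda p: (p.pam_start, 0 if p.strand == "+" else 1))
    return sites


def census(genomes: Sequence[GenomeSequence], motif: PamMotif) -> PamCensus:
    """Both-strand PAM census aggregated over all records.

    Mean spacing divides the summed record length (single-stranded) by the
    two-strand total count, the convention that reproduces ~54.7 bp between
    TTC PAMs on an ~8.7 Mb streptomycete chromosome.
    """
    if not genomes:
        raise ValueError("census needs at least one genome")
    fwd = rev = total_len = 0
    for g in genomes:
        fwd += len(_plus_strand_starts(g.seq, motif.pattern))
        rev += len(_plus_strand_starts(g.seq, revcomp(motif.pattern)))
        total_len += len(g)
    return PamCensus(motif=motif, total_count=fwd + rev, forward_count=fwd,
                     reverse_count=rev, genome_length=total_len)


def _protospacer_interval(site: PamSite, motif: PamMotif,
                          spacer_len: int) -> tuple[int, int]:
    """+ strand interval of the spacer_len bases adjacent on the PAM's strand."""
    # 5prime PAM: protospacer 3' of the motif on its own strand.
    # 3prime PAM: protospacer 5' of the motif on its own strand.
    downstream = (motif.pam_side == "5prime") == (site.strand == "+")
    if downstream:
        return site.pam_end, site.pam_end + spacer_len
    return site.pam_start - spacer_len, site.pam_start


def extract_spacers(genome: GenomeSequence, region: GenomicInterval,
                    motif: PamMotif, spacer_len: int = 34,
                    seed_len: int = 8) -> list[SpacerCandidate]:
    """Protospacer candidates for every PAM lying entirely inside ``region``.

    Candidates whose protospacer would run off the record end are dropped.
    The seed is the PAM-proximal ``seed_len`` portion of the protospacer.
    """
    if not (1 <= seed_len <= spacer_len):
        raise ValueError(f"need spacer_len >= seed_len >= 1, got {spacer_len}, {seed_len}")
    if region.record_id != genome.id:
        raise ValueError(f"region record {region.record_id!r} != genome id {genome.id!r}")
    if region.end > len(genome):
        raise ValueError("region out of bounds")
    out: list[SpacerCandidate] = []
    for site in scan_motif(genome, motif, strands="both"):
        if not (region.start <= site.pam_start and site.pam_end <= region.end):
            continue
        ps, pe = _protospacer_interval(site, motif, spacer_len)
        if ps < 0 or pe > len(genome):
            continue
        iv = GenomicInterval(genome.id, ps, pe, site.strand)
        spacer = slice_interval(genome, iv)  # 5'->3' on the PAM's strand
        # PAM-proximal end: prefix for 5prime geometry, suffix for 3prime.
        if motif.pam_side == "5prime":
            seed = spacer[:seed_len]
        else:
            seed = spacer[-seed_len:]
        out.append(SpacerCandidate(pam=site, protospacer_iv=iv,
                                   protospacer_seq=spacer, seed_seq=seed,
                                   gc_fraction=gc_fraction(spacer)))
    return out


def candidates_to_dataframe(candidates: Iterable[SpacerCandidate]) -> pd.DataFrame:
    """Tabular report; adds 1-based inclusive coordinates for bench users."""
    rows = []
    for c in candidates:
        row = {
            "record": c.record_id,
            "pam_start": c.pam.pam_start,
            "pam_start_1based": c.pam.pam_start + 1,
            "strand": c.strand,
            "pam_seq": c.pam.pam_seq,
            "protospacer_start": c.protospacer_iv.start,
            "protospacer_end": c.protospacer_iv.end,
            "protospacer": c.protospacer_seq,
            "seed": c.seed_seq,
            "gc_fraction": round(c.gc_fraction, 4),
        }
        row.update(c.annotations)
        rows.append(row)
    return pd.DataFrame(rows)


def candidates_to_bed(candidates: Iterable[SpacerCandidate]) -> list[tuple]:
    """BED6 rows: protospacer locus, score = seed+PAM off-target count."""
    rows = []
    for i, c in enumerate(candidates):
        score = c.annotations.get("seed_pam_count", 0)
        name = f"spacer_{i + 1}_{c.record_id}_{c.protospacer_iv.start}{c.strand}"
        rows.append((c.record_id, c.protospacer_iv.start, c.protospacer_iv.end,
                     name, score, c.strand))
    return rows
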