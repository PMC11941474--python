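"""Genome-wide off-target evaluation of spacer candidates.

Two exact evaluations mirror the manual screening workflow for this system:
the whole-length search counts every exact occurrence of the full protospacer
(PAM not required), while the seed search counts occurrences of the PAM motif
plus the PAM-proximal seed in the correct geometry — a seed match without an
adjacent PAM contributes nothing. Both counts include the on-target site, so
a perfectly specific spacer reads (1, 1), not (0, 0). A Hamming
mismatch-tolerant scan (no indels) is available for a closer look at
near-matches.
"""

from __future__ import annotations

import dataclasses
import re
from typing import Optional, Sequence

import numpy as np
from Bio.Data.IUPACData import ambiguous_dna_values

from .pamscan import PamMotif, SpacerCandidate, iupac_regex
from .seqio import GenomeSequence, GenomicInterval, revcomp


@dataclasses.dataclass(frozen=True)
class OffTargetHit:
    location: GenomicInterval
    mismatches: int
    pam_present: bool
    is_on_target: bool


@dataclasses.dataclass(frozen=True)
class OffTargetSummary:
    full_length_count: int
    seed_pam_count: int
    mismatch_histogram: Optional[dict[int, int]] = None


@dataclasses.dataclass(frozen=True)
class FilterSpec:
    """Retention thresholds; defaults keep only perfectly specific spacers."""

    max_full_length_count: int = 1
    max_seed_pam_count: int = 1
    gc_min: float = 0.0
    gc_max: float = 1.0
    region_position_preference: str = "none"

    def __post_init__(self) -> None:
        if self.max_full_length_count < 1 or self.max_seed_pam_count < 1:
            raise ValueError("max counts must be >= 1 (the on-target site always counts)")
        if self.region_position_preference not in {"edge", "middle", "none"}:
            raise ValueError(f"bad position preference {self.region_position_preference!r}")


def adhoc_candidate(spacer: str, motif: Optional[PamMotif] = None,
                    seed_len: int = 8) -> SpacerCandidate:
    """Wrap a bare spacer sequence (no genomic location) for the count/scan
    functions; it can never be flagged as on-target."""
    from Bio.SeqUtils import gc_fraction

    from .pamscan import PamSite

    if motif is None:
        motif = PamMotif()
    spacer = spacer.upper()
    if set(spacer) - set("ACGT"):
        raise ValueError("spacer must be unambiguous A/C/G/T")
    if seed_len > len(spacer):
        raise ValueError("seed_len exceeds spacer length")
    seed = spacer[:seed_len] if motif.pam_side == "5prime" else spacer[-seed_len:]
    pam = PamSite(record_id="<query>", strand="+", pam_start=0,
                  pam_end=len(motif.pattern), pam_seq=motif.pattern)
    iv = GenomicInterval("<query>", 0, len(spacer), "+")
    return SpacerCandidate(pam=pam, protospacer_iv=iv, protospacer_seq=spacer,
                           seed_seq=seed, gc_fraction=gc_fraction(spacer))


def _count_plus(seq: str, pattern: str) -> int:
    """Overlapping occurrences of an IUPAC pattern on the given strand."""
    return sum(1 for _ in iupac_regex(pattern).finditer(seq))


def count_occurrences(query: str, genomes: Sequence[GenomeSequence]) -> int:
    """Exact occurrences of ``query`` on both strands of all records.

    Overlapping occurrences included; strands counted independently, so a
    palindromic query at one locus counts twice.
    """
    total = 0
    rc = revcomp(query)
    for g in genomes:
        total += _count_plus(g.seq, query) + _count_plus(g.seq, rc)
    return total


def count_full_length(candidate: SpacerCandidate,
                      genomes: Sequence[GenomeSequence]) -> int:
    """Exact whole-protospacer occurrences, PAM-independent, on-target included."""
    return count_occurrences(candidate.protospacer_seq, genomes)


def seed_pam_query(candidate: SpacerCandidate, motif: PamMotif,
                   seed_len: int = 8) -> str:
    """The concatenated PAM+seed query, e.g. the 11-mer TTC+N8 by default."""
    if seed_len > len(candidate.protospacer_seq):
        raise ValueError("seed_len exceeds spacer length")
    if motif.pam_side == "5prime":
        seed = candidate.protospacer_seq[:seed_len]
        return motif.pattern + seed
    seed = candidate.protospacer_seq[-seed_len:]
    return seed + motif.pattern


def count_seed_pam(candidate: SpacerCandidate, genomes: Sequence[GenomeSequence],
                   motif: PamMotif, seed_len: int = 8) -> int:
    """Occurrences of PAM motif + PAM-proximal seed in the correct geometry.

    This is the "seed off-targets are only counted when a PAM is present"
    rule: the query string itself carries the PAM.
    """
    return count_occurrences(seed_pam_query(candidate, motif, seed_len), genomes)


def _matches_at(seq: str, pattern: str, start: int) -> bool:
    """IUPAC-class match of pattern at a fixed + strand offset (no overlap)."""
    if start < 0 or start + len(pattern) > len(seq):
        return False
    for off, letter in enumerate(pattern):
        if seq[start + off] not in ambiguous_dna_values[letter]:
            return False
    return True


def _pam_adjacent(genome: GenomeSequence, motif: PamMotif,
                  start: int, end: int, strand: str) -> bool:
    """Is a valid PAM adjacent to the window [start, end) in correct geometry?"""
    m = len(motif.pattern)
    pam_is_downstream_on_plus = (motif.pam_side == "3prime") == (strand == "+")
    if pam_is_downstream_on_plus:
        pat = motif.pattern if strand == "+" else revcomp(motif.pattern)
        return _matches_at(genome.seq, pat, end)
    pat = motif.pattern if strand == "+" else revcomp(motif.pattern)
    return _matches_at(genome.seq, pat, start - m)


def mismatch_scan(candidate: SpacerCandidate, genomes: Sequence[GenomeSequence],
                  max_mm: int, require_pam: bool = False,
                  motif: Optional[PamMotif] = None) -> list[OffTargetHit]:
    """Exhaustive Hamming scan: every window within ``max_mm`` of the spacer.

    Both strands of all records; no indels. Vectorized window comparison; the
    result set is exactly what a naive per-window Hamming count yields.
    """
    query = candidate.protospacer_seq
    L = len(query)
    if not 0 <= max_mm <= L:
        raise ValueError(f"max_mm must be in [0, {L}], got {max_mm}")
    if motif is None:
        motif = PamMotif()
    q_plus = np.frombuffer(query.encode("ascii"), dtype=np.uint8)
    q_minus = np.frombuffer(revcomp(query).encode("ascii"), dtype=np.uint8)
    hits: list[OffTargetHit] = []
    for g in genomes:
        if len(g) < L:
            continue
        arr = np.frombuffer(g.seq.encode("ascii"), dtype=np.uint8)
        windows = np.lib.stride_tricks.sliding_window_view(arr, L)
        for strand, q in (("+", q_plus), ("-", q_minus)):
            mm = (windows != q).sum(axis=1)
            for s in np.nonzero(mm <= max_mm)[0].tolist():
                pam_ok = _pam_adjacent(g, motif, s, s + L, strand)
                if require_pam and not pam_ok:
                    continue
                iv = GenomicInterval(g.id, s, s + L, strand)
                on = (g.id == candidate.record_id
                      and s == candidate.protospacer_iv.start
                      and strand == candidate.strand)
                hits.append(OffTargetHit(location=iv, mismatches=int(mm[s]),
                                         pam_present=pam_ok, is_on_target=on))
    hits.sort(key=lambda h: (h.location.record_id, h.location.start,
                             0 if h.location.strand == "+" else 1))
    return hits


def summarize(candidate: SpacerCandidate, genomes: Sequence[GenomeSequence],
              motif: PamMotif, seed_len: int = 8,
              max_mm: Optional[int] = None) -> OffTargetSummary:
    """Annotate one candidate with both exact counts (and optionally a
    mismatch histogram)."""
    full = count_full_length(candidate, genomes)
    seed = count_seed_pam(candidate, genomes, motif, seed_len)
    hist = None
    if max_mm is not None:
        hist = {k: 0 for k in range(max_mm + 1)}
        for hit in mismatch_scan(candidate, genomes, max_mm, motif=motif):
            hist[hit.mismatches] += 1
    return OffTargetSummary(full_length_count=full, seed_pam_count=seed,
                            mismatch_histogram=hist)


def _position_key(candidate: SpacerCandidate, region: GenomicInterval,
                  preference: str) -> float:
    mid = (candidate.protospacer_iv.start + candidate.protospacer_iv.end) / 2
    if preference == "edge":
        return min(mid - region.start, region.end - mid)
    if preference == "middle":
        return abs(mid - (region.start + region.end) / 2)
    return candidate.protospacer_iv.start


def annotate_and_rank(candidates: list[SpacerCandidate],
                      genomes: Sequence[GenomeSequence], motif: PamMotif,
                      filter_spec: FilterSpec, region: GenomicInterval,
                      seed_len: int = 8,
                      max_mm: Optional[int] = None) -> list[SpacerCandidate]:
    """Annotate every candidate, drop filter violations, impose a total order.

    Order: seed+PAM count asc, whole-length count asc, position criterion per
    the filter's preference, then coordinate asc and + before - as tie-breaks.
    Deterministic regardless of input order.
    """
    annotated: list[SpacerCandidate] = []
    for c in candidates:
        summ = summarize(c, genomes, motif, seed_len=seed_len, max_mm=max_mm)
        c.annotations["full_length_count"] = summ.full_length_count
        c.annotations["seed_pam_count"] = summ.seed_pam_count
        if summ.mismatch_histogram is not None:
            for k, v in summ.mismatch_histogram.items():
                c.annotations[f"mm{k}"] = v
        if summ.full_length_count > filter_spec.max_full_length_count:
            continue
        if summ.seed_pam_count > filter_spec.max_seed_pam_count:
            continue
        if not (filter_spec.gc_min <= c.gc_fraction <= filter_spec.gc_max):
            continue
        annotated.append(c)
    annotated.sort(key=lambda c: (
        c.annotations["seed_pam_count"],
        c.annotations["full_length_count"],
        _position_key(c, region, filter_spec.region_position_preference),
        c.protospacer_iv.start,
        0 if c.strand == "+" else 1,
    ))
    return annotated
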