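"""Cloning-side design: spacer primers, in-silico Gibson assembly, restriction
digestion, and repair-template (homology arm +/- cargo) design.

The spacer-cloning scheme modeled here: the destination plasmid carries two
CRISPR repeats (the second sequence-modified to prevent recombination between
them) around a stuffer. A BstBI/NdeI double digest drops the stuffer segment
together with the origin-bearing region, so only correctly assembled plasmids
replicate. Two PCRs — each pairing a fixed backbone primer with a
repeat-annealing primer whose 5' overhang carries the 34-nt spacer — produce
fragments that Gibson-assemble with the retained backbone, recreating the
plasmid with repeat1 + spacer + repeat2.

Digestion is abstracted as blunt cuts at recognition-site start offsets;
sticky-end chemistry is irrelevant to overlap-based assembly verification.
"""

from __future__ import annotations

import dataclasses
import json
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence

from .seqio import AlphabetError, GenomeSequence, GenomicInterval, _validate_dna, revcomp

DEFAULT_ENZYMES: dict[str, str] = {
    "NdeI": "CATATG",
    "HindIII": "AAGCTT",
    "BstBI": "TTCGAA",
    "NcoI": "CCATGG",
    "SnaBI": "TACGTA",
}


class ConstructError(ValueError):
    pass


class KitError(ConstructError):
    pass


class EnzymeSiteError(ConstructError):
    pass


class GibsonError(ConstructError):
    pass


class MissingOverlapError(GibsonError):
    pass


class AmbiguousOverlapError(GibsonError):
    pass


class CircularizationError(GibsonError):
    pass


class InsufficientFlankError(ConstructError):
    pass


def _circ_find_unique(backbone: str, anchor: str, what: str) -> int:
    """Start offset of the single circular occurrence of anchor (+ strand)."""
    n = len(backbone)
    doubled = backbone + backbone[: len(anchor) - 1]
    starts = []
    pos = doubled.find(anchor)
    while pos != -1 and pos < n:
        starts.append(pos)
        pos = doubled.find(anchor, pos + 1)
    if len(starts) != 1:
        raise KitError(f"{what} must occur exactly once in the backbone "
                       f"(found {len(starts)} times)")
    return starts[0]


def _circ_slice(backbone: str, start: int, end: int) -> str:
    """Circular slice [start, end) with end possibly 'before' start."""
    n = len(backbone)
    start %= n
    end %= n
    if end > start:
        return backbone[start:end]
    return backbone[start:] + backbone[:end]


@dataclasses.dataclass(frozen=True)
class CloningKit:
    """Plasmid-side constants for spacer cloning."""

    repeat1: str
    repeat2: str
    upstream_anneal: str
    downstream_anneal: str
    backbone: Optional[str] = None
    enzymes: Mapping[str, str] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_ENZYMES))
    digestion_enzymes: tuple[str, ...] = ("BstBI", "NdeI")
    min_overlap: int = 20
    spacer_len: int = 34

    def __post_init__(self) -> None:
        for name in ("repeat1", "repeat2", "upstream_anneal", "downstream_anneal"):
            val = getattr(self, name)
            if not val:
                raise KitError(f"{name} must be non-empty")
            object.__setattr__(self, name, _validate_dna(val, name))
        if self.repeat1 == self.repeat2:
            raise KitError("repeat2 must differ from repeat1 "
                           "(anti-recombination modification)")
        if self.backbone is not None:
            object.__setattr__(self, "backbone",
                               _validate_dna(self.backbone, "backbone"))
            for name in ("repeat1", "repeat2", "upstream_anneal", "downstream_anneal"):
                _circ_find_unique(self.backbone, getattr(self, name), name)
        for enz in self.digestion_enzymes:
            if enz not in self.enzymes:
                raise KitError(f"digestion enzyme {enz!r} not in enzyme table")

    @classmethod
    def from_json(cls, path: str | Path) -> "CloningKit":
        with open(path) as fh:
            raw = json.load(fh)
        raw.pop("name", None)
        raw.pop("description", None)
        if "digestion_enzymes" in raw:
            raw["digestion_enzymes"] = tuple(raw["digestion_enzymes"])
        return cls(**raw)


def toy_kit() -> CloningKit:
    """The shipped synthetic toy kit (documented stand-in, not the real plasmid)."""
    ref = resources.files("spacerforge").joinpath("data/toy_kit.json")
    with resources.as_file(ref) as path:
        return CloningKit.from_json(path)


@dataclasses.dataclass(frozen=True)
class PrimerSet:
    fixed_fwd: str
    fixed_rev: str
    spacer_fwd: str
    spacer_rev: str
    fragment_a: Optional[str]
    fragment_b: Optional[str]
    warnings: tuple[str, ...] = ()

    def as_fasta_records(self) -> list[tuple[str, str]]:
        recs = [("fixed_fwd", self.fixed_fwd), ("fixed_rev", self.fixed_rev),
                ("spacer_fwd", self.spacer_fwd), ("spacer_rev", self.spacer_rev)]
        if self.fragment_a:
            recs.append(("fragment_A", self.fragment_a))
        if self.fragment_b:
            recs.append(("fragment_B", self.fragment_b))
        return recs


def design_spacer_primers(spacer: str, kit: CloningKit) -> PrimerSet:
    """The four primers for two-PCR Gibson cloning of a spacer.

    Fragment A runs from the upstream annealing site across repeat1 and gains
    the spacer as a 3' extension from the spacer_rev overhang; fragment B
    starts with the spacer (spacer_fwd overhang), crosses repeat2 and the
    origin-bearing region, and ends at the downstream annealing site. The
    A-B junction overlap is the spacer itself.
    """
    spacer = spacer.upper()
    if set(spacer) - set("ACGT"):
        raise AlphabetError("spacer must be unambiguous A/C/G/T")
    if len(spacer) != kit.spacer_len:
        raise ConstructError(
            f"spacer length {len(spacer)} != kit spacer length {kit.spacer_len}")
    warnings = []
    for enz in kit.digestion_enzymes:
        site = kit.enzymes[enz]
        if site in spacer or revcomp(site) in spacer:
            warnings.append(
                f"spacer contains {enz} site {site}; destination digestion "
                "will cut the insert-side PCR product")
    fixed_fwd = kit.upstream_anneal
    fixed_rev = revcomp(kit.downstream_anneal)
    spacer_fwd = spacer + kit.repeat2          # overhang: spacer
    spacer_rev = revcomp(kit.repeat1 + spacer)  # overhang: revcomp(spacer)
    frag_a = frag_b = None
    if kit.backbone is not None:
        b = kit.backbone
        u = _circ_find_unique(b, kit.upstream_anneal, "upstream_anneal")
        r1 = _circ_find_unique(b, kit.repeat1, "repeat1")
        r2 = _circ_find_unique(b, kit.repeat2, "repeat2")
        d = _circ_find_unique(b, kit.downstream_anneal, "downstream_anneal")
        frag_a = _circ_slice(b, u, r1 + len(kit.repeat1)) + spacer
        frag_b = spacer + _circ_slice(b, r2, d + len(kit.downstream_anneal))
    return PrimerSet(fixed_fwd=fixed_fwd, fixed_rev=fixed_rev,
                     spacer_fwd=spacer_fwd, spacer_rev=spacer_rev,
                     fragment_a=frag_a, fragment_b=frag_b,
                     warnings=tuple(warnings))


def digest(backbone: str, recognition_seqs: Sequence[str]) -> list[str]:
    """Cut a circular sequence at every recognition site (both strands).

    Blunt-cut abstraction: the cut falls at the + strand start offset of each
    site occurrence. Fragments are returned in position order starting from
    the first cut. An enzyme with zero sites raises EnzymeSiteError.
    """
    backbone = _validate_dna(backbone, "backbone")
    n = len(backbone)
    cuts: set[int] = set()
    for site in recognition_seqs:
        site = _validate_dna(site, "recognition site")
        found: set[int] = set()
        for pat in {site, revcomp(site)}:
            doubled = backbone + backbone[: len(pat) - 1]
            pos = doubled.find(pat)
            while pos != -1 and pos < n:
                found.add(pos)
                pos = doubled.find(pat, pos + 1)
        if not found:
            raise EnzymeSiteError(f"no site for recognition sequence {site}")
        cuts |= found
    offsets = sorted(cuts)
    if len(offsets) == 1:
        s = offsets[0]
        return [backbone[s:] + backbone[:s]]
    frags = []
    for i, s in enumerate(offsets):
        e = offsets[(i + 1) % len(offsets)]
        frags.append(_circ_slice(backbone, s, e))
    return frags


def _terminal_overlap(a: str, b: str, min_overlap: int,
                      max_k: Optional[int] = None) -> int:
    """Largest k >= min_overlap with suffix(a, k) == prefix(b, k); 0 if none."""
    hi = min(len(a), len(b))
    if max_k is not None:
        hi = min(hi, max_k)
    for k in range(hi, min_overlap - 1, -1):
        if a[-k:] == b[:k]:
            return k
    return 0


def simulate_gibson(fragments: Sequence[str], backbone_digested: Sequence[str],
                    min_overlap: int = 20) -> str:
    """Merge fragments at unique terminal overlaps into one circular sequence.

    Greedy chaining from the first backbone piece; at every junction exactly
    one remaining fragment may share a terminal overlap >= min_overlap, and
    the chain must close on itself. Returns the canonical (lexicographically
    minimal) rotation of the assembled circle.
    """
    pieces = [_validate_dna(p, "fragment") for p in
              list(backbone_digested) + list(fragments)]
    if not pieces:
        raise GibsonError("nothing to assemble")
    current = pieces[0]
    remaining = list(range(1, len(pieces)))
    while remaining:
        matches = [(i, _terminal_overlap(current, pieces[i], min_overlap))
                   for i in remaining]
        matches = [(i, k) for i, k in matches if k > 0]
        if not matches:
            raise MissingOverlapError(
                f"no fragment shares a terminal overlap >= {min_overlap} nt "
                "with the growing assembly")
        if len(matches) > 1:
            raise AmbiguousOverlapError(
                f"{len(matches)} fragments share a terminal overlap with the "
                "growing assembly; junctions must be unique")
        i, k = matches[0]
        current = current + pieces[i][k:]
        remaining.remove(i)
    k = _terminal_overlap(current, current, min_overlap, max_k=len(current) - 1)
    if k == 0:
        raise CircularizationError(
            "assembled chain cannot circularize (no terminal self-overlap "
            f">= {min_overlap} nt)")
    return canonical_rotation(current[:-k])


def canonical_rotation(seq: str) -> str:
    """Lexicographically minimal rotation (Booth's algorithm)."""
    s = seq + seq
    n = len(seq)
    f = [-1] * len(s)
    k = 0
    for j in range(1, len(s)):
        sj = s[j]
        i = f[j - k - 1]
        while i != -1 and sj != s[k + i + 1]:
            if sj < s[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != s[k + i + 1]:
            if sj < s[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return s[k : k + n]


def rotations_equal(a: str, b: str) -> bool:
    """Are two circular sequences the same up to rotation?"""
    return len(a) == len(b) and a in b + b


@dataclasses.dataclass(frozen=True)
class RepairTemplateDesign:
    deletion: GenomicInterval
    arm_len: int
    left_arm: str
    right_arm: str
    cargo: str
    junction_seq: str
    enzyme_violations: tuple[tuple[str, int], ...]
    edited_locus: str  # full edited record sequence


def _enzyme_hits(seq: str, enzymes: Mapping[str, str]) -> list[tuple[str, int]]:
    """(name, offset) for every both-strand occurrence of each site in seq."""
    hits = []
    for name, site in enzymes.items():
        for pat in sorted({site, revcomp(site)}):
            pos = seq.find(pat)
            while pos != -1:
                hits.append((name, pos))
                pos = seq.find(pat, pos + 1)
    return sorted(set(hits), key=lambda t: (t[1], t[0]))


def design_repair_template(genome: GenomeSequence, deletion: GenomicInterval,
                           arm_len: int = 1000, cargo: str = "",
                           enzymes: Optional[Mapping[str, str]] = None,
                           ) -> RepairTemplateDesign:
    """Homology arms flanking a deletion, optional cargo between them.

    1-kb arms are the working default for homology-directed repair in
    streptomycetes. Every occurrence of a kit enzyme recognition site within
    left_arm + cargo + right_arm is reported so clashes with the cloning
    enzymes (HindIII MCS etc.) are visible before ordering DNA.
    """
    if enzymes is None:
        enzymes = DEFAULT_ENZYMES
    if deletion.record_id != genome.id:
        raise ConstructError("deletion interval names a different record")
    if deletion.end > len(genome):
        raise ConstructError("deletion out of bounds")
    cargo = _validate_dna(cargo, "cargo") if cargo else ""
    max_arm = min(deletion.start, len(genome) - deletion.end)
    if arm_len > max_arm:
        raise InsufficientFlankError(
            f"arm_len {arm_len} exceeds available flank; maximum feasible "
            f"arm_len here is {max_arm}")
    left = genome.seq[deletion.start - arm_len : deletion.start]
    right = genome.seq[deletion.end : deletion.end + arm_len]
    junction = left + cargo + right
    edited = genome.seq[: deletion.start] + cargo + genome.seq[deletion.end :]
    return RepairTemplateDesign(
        deletion=deletion, arm_len=arm_len, left_arm=left, right_arm=right,
        cargo=cargo, junction_seq=junction,
        enzyme_violations=tuple(_enzyme_hits(junction, enzymes)),
        edited_locus=edited)


@dataclasses.dataclass(frozen=True)
class EditedLocusWindow:
    seq: str
    start: int  # start of the window within the edited record
    end: int
    junction_start: int  # cargo start within the edited record
    junction_end: int
    truncated: bool


def predict_edited_locus(genome: GenomeSequence, design: RepairTemplateDesign,
                         window: int) -> EditedLocusWindow:
    """Edited sequence +/- ``window`` bases around the repair junction.

    Suitable as a mapping reference for sequencing-based verification of the
    edit. window = 0 returns exactly the inserted cargo (empty for a pure
    deletion). The window is truncated (and flagged) at record ends.
    """
    if design.deletion.record_id != genome.id:
        raise ConstructError("design derives from a different record")
    edited = design.edited_locus
    j0 = design.deletion.start
    j1 = j0 + len(design.cargo)
    start = j0 - window
    end = j1 + window
    truncated = start < 0 or end > len(edited)
    start = max(0, start)
    end = min(len(edited), end)
    return EditedLocusWindow(seq=edited[start:end], start=start, end=end,
                             junction_start=j0, junction_end=j1,
                             truncated=truncated)
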