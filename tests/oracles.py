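"""Naive brute-force oracles, independent of the library's scan machinery.

Everything here is a direct transcription of the definitions: per-position
sliding windows, explicit IUPAC class membership, early-exit Hamming counts.
Deliberately no regex and no numpy, so agreement with the library is a real
cross-check.
"""

from Bio.Data.IUPACData import ambiguous_dna_values

COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def rc(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def motif_starts(seq: str, pattern: str) -> list[int]:
    """+ strand start offsets of all (overlapping) IUPAC-pattern matches.

    A genome ambiguity letter never satisfies a pattern letter: membership is
    tested against the pattern letter's unambiguous expansion.
    """
    classes = [ambiguous_dna_values[p] for p in pattern]
    m = len(pattern)
    out = []
    for i in range(len(seq) - m + 1):
        if all(seq[i + j] in classes[j] for j in range(m)):
            out.append(i)
    return out


def scan_both(seq: str, pattern: str) -> list[tuple[int, str]]:
    """(+ strand start, strand) for matches on both strands, + coordinates."""
    hits = [(i, "+") for i in motif_starts(seq, pattern)]
    hits += [(i, "-") for i in motif_starts(seq, rc(pattern))]
    return sorted(hits, key=lambda t: (t[0], t[1] != "+"))


def count_occurrences(query: str, seqs: list[str]) -> int:
    """Exact overlapping occurrences of an IUPAC query, both strands."""
    total = 0
    for seq in seqs:
        total += len(motif_starts(seq, query)) + len(motif_starts(seq, rc(query)))
    return total


def hamming_hits(seq: str, query: str, max_mm: int) -> list[tuple[int, str, int]]:
    """(start, strand, mismatches) for every window within max_mm, both strands.

    Early-exit per window; one pass serves every threshold <= max_mm.
    """
    L = len(query)
    out = []
    for strand, q in (("+", query), ("-", rc(query))):
        for i in range(len(seq) - L + 1):
            mm = 0
            for j in range(L):
                if seq[i + j] != q[j]:
                    mm += 1
                    if mm > max_mm:
                        break
            else:
                out.append((i, strand, mm))
    return out


def enzyme_hits(seq: str, enzymes: dict[str, str]) -> list[tuple[str, int]]:
    """(name, offset) for every both-strand recognition-site occurrence."""
    out = []
    for name, site in enzymes.items():
        pats = {site, rc(site)}
        for i in range(len(seq)):
            for pat in pats:
                if seq[i : i + len(pat)] == pat and len(seq) - i >= len(pat):
                    out.append((name, i))
                    break
    return sorted(out, key=lambda t: (t[1], t[0]))
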