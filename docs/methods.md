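# Methods

## Scope and model

spacerforge designs spacers (crRNA guides) for a compact type I-C
CASCADE-Cas3 system and the DNA constructs needed to use them: Gibson-cloning
primers for the editing plasmid and homology-directed-repair templates. The
target recognition model is purely sequence-based: a protospacer is valid
when a PAM matching the configured motif (default 5'-TTC-3') lies immediately
5' of it on the same strand, and specificity is judged by exact string
occurrence counts, not by thermodynamic or cleavage-efficiency scoring. The
same scanner with pattern `NGG` and `pam_side="3prime"` reproduces SpyCas9
geometry, which is how the TTC-vs-NGG PAM-density comparison for high-GC
genomes is made.

## Coordinates and scanning conventions

* Coordinates are 0-based half-open internally and in BED output; TSV reports
  add 1-based inclusive columns; the CLI accepts `record:start-end` 1-based
  inclusive. The conversion is round-trip tested.
* Overlapping motif occurrences all count, and the two strands are counted
  independently, so a palindromic motif (or query) at one locus counts twice.
  This is the simplest reproducible convention; the census test against the
  real chromosome also enumerates the three alternative conventions
  (single-strand counting, non-overlapping counting, and their combination)
  so a mismatch can be diagnosed rather than silently absorbed.
* Ambiguity letters are preserved in sequences but a genome ambiguity letter
  never satisfies a motif letter — an `N` in an assembly cannot be claimed as
  a PAM. A motif ambiguity letter matches its IUPAC class over A/C/G/T.
* Mean PAM spacing divides the summed single-stranded record length by the
  two-strand site count.

## Off-target evaluation

Two exact counts per candidate, both including the on-target occurrence (so
perfect specificity is (1, 1), never (0, 0)):

* **full-length** — exact occurrences of the whole 34-mer, both strands,
  PAM-independent;
* **seed+PAM** — exact occurrences of the concatenated PAM + PAM-proximal
  8-nt seed (the 11-mer `TTC` + seed by default). Carrying the PAM inside the
  query *is* the "seed off-targets only count when a PAM is present" rule.

The optional mismatch scan is exhaustive Hamming search (no indels/bulges)
over every window of every strand, vectorized with numpy byte comparisons;
tests pin its result set to a pure-Python per-window oracle for mismatch
thresholds 0–4. Default `max_mm` = 3 is a conservative, configurable choice;
the scan reports per-hit mismatch counts and PAM-presence flags rather than
imposing a score.

Ranking after filtering is a documented total order: seed+PAM count, then
full-length count, then a position criterion (distance to the nearest region
edge, to the region midpoint, or plain coordinate — exposed because editing
outcomes can depend on where the cut falls relative to the repair arms,
without a firm rule), with coordinate and strand as final tie-breaks. The
order is invariant to input permutation.

## Cloning design

The editing plasmid carries two CRISPR repeats around a stuffer; the second
repeat is sequence-modified to prevent recombination between the repeats.
Spacer cloning is modeled as the two-PCR Gibson workflow: fixed primers
anneal up/downstream of the spacer slot, and two repeat-annealing primers
carry the spacer (or its reverse complement) as 5' overhangs. Fragment A runs
from the upstream annealing site across repeat 1 and ends in the spacer;
fragment B starts with the spacer, crosses repeat 2 and the origin-bearing
segment, and ends at the downstream annealing site. A BstBI+NdeI double
digest drops the stuffer segment together with the origin, so only correctly
assembled plasmids replicate.

Numerical/representational choices:

* Digestion is abstracted as blunt cuts at recognition-site start offsets
  (both strands searched, circularly). Sticky ends are irrelevant to
  overlap-based assembly verification.
* Gibson assembly is exact-overlap merging: greedy chaining from the backbone
  fragment, requiring a unique partner with a terminal overlap ≥
  `min_overlap` (default 20 nt, a standard Gibson homology length) at every
  junction, then circular closure; missing, ambiguous and non-circularizable
  cases raise distinct errors. Assembled circles are compared
  rotation-invariantly (lexicographically minimal rotation, Booth's
  algorithm). Fragment orientation is taken as given; strand flipping is not
  attempted.
* The shipped kit is a **synthetic toy kit** (random sequences with the real
  enzymes' recognition sites and the real plasmid's geometry), because the
  actual plasmid sequence is distributed via a repository rather than printed
  text. Users supply their own kit JSON for real work; every structural claim
  (unique anchors, distinct repeats) is validated on load.

Repair templates take the `arm_len` (default 1000 bp) bases flanking the
deletion as homology arms, optionally with a cargo (e.g. a 51-bp *attB*
integrase attachment site) between them, in the given orientation — no
automatic orientation choice. The design reports every kit-enzyme
recognition-site occurrence inside arm+cargo+arm (both strands) so clashes
with the cloning enzymes are visible, and emits the full edited record plus a
windowed junction reference for sequencing-based verification. Length
conservation (edited = original − deletion + cargo) is asserted structurally
and property-tested.

## Synthetic-genome fixtures

`generate_genome` draws i.i.d. bases with P(G)=P(C)=gc/2 (default gc = 0.72,
typical of streptomycete chromosomes); `plant_sites` overwrites
non-overlapping windows with known sequences on either strand. This order-0
model gives exact planted-site ground truth, which is what the tests need. It
deliberately lacks features of real genomes — codon structure, repeats,
skewed k-mer spectra, mobile elements — so passing tests demonstrate
correctness of the counting and construction logic, not field performance of
any specificity heuristic on a real chromosome. Notably, an i.i.d. 72%-GC
genome has a TTC spacing of ~70 bp, whereas the real *S. coelicolor*
chromosome's codon usage yields ~55 bp; the pinned-genome integration test
covers the real-composition case when the chromosome FASTA is locally
available.

## Problem sizes in the shipped checks

Oracle-equivalence tests use 200 random genomes (lengths 0.8–2 kb plus six at
10 kb, GC ∈ {0.3, 0.5, 0.72}); planted-site recovery uses 100-kb genomes with
0/1/2/5 extra copies; the density-ratio property uses a 1-Mb genome; the
cloning round trip runs 1000 random spacers in the test suite and 300 in the
acceptance script; template arithmetic covers 100 random designs. All seeds
are fixed or derived from the acceptance script's `--seed`.

## Known limitations

* No cleavage-efficiency or off-target *scoring* (CFD/MIT-style); counts and
  mismatch histograms only. No bulge (indel) off-target search.
* No melting-temperature or primer-dimer optimization of the generated
  primers; annealing portions are the full repeat/anchor sequences.
* Deletions driven by the processive nuclease can extend beyond the designed
  repair junction in vivo; only the designed junction is computable and
  modeled.
* Circular (wrap-around) target regions are supported for slicing but spacer
  extraction does not wrap across the origin of a circular record.
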