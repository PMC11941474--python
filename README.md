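# spacerforge

Spacer design, off-target evaluation and cloning-construct design for compact
**type I-C CRISPR-Cas3** genome engineering in high-GC bacteria such as
*Streptomyces*.

Type I CRISPR systems use a multi-subunit CASCADE complex (Cas5/Cas8/Cas7 +
crRNA) to bind a target adjacent to a T-rich **5'-TTC-3' PAM** and recruit the
processive nuclease Cas3, enabling efficient large deletions and
deletion-plus-cargo substitutions of biosynthetic gene clusters. Designing an
experiment means: find PAM sites in a target region, extract the adjacent
**34-nt protospacers**, count genome-wide off-targets (whole-length matches,
and **PAM + 8-nt seed** matches — a seed match only counts when a PAM is
present), pick the most specific spacer, and generate the wet-lab DNA: four
primers for two-PCR Gibson assembly of the spacer between the two CRISPR
repeats of the editing plasmid, plus ~1-kb homology-arm repair templates with
an optional cargo (e.g. a 51-bp phiC31 *attB* site) between the arms.

For a spacer *s* of length *L* = 34 next to PAM *p* = TTC, the two exact
specificity counts over both strands of all genome records *G* are

    full_length(s)  = |{ i : G[i .. i+L) = s }|                (PAM-independent)
    seed_pam(s)     = |{ i : G[i .. i+|p|+8) = p + s[0..8) }|  (PAM required)

with overlapping occurrences counted and the on-target site included, so a
perfectly specific spacer reads (1, 1). A Hamming mismatch scan (no indels)
reports near-matches with PAM-presence flags.

## Worked example

Everything runs offline on reproducible synthetic genomes:

```bash
# reproducible 50-kb random genome at 72% GC
spacerforge fixture --length 50000 --gc 0.72 --seed 99 --out genome.fa

# end-to-end design for a 5-kb deletion region (1-based inclusive coords)
spacerforge design --genome genome.fa --region synthetic:23501-28500 \
    --out-dir design_out
```

prints

```
candidates_in_region	69
candidates_after_filter	66
```

meaning 69 TTC-adjacent 34-mers lie in the region and 66 of them are perfectly
specific — unique whole-length match *and* unique PAM+seed match in the whole
genome, i.e. off-target summary (1, 1). `design_out/` then contains the ranked
candidate table (TSV + BED6), the Gibson primers for the top candidates, the
1-kb repair-template arms, and a `run.log` with every parameter. The PAM
census shows why the T-rich PAM helps in high-GC genomes:

```bash
spacerforge census --genome genome.fa --pam TTC --pam NGG
```

```
pam	total_count	forward_count	reverse_count	genome_length	mean_spacing_bp
TTC	705	343	362	50000	70.9
NGG	12977	6581	6396	50000	3.9
```

— roughly an order of magnitude fewer potential off-target PAM sites for the
type I-C system than for Cas9's NGG. `spacerforge verify-assembly --spacer
<34-mer>` digests the (toy) plasmid with BstBI+NdeI, simulates the
two-fragment Gibson assembly and confirms the product equals direct insertion
of the spacer between the two repeats.

### The real chromosome (optional)

The census integration test against the *S. coelicolor* A3(2) chromosome
expects a local copy at `tests/data/NC_003888.fasta` (about 8.7 Mb, not
shipped); download it once from RefSeq (accession NC_003888.3) and the test
checks the published site counts for TTC and NGG. Without the file the test
skips.

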