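{
  "name": "toy_kit (synthetic)",
  "description": "Synthetic stand-in cloning kit for tests and examples. Geometry mirrors the pCRISPR-Cas3 spacer slot: two non-identical CRISPR repeats around a stuffer, fixed annealing sites up/downstream, and a BstBI/NdeI double digest that drops the spacer slot together with the origin-bearing segment. Sequences are randomly generated, NOT the real plasmid.",
  "repeat1": "CGTGTGGCAGTCGCGGTAGCGACAAAGCGTTAC",
  "repeat2": "CTTGCTGCAGTCGCGGTAGCGACATAGAGTGAC",
  "upstream_anneal": "CGACCTGGCGGTGCATCATGTCGGG",
  "downstream_anneal": "GGCAAGACTTGCTGCGCGCCGGAGG",
  "backbone": "CGACCTGGCGGTGCATCATGTCGGGCATATGCGTGTGGCAGTCGCGGTAGCGACAAAGCGTTACTAGGGGTGCTCCATGGGCGAGGCGTGCTTGCTGCAGTCGCGGTAGCGACATAGAGTGACCCGCCCGGAGAGCTCGGCAGCCCGGCCGAACCCGCAGGCTGCCACCCCGGTTTGCGCTAGTTCGAAGGCAAGACTTGCTGCGCGCCGGAGGTGATTCCGTTCTGGGATGACCACAATATTGGTCCGTAATCGGCGTGGTGACTCACGCCGGGTGGCGAGCAACATGGTCCG",
  "enzymes": {
    "NdeI": "CATATG",
    "HindIII": "AAGCTT",
    "BstBI": "TTCGAA",
    "NcoI": "CCATGG",
    "SnaBI": "TACGTA"
  },
  "digestion_enzymes": ["BstBI", "NdeI"],
  "min_overlap": 20,
  "spacer_len": 34
}
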