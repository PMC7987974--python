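{
  "schema": "agaclust-codon-preferences-v1",
  "comment": "Single preferred codon per amino acid used by reverse_translate for synthetic coding sequences. Choices follow high-usage E. coli K-12 codons; any synonymous table may be substituted.",
  "preferred_codons": {
    "A": "GCG",
    "C": "UGC",
    "D": "GAU",
    "E": "GAA",
    "F": "UUU",
    "G": "GGC",
    "H": "CAU",
    "I": "AUC",
    "K": "AAA",
    "L": "CUG",
    "M": "AUG",
    "N": "AAC",
    "P": "CCG",
    "Q": "CAG",
    "R": "CGU",
    "S": "AGC",
    "T": "ACC",
    "V": "GUG",
    "W": "UGG",
    "Y": "UAU"
  }
}
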