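{
  "expected_gc3": 0.6910256410256408,
  "family_frequencies": {
    "A": {
      "GCA": 0.15000000000000002,
      "GCC": 0.35,
      "GCG": 0.35,
      "GCT": 0.15000000000000002
    },
    "C": {
      "TGC": 0.7,
      "TGT": 0.30000000000000004
    },
    "D": {
      "GAC": 0.7,
      "GAT": 0.30000000000000004
    },
    "E": {
      "GAA": 0.30000000000000004,
      "GAG": 0.7
    },
    "F": {
      "TTC": 0.7,
      "TTT": 0.30000000000000004
    },
    "G": {
      "GGA": 0.15000000000000002,
      "GGC": 0.35,
      "GGG": 0.35,
      "GGT": 0.15000000000000002
    },
    "H": {
      "CAC": 0.7,
      "CAT": 0.30000000000000004
    },
    "I": {
      "ATA": 0.23076923076923078,
      "ATC": 0.5384615384615384,
      "ATT": 0.23076923076923078
    },
    "K": {
      "AAA": 0.30000000000000004,
      "AAG": 0.7
    },
    "L": {
      "CTA": 0.10000000000000002,
      "CTC": 0.2333333333333333,
      "CTG": 0.2333333333333333,
      "CTT": 0.10000000000000002,
      "TTA": 0.10000000000000002,
      "TTG": 0.2333333333333333
    },
    "N": {
      "AAC": 0.7,
      "AAT": 0.30000000000000004
    },
    "P": {
      "CCA": 0.15000000000000002,
      "CCC": 0.35,
      "CCG": 0.35,
      "CCT": 0.15000000000000002
    },
    "Q": {
      "CAA": 0.30000000000000004,
      "CAG": 0.7
    },
    "R": {
      "AGA": 0.10000000000000002,
      "AGG": 0.2333333333333333,
      "CGA": 0.10000000000000002,
      "CGC": 0.2333333333333333,
      "CGG": 0.2333333333333333,
      "CGT": 0.10000000000000002
    },
    "S": {
      "AGC": 0.2333333333333333,
      "AGT": 0.10000000000000002,
      "TCA": 0.10000000000000002,
      "TCC": 0.2333333333333333,
      "TCG": 0.2333333333333333,
      "TCT": 0.10000000000000002
    },
    "T": {
      "ACA": 0.15000000000000002,
      "ACC": 0.35,
      "ACG": 0.35,
      "ACT": 0.15000000000000002
    },
    "V": {
      "GTA": 0.15000000000000002,
      "GTC": 0.35,
      "GTG": 0.35,
      "GTT": 0.15000000000000002
    },
    "Y": {
      "TAC": 0.7,
      "TAT": 0.30000000000000004
    }
  },
  "gc3_bias": 0.7,
  "max_aa": 90,
  "min_aa": 60,
  "n_sequences": 5,
  "name": "mini_virus",
  "protein_template": null,
  "seed": 2024
}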