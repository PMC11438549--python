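{
  "_comment": "Published per-residue scales used by the physico-chemical descriptors. hydrophobicity: Eisenberg consensus scale (Eisenberg et al. 1984). boman: per-residue protein-interaction potential values (Boman 2003, from Radzicka & Wolfenden transfer free energies; Pro unmeasured, set to 0). pka: EMBOSS ionizable-group pKa set including the peptide termini.",
  "hydrophobicity_eisenberg": {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29,
    "Q": -0.85, "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38,
    "L": 1.06, "K": -1.50, "M": 0.64, "F": 1.19, "P": 0.12,
    "S": -0.18, "T": -0.05, "W": 0.81, "Y": 0.26, "V": 1.08
  },
  "boman": {
    "L": -4.92, "I": -4.92, "V": -4.04, "F": -2.98, "M": -2.35,
    "W": -2.33, "A": -1.81, "C": -1.28, "G": -0.94, "Y": -0.14,
    "T": 2.57, "S": 3.40, "H": 4.66, "Q": 5.54, "K": 5.55,
    "N": 6.64, "E": 6.81, "D": 8.72, "R": 14.92, "P": 0.0
  },
  "pka": {
    "n_terminus": 8.6,
    "c_terminus": 3.6,
    "positive_side_chains": {"K": 10.8, "R": 12.5, "H": 6.5},
    "negative_side_chains": {"D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}
  }
}
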