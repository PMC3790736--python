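{
  "comment": "AMBER-style residue templates: atom counts include hydrogens; internal deoxyribonucleotides carry one phosphate (formal charge -1). Terminal deltas: a 5'-terminal residue lacks the phosphate group (P, OP1, OP2 removed, HO5' added: -2 atoms, +1 charge); a 3'-terminal residue gains HO3' (+1 atom).",
  "residues": {
    "DA": {"atoms": 32, "charge": -1},
    "DC": {"atoms": 30, "charge": -1},
    "DG": {"atoms": 33, "charge": -1},
    "DT": {"atoms": 32, "charge": -1},
    "HOH": {"atoms": 3, "charge": 0},
    "NA": {"atoms": 1, "charge": 1},
    "CL": {"atoms": 1, "charge": -1}
  },
  "terminal": {
    "five_prime": {"atoms": -2, "charge": 1},
    "three_prime": {"atoms": 1, "charge": 0}
  }
}
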