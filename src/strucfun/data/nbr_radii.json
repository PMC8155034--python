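{
  "_comment": "Per-amino-acid neighbor radii (Angstroms) for NBR-NBR contact maps: a potential interaction sphere covered by the side chain over its conformations, measured from the neighbor atom (C-beta; C-alpha for glycine). Approximate values following the Rosetta convention; configurable via build_contact_map(radii=...).",
  "A": 3.5, "R": 6.1, "N": 4.4, "D": 4.4, "C": 4.1,
  "Q": 5.0, "E": 4.9, "G": 3.1, "H": 4.9, "I": 4.2,
  "L": 4.3, "K": 5.7, "M": 4.8, "F": 5.1, "P": 3.8,
  "S": 3.7, "T": 3.9, "V": 3.9, "W": 5.6, "Y": 5.4
}
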