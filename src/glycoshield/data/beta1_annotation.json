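{
  "subunit": "beta1",
  "gene": "SCN1B",
  "ig_start": 19,
  "ig_end": 144,
  "linker_anchor": 154,
  "tm_start": 160,
  "contour_per_residue_A": 3.63,
  "notes": "Ig-domain boundary and anchor residue (M154) per the extracellular topology of beta1; the linker runs from the Ig C-terminal boundary (145) through the anchor; residues between the anchor and the first transmembrane residue set the membrane anchoring offset."
}
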