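{
  "description": "Default 64-symbol SMILES base alphabet. The published alphabet was never enumerated, so this table is a reconstruction covering the organic subset, aromatic lowercase atoms, common two-character elements, ring-bond digits and SMILES punctuation; it is config-overridable and vocabularies can also be derived from a corpus.",
  "symbols": [
    "Br", "Cl", "Si", "Se", "As", "Te", "Li", "Na", "Mg", "Al",
    "Ca", "Fe", "Mn", "Co", "Ni", "Cu", "Zn", "Sn", "Ag", "Pt",
    "B", "C", "N", "O", "P", "S", "F", "I", "K", "H",
    "b", "c", "n", "o", "p", "s",
    "0", "1", "2", "3", "4", "5", "6", "7", "8", "9",
    "[", "]", "(", ")", "=", "#", "-", "+", ".", "/", "\\",
    "@@", "@", ":", "%", "*", "~", "$"
  ]
}
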