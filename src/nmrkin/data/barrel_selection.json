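{
  "comment": "58 C-alpha fitting frame over the eight beta-barrel strands. Approximation: strand segments taken between the variable-loop boundaries (L1 38-51, L2 70-76, L3 95-105, L4 125-132); override with --fit-selection for a curated strand list.",
  "chain": null,
  "residues": [30, 31, 32, 33, 34, 35, 36, 37,
               52, 53, 54, 55, 56, 57, 58,
               63, 64, 65, 66, 67, 68, 69,
               77, 78, 79, 80, 81, 82, 83,
               88, 89, 90, 91, 92, 93, 94,
               106, 107, 108, 109, 110, 111, 112,
               118, 119, 120, 121, 122, 123, 124,
               133, 134, 135, 136, 137, 138, 139, 140],
  "atoms": ["CA"]
}
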