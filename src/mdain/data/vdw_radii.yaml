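# Heavy-atom van der Waals radii (Angstrom), Bondi-style set.
# Contact threshold for an atom pair is r(u) + r(v) + margin; results depend on
# this table, so it ships as an editable file and is recorded in output metadata.
radii:
  C: 1.70
  N: 1.55
  O: 1.52
  S: 1.80
  P: 1.80
  F: 1.47
  CL: 1.75
  BR: 1.85
  I: 1.98
  SE: 1.90
  NA: 2.27
  K: 2.75
  MG: 1.73
  CA: 2.31
  ZN: 1.39
  FE: 1.80
  LI: 1.82
default: 1.70
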