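# Subsegment parsing of the LeuT sequence (residues 1-515): each TM helix split
# into extracellular (e), middle (m) and intracellular (i) sections, plus loops
# (EL*/IL*) and the N terminus.  Region labels drive the 2-D network layout.
scheme_name: leut
entries:
  - {name: NT,    first: 1,   last: 9,   region: terminus}
  - {name: TM1i,  first: 10,  last: 19,  region: i}
  - {name: TM1m,  first: 20,  last: 27,  region: m}
  - {name: TM1e,  first: 28,  last: 37,  region: e}
  - {name: EL1,   first: 38,  last: 40,  region: loop}
  - {name: TM2e,  first: 41,  last: 46,  region: e}
  - {name: TM2m,  first: 47,  last: 56,  region: m}
  - {name: TM2i,  first: 57,  last: 70,  region: i}
  - {name: IL1,   first: 71,  last: 87,  region: loop}
  - {name: TM3i,  first: 88,  last: 103, region: i}
  - {name: TM3m,  first: 104, last: 108, region: m}
  - {name: TM3e,  first: 109, last: 124, region: e}
  - {name: EL2,   first: 125, last: 165, region: loop}
  - {name: TM4e,  first: 166, last: 174, region: e}
  - {name: TM4i,  first: 175, last: 183, region: i}
  - {name: IL2,   first: 184, last: 190, region: loop}
  - {name: TM5i,  first: 191, last: 200, region: i}
  - {name: TM5e,  first: 201, last: 213, region: e}
  - {name: EL3,   first: 214, last: 240, region: loop}
  - {name: TM6e,  first: 241, last: 249, region: e}
  - {name: TM6m,  first: 250, last: 261, region: m}
  - {name: TM6i,  first: 262, last: 268, region: i}
  - {name: IL3,   first: 269, last: 275, region: loop}
  - {name: TM7i,  first: 276, last: 285, region: i}
  - {name: TM7m,  first: 286, last: 292, region: m}
  - {name: TM7e,  first: 293, last: 306, region: e}
  - {name: EL4a,  first: 307, last: 319, region: loop}
  - {name: EL4b,  first: 320, last: 336, region: loop}
  - {name: TM8e,  first: 337, last: 350, region: e}
  - {name: TM8m,  first: 351, last: 359, region: m}
  - {name: TM8i,  first: 360, last: 369, region: i}
  - {name: IL4,   first: 370, last: 374, region: loop}
  - {name: TM9i,  first: 375, last: 384, region: i}
  - {name: TM9e,  first: 385, last: 395, region: e}
  - {name: EL5,   first: 396, last: 398, region: loop}
  - {name: TM10e, first: 399, last: 406, region: e}
  - {name: TM10m, first: 407, last: 411, region: m}
  - {name: TM10i, first: 412, last: 424, region: i}
  - {name: IL5,   first: 425, last: 446, region: loop}
  - {name: TM11i, first: 447, last: 469, region: i}
  - {name: TM11e, first: 470, last: 477, region: e}
  - {name: EL6,   first: 478, last: 482, region: loop}
  - {name: TM12e, first: 483, last: 492, region: e}
  - {name: TM12i, first: 493, last: 515, region: i}
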