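# Donor / acceptor typing for the polar-interaction channel.
# donors: [heavy donor atom, [names of hydrogens bonded to it]]
# acceptors: heavy acceptor atom names.
# Backbone entries apply to every standard residue; PRO has no backbone N-H.
backbone:
  donors:
    - [N, [H, HN, H1, H2, H3]]
  acceptors: [O, OXT]
residues:
  ALA: {donors: [], acceptors: []}
  GLY: {donors: [], acceptors: []}
  VAL: {donors: [], acceptors: []}
  LEU: {donors: [], acceptors: []}
  ILE: {donors: [], acceptors: []}
  PHE: {donors: [], acceptors: []}
  PRO: {donors: [], acceptors: [], no_backbone_donor: true}
  MET: {donors: [], acceptors: [SD]}
  SER: {donors: [[OG,  [HG, HG1]]],           acceptors: [OG]}
  THR: {donors: [[OG1, [HG1]]],               acceptors: [OG1]}
  CYS: {donors: [[SG,  [HG, HG1]]],           acceptors: [SG]}
  TYR: {donors: [[OH,  [HH]]],                acceptors: [OH]}
  TRP: {donors: [[NE1, [HE1]]],               acceptors: []}
  ASN: {donors: [[ND2, [HD21, HD22]]],        acceptors: [OD1]}
  GLN: {donors: [[NE2, [HE21, HE22]]],        acceptors: [OE1]}
  ASP: {donors: [],                           acceptors: [OD1, OD2]}
  GLU: {donors: [],                           acceptors: [OE1, OE2]}
  LYS: {donors: [[NZ,  [HZ1, HZ2, HZ3]]],     acceptors: []}
  ARG: {donors: [[NE,  [HE]],
                 [NH1, [HH11, HH12]],
                 [NH2, [HH21, HH22]]],        acceptors: []}
  HIS: {donors: [[ND1, [HD1]], [NE2, [HE2]]], acceptors: [ND1, NE2]}
  HSD: {donors: [[ND1, [HD1]]],               acceptors: [NE2]}
  HSE: {donors: [[NE2, [HE2]]],               acceptors: [ND1]}
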