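# Donor/acceptor and formal-charge chemistry for standard residues and the
# synthetic ligand used by the built-in generators.  Edit or replace via the
# `chemistry` argument of the readers and detectors.
#
#   cationic / anionic: res_name -> atom names carrying the formal charge group
#   donors:             res_name -> {donor heavy atom: its proton name}
#   acceptors:          res_name -> atom names able to accept an H bond

cationic:
  ARG: [NE, NH1, NH2, CZ]
  LYS: [NZ]
  HIS: [ND1, NE2]
  LIG: [N1]
anionic:
  ASP: [OD1, OD2]
  GLU: [OE1, OE2]
  LIG: [O1, O2]

donors:
  ARG: {NE: HE, NH1: HH11, NH2: HH21}
  LYS: {NZ: HZ1}
  SER: {OG: HG}
  THR: {OG1: HG1}
  TYR: {OH: HH}
  TRP: {NE1: HE1}
  ASN: {ND2: HD21}
  GLN: {NE2: HE21}
  HIS: {ND1: HD1, NE2: HE2}
  CYS: {SG: HG}
  LIG: {N1: H1}

acceptors:
  ASP: [OD1, OD2]
  GLU: [OE1, OE2]
  ASN: [OD1]
  GLN: [OE1]
  SER: [OG]
  THR: [OG1]
  TYR: [OH]
  HIS: [ND1, NE2]
  MET: [SD]
  LIG: [O1, O2, O3]
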