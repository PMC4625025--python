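# Named diagnostic positions on the synthetic reference template
# (template_synthetic.fasta). Indices are 1-based residue positions on the
# template. The coordinates are a property of the shipped template, not of
# any natural aquaporin; override --positions/--template together when
# anchoring to a real structure-resolved reference.
template_id: mip_template_synthetic
named_positions:
  SDP1: 45
  SDP2: 52
  SDP3: 63
  H2: 88
  NPA_LB1: 100
  NPA_LB2: 101
  NPA_LB3: 102
  PHOS1: 115
  SDP4: 128
  SDP5: 142
  SDP6: 158
  SDP7: 171
  P1: 180
  SDP8: 190
  H5: 205
  P2: 212
  P3: 216
  NPA_LE1: 222
  NPA_LE2: 223
  NPA_LE3: 224
  LE1: 226
  LE2: 231
  P4: 240
  P5: 241
  SDP9: 252
  PHOS2: 274
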