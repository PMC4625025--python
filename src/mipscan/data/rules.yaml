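# Subfamily classification cascade for plant MIP/aquaporin diagnostic
# profiles. Rules are evaluated in order; the first rule whose predicate
# holds assigns the subfamily. The order is part of the contract: PIP must
# precede TIP (both are water-type at Froger P4/P5), and the NIP Froger-P5
# test must precede the XIP first-motif tests.
subfamily_cascade:
  - label: PIP
    name: arr_FHTR
    predicate:
      type: arr_equals
      value: [F, H, T, R]
  - label: NIP
    name: froger_P5_aliphatic
    predicate:
      type: froger_in
      position: P5
      value: [I, L, M]
  - label: XIP
    name: xip_motif_or_P2C
    predicate:
      type: any
      clauses:
        - {type: froger_in, position: P2, value: [C]}
        - {type: npa_lb_startswith, value: S}
        - {type: npa_lb_in, value: [NPV, NPI]}
  - label: TIP
    name: froger_P4Y_and_H2_HN
    predicate:
      type: all
      clauses:
        - {type: froger_in, position: P4, value: [Y]}
        - {type: arr_in, position: H2, value: [H, N]}
  - label: SIP
    name: froger_P4Y
    predicate:
      type: froger_in
      position: P4
      value: [Y]

# ar/R filters characteristic of the three XIP subgroups. Matching is
# MISSING-tolerant: positions absent from the profile are ignored, and the
# first listed pattern compatible with the observed residues wins.
xip_arr_patterns:
  XIP1: [V, F, V, R]
  XIP2: [I, F, V, R]
  XIP3: [V, Y, A, R]

# NIP subgroup rules (ar/R-filter nomenclature). Checked in listed order.
nip_subgroups:
  - label: NIP I
    arr_any_of:
      - [W, V, A, R]
      - [W, A, A, R]
  - label: NIP III
    arr_any_of:
      - [G, S, G, R]
  - label: NIP II
    npa_any_of: [NPS, NPV]
    h2_any_of: [A, T]
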