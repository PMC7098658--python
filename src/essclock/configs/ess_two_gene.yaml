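# Extended S-System two-gene clock fixture (frozen ground truth).
#
# Circuit: protein P2 activates gene G1 (positive kinetic order); G1 is also
# driven additively by light at dawn; P1 is translated from G1; P1 inhibits
# gene G2 (negative kinetic order); P2 is translated from G2.  A delayed
# negative feedback loop entrained by the light-dark cycle.
#
# Free parameters (K_Theta = 12): the four production rate constants alpha,
# the four degradation rates beta, the two regulatory kinetic orders, the
# G1->P1 translation exponent and the light gain.  The G2->P2 translation
# exponent is fixed at 1.
species:
  - {name: G1, role: mRNA}
  - {name: P1, role: protein_aggregate}
  - {name: G2, role: mRNA}
  - {name: P2, role: protein_aggregate}
dynamics:
  G1:
    alpha: {value: 0.25, free: true}
    production:
      - {members: [P2], exponent: 2.0, free: true}
    degradation:
      - {rate: 0.30, free: true}
    light:
      - {gain: 0.08, light: true, free: true}
  P1:
    alpha: {value: 0.30, free: true}
    production:
      - {members: [G1], exponent: 1.0, free: true}
    degradation:
      - {rate: 0.25, free: true}
  G2:
    alpha: {value: 0.25, free: true}
    production:
      - {members: [P1], exponent: -2.5, free: true}
    degradation:
      - {rate: 0.30, free: true}
  P2:
    alpha: {value: 0.30, free: true}
    production:
      - {members: [G2], exponent: 1.0, free: false}
    degradation:
      - {rate: 0.25, free: true}
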