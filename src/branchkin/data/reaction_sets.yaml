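# Reaction-set definitions for the five network variants: which of the 29
# reactions each includes, which rate constants float during global fitting,
# and the baseline / variable reaction conditions (concentrations in uM).
# `k-N` denotes the reverse rate constant of reaction N; `k_fil_on` is a
# single global variable applied to reactions 13, 19, 21 and 22.
variants:
  spontaneous:
    reactions: [1, 2, 3, 4]
    floated: [k1, k-1, k2, k-2, k3]
    base_conditions: {}
    variable: {actin_monomer: [2.0, 3.0, 4.0, 5.0, 6.0]}
  vca_only:
    reactions: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12]
    floated: [k9, k-9, k10, k-10, k11, k-11, k12]
    base_conditions: {actin_monomer: 3.0}
    variable: {gst_vca_monomeric: [0.0, 0.02, 0.04, 0.08, 0.1, 0.2, 0.6, 0.8, 1.0]}
  branching:
    reactions: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 16, 17, 18,
                19, 20, 21, 22, 23, 24, 25]
    floated: [k25]
    base_conditions: {actin_monomer: 3.0, arp23: 0.05}
    variable: {gst_vca_monomeric: [0.0, 0.01, 0.025, 0.05, 0.1, 0.15, 0.25, 0.5, 1.0]}
  displacement:
    reactions: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 16, 17, 18,
                19, 20, 21, 22, 23, 24, 25, 26, 27, 28]
    floated: [k_fil_on, k25, k28]
    base_conditions: {actin_monomer: 3.0, arp23: 0.02, gst_vca_monomeric: 0.1}
    variable: {cortactin: [0.0, 0.005, 0.025, 0.075, 0.1, 0.25, 1.0]}
  recycling:
    reactions: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 16, 17, 18,
                19, 20, 21, 22, 23, 24, 25, 29]
    floated: [k29, k-29]
    base_conditions: {actin_monomer: 3.0, arp23: 0.02, gst_vca_monomeric: 0.1}
    variable: {cortactin: [0.0, 0.005, 0.025, 0.075, 0.1, 0.25, 1.0]}
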