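# Assessment-unit configuration for T204: ABC transporter plus MlaD
# hexamer extending into a helical tube. Structurally similar subunit
# interfaces are grouped into eight 'super' interfaces (1-8); groups
# 1-2 (the tube and the C-terminal domain) form AU204.1, groups 3-8
# (the transmembrane domain organisation) form AU204.2. AU204.1 keeps
# K = 2: performance is the best predicted interface among the tube
# interfaces (group 1) plus the C-terminal-domain interface (group 2).
assessment_units:
  - au_id: AU204.1
    member_targets: [T204]
    interface_groups:
      T204.1:   # helical tube, neighbouring chains (grouped copies)
        - {member: T204.1a, target: T204, chain_pairs: [[A, B]]}
        - {member: T204.1b, target: T204, chain_pairs: [[B, C]]}
        - {member: T204.1c, target: T204, chain_pairs: [[C, D]]}
        - {member: T204.1d, target: T204, chain_pairs: [[D, E]]}
        - {member: T204.1e, target: T204, chain_pairs: [[E, F]]}
      T204.2:   # C-terminal domain of non-neighbouring tube chains
        - {member: T204.2a, target: T204, chain_pairs: [[E, A]]}
  - au_id: AU204.2
    member_targets: [T204]
    interface_groups:
      T204.3:   # TM heterodimer
        - {member: T204.3a, target: T204, chain_pairs: [[G, H]]}
      T204.4:   # TM / MlaD
        - {member: T204.4a, target: T204, chain_pairs: [[G, A]]}
      T204.5:   # TM / MlaD (second mode)
        - {member: T204.5a, target: T204, chain_pairs: [[H, B]]}
      T204.6:   # ABC homodimer
        - {member: T204.6a, target: T204, chain_pairs: [[I, J]]}
      T204.7:   # TM / ABC
        - {member: T204.7a, target: T204, chain_pairs: [[G, I]]}
      T204.8:   # MlaD hexamer interface
        - {member: T204.8a, target: T204, chain_pairs: [[A, F]]}
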