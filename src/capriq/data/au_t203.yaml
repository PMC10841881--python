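# Assessment-unit configuration for T203: a trimer of peptide-bound
# trimers, (A3B1)3. AU203.1 groups the three distinct interfaces of the
# inner (minor) trimer; AU203.2 is the single unique inter-trimer
# interface of the outer (major) trimer. Symmetric replicas across the
# three trimer copies are listed as members of the same group; the best
# replica represents the group.
assessment_units:
  - au_id: AU203.1
    member_targets: [T203]
    interface_groups:
      T203.1:
        - {member: T203.1a, target: T203, chain_pairs: [[A, B]]}
        - {member: T203.1b, target: T203, chain_pairs: [[B, C]]}
        - {member: T203.1c, target: T203, chain_pairs: [[A, C]]}
      T203.2:
        - {member: T203.2a, target: T203, chain_pairs: [[C, P]]}
      T203.3:
        - {member: T203.3a, target: T203, chain_pairs: [[A, P]]}
  - au_id: AU203.2
    member_targets: [T203]
    interface_groups:
      T203.4:
        - {member: T203.4a, target: T203, chain_pairs: [[A, D]]}
        - {member: T203.4b, target: T203, chain_pairs: [[D, G]]}
        - {member: T203.4c, target: T203, chain_pairs: [[G, A]]}
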