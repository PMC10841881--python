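# Assessment-unit configuration for the T219/T220/T221 family: three
# solved structures of the same RuvB hexamer binding zero, one or two
# RuvA molecules. AU219 (the apo hexamer) groups nine member
# interfaces: per structure, the tight super-interface (A:B and B:C),
# the intermediate one (C:D and A:F) and the loose one (D:E and E:F),
# taken across all three structures. AU220 (RuvB:RuvA) groups the
# similar RuvB/RuvA interfaces of T220 and T221. The best model over
# all member targets submitted by a group represents the AU.
assessment_units:
  - au_id: AU219
    member_targets: [T219, T220, T221]
    interface_groups:
      AU219.tight:
        - {member: T219.1, target: T219, chain_pairs: [[A, B], [B, C]]}
        - {member: T220.1, target: T220, chain_pairs: [[A, B], [B, C]]}
        - {member: T221.1, target: T221, chain_pairs: [[A, B], [B, C]]}
      AU219.intermediate:
        - {member: T219.2, target: T219, chain_pairs: [[C, D], [A, F]]}
        - {member: T220.2, target: T220, chain_pairs: [[C, D], [A, F]]}
        - {member: T221.2, target: T221, chain_pairs: [[C, D], [A, F]]}
      AU219.loose:
        - {member: T219.3, target: T219, chain_pairs: [[D, E], [E, F]]}
        - {member: T220.3, target: T220, chain_pairs: [[D, E], [E, F]]}
        - {member: T221.3, target: T221, chain_pairs: [[D, E], [E, F]]}
  - au_id: AU220
    member_targets: [T220, T221]
    interface_groups:
      AU220.4:
        - {member: T220.4, target: T220, chain_pairs: [[D, G]]}
        - {member: T221.4, target: T221, chain_pairs: [[D, G], [E, H]]}
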