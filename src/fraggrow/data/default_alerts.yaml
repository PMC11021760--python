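# Default medicinal-chemistry filter rule set.
#
# This is an explicit, documented list of reactive / unstable / undesirable
# motifs, not a reproduction of any proprietary filter catalogue.  Users may
# replace it wholesale with their own file of the same layout.

structural_alerts:
  acyl_halide:
    smarts: "[CX3](=[OX1])[F,Cl,Br,I]"
    severity: reject
  peroxide:
    smarts: "[OX2][OX2]"
    severity: reject
  geminal_diol:
    smarts: "[CX4]([OX2H])[OX2H]"
    severity: reject
  aliphatic_aldehyde:
    smarts: "[CX3H1](=[OX1])[CX4,#1]"
    severity: reject
  azo_triazene_chain:
    smarts: "[#7]-[#7]=[#7]"
    severity: reject
  michael_acceptor_extreme:
    smarts: "[CX3]=[CX3]-[CX3]=[OX1]"
    severity: reject
  acid_anhydride:
    smarts: "[CX3](=[OX1])[OX2][CX3]=[OX1]"
    severity: reject
  isocyanate:
    smarts: "[NX2]=[CX2]=[OX1,SX1]"
    severity: reject

# Alerts evaluated only against terminal acyclic substituents (enhanced mode).
terminal_alerts:
  terminal_aldehyde:
    smarts: "[CX3H1]=[OX1]"
    severity: reject
  terminal_alkyl_halide:
    smarts: "[CX4][Cl,Br,I]"
    severity: reject
  terminal_thiol:
    smarts: "[SX2H]"
    severity: reject

allowed_elements: [C, H, N, O, S, F, Cl, Br]

ring_size_min: 3
ring_size_max: 8

# Property bounds applied in enhanced mode only.
property_bounds:
  mw_max: 550.0
  heavy_atoms_max: 40
  rotatable_bonds_max: 10
  ring_count_max: 6
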