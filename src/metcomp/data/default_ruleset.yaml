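# Default permeability ruleset.
#
# one_param: class by TPSA alone; the values are upper bounds of the H, MH
# and ML bands (Angstrom^2); anything above the last bound is L. A compound
# exactly on a bound falls into the less-permeable class and is flagged.
#
# three_param: ordered decision list over TPSA, computed logP and H-bond
# donor count; first matching rule wins. The logP/HBD clause captures
# amphoteric (zwitterionic) compounds such as free amino acids, which
# permeate poorly despite moderate polar surface area.
one_param:
  H: 60.0
  MH: 120.0
  ML: 200.0
three_param:
  - {class: ML, tpsa_gt: 140.0}
  - {class: ML, logp_gt: 0.5, hbd_ge: 3}
  - {class: H, tpsa_le: 120.0}
  - {class: MH, tpsa_le: 135.0}
  - {class: ML, tpsa_le: 200.0}
  - {class: L}
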