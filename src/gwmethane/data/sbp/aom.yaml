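# Sequential binary partition for anaerobic oxidation of CH4 (AOM). Row 1
# separates products (HCO3, HS) from reactants (CH4, SO4); row 2 partitions
# the products; row 3 partitions the reactants (CH4 vs SO4).
name: AOM
parts: [HCO3, CH4, SO4, HS]
matrix:
  - [1, -1, -1, 1]
  - [1, 0, 0, -1]
  - [0, 1, -1, 0]
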