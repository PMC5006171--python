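# Sequential binary partition for the CO2-reduction (hydrogenotrophic
# methanogenesis) pathway. Row 1 separates the product (CH4) from the
# reactants; rows 2-3 partition the reactants (H2 vs H+/HCO3, then HCO3 vs H+).
name: CO2_REDUCTION
parts: [H, H2, HCO3, CH4]
matrix:
  - [-1, -1, -1, 1]
  - [-1, 1, -1, 0]
  - [-1, 0, 1, 0]
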