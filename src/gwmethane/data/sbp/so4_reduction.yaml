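# Sequential binary partition for the sulfate-reduction pathway. Row 1
# separates the product (HS-) from the reactants; rows 2-3 partition the
# reactants (H2 vs SO4/H+, then SO4 vs H+).
name: SO4_REDUCTION
parts: [SO4, H2, H, HS]
matrix:
  - [-1, -1, -1, 1]
  - [-1, 1, -1, 0]
  - [1, 0, -1, 0]
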