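# Standard-state AQUEOUS thermodynamic constants at 25 °C, molal standard
# state, from standard compilations of aqueous formation enthalpies and free
# energies (kJ/mol). Per-reaction ΔH° and ΔS° are derived from these at load
# time; the printed check values the shipped reactions must reproduce are
# ΔG°(25 °C) ≈ −229 (CO2 reduction), −262 (SO4 reduction) and ≈ −33 (AOM).
species:
  H:    {dGf: 0.0,     dHf: 0.0,     charge: 1,  elements: {H: 1}}
  H2:   {dGf: 17.57,   dHf: -4.2,    charge: 0,  elements: {H: 2}}
  H2O:  {dGf: -237.18, dHf: -285.83, charge: 0,  elements: {H: 2, O: 1}}
  HCO3: {dGf: -586.8,  dHf: -691.99, charge: -1, elements: {H: 1, C: 1, O: 3}}
  CH4:  {dGf: -34.33,  dHf: -89.04,  charge: 0,  elements: {C: 1, H: 4}}
  SO4:  {dGf: -744.5,  dHf: -909.27, charge: -2, elements: {S: 1, O: 4}}
  HS:   {dGf: 12.05,   dHf: -17.6,   charge: -1, elements: {H: 1, S: 1}}

# Microbial redox reactions (products positive, reactants negative).
# All three transfer 8 electrons (4 H2 -> 8 e-; AOM: S(+6) -> S(-2)).
reactions:
  CO2_REDUCTION:
    stoichiometry: {HCO3: -1, H2: -4, H: -1, CH4: 1, H2O: 3}
    n_electrons: 8
  SO4_REDUCTION:
    stoichiometry: {SO4: -1, H2: -4, H: -1, HS: 1, H2O: 4}
    n_electrons: 8
  AOM:
    stoichiometry: {CH4: -1, SO4: -1, HCO3: 1, HS: 1, H2O: 1}
    n_electrons: 8
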