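# Column dictionary for the sample-table CSV schema (read_samples/write_samples).
# Censoring convention: a concentration cell "<X" marks a value below the
# detection limit X; empty cells are absent fields (never zero). An optional
# "<prefix>_below_dl" flag column (true/1) is accepted as an alternative.
columns:
  sample_id:        {type: string, required: true,  units: null, description: Unique well/sample identifier}
  aquifer_group:    {type: enum,   required: true,  units: null, values: [ALLUVIUM, SHALLOW_COAL_MEASURES, GAS_RESERVOIR, KUMBARILLA], description: Hydrostratigraphic group}
  screen_depth_m:   {type: float,  required: false, units: m, description: Well screen depth}
  temperature_c:    {type: float,  required: true,  units: degC, description: Field water temperature, valid (0, 60)}
  ph:               {type: float,  required: true,  units: null, description: Field pH, valid (2, 12)}
  do_mgl:           {type: float,  required: false, units: mg/L, description: Dissolved oxygen}
  na_mgl:           {type: censored_float, required: false, units: mg/L, description: Sodium}
  k_mgl:            {type: censored_float, required: false, units: mg/L, description: Potassium}
  ca_mgl:           {type: censored_float, required: false, units: mg/L, description: Calcium}
  mg_mgl:           {type: censored_float, required: false, units: mg/L, description: Magnesium}
  hco3_mgl:         {type: censored_float, required: false, units: mg/L, description: Bicarbonate (as bicarbonate alkalinity)}
  cl_mgl:           {type: censored_float, required: false, units: mg/L, description: Chloride}
  br_mgl:           {type: censored_float, required: false, units: mg/L, description: Bromide}
  so4_mgl:          {type: censored_float, required: false, units: mg/L, description: Sulfate}
  no3_mgl:          {type: censored_float, required: false, units: mg/L, description: Nitrate}
  s2_mgl:           {type: censored_float, required: false, units: mg/L, description: Sulfide (S2-)}
  hs_mgl:           {type: censored_float, required: false, units: mg/L, description: Bisulfide (HS-)}
  fe_mgl:           {type: censored_float, required: false, units: mg/L, description: Total dissolved iron}
  mn_mgl:           {type: censored_float, required: false, units: mg/L, description: Total dissolved manganese}
  ch4_ugl:          {type: censored_float, required: false, units: ug/L, description: Dissolved methane}
  doc_mgl:          {type: float,  required: false, units: mg/L, description: Dissolved organic carbon}
  tritium_tu:       {type: float,  required: false, units: TU, description: Tritium activity}
  d13c_ch4_permil:  {type: float,  required: false, units: permil, description: delta 13C of CH4 (VPDB)}
  d2h_ch4_permil:   {type: float,  required: false, units: permil, description: delta 2H of CH4 (VSMOW)}
  d13c_dic_permil:  {type: float,  required: false, units: permil, description: delta 13C of DIC (VPDB)}
  d2h_h2o_permil:   {type: float,  required: false, units: permil, description: delta 2H of water (VSMOW)}
  d18o_h2o_permil:  {type: float,  required: false, units: permil, description: delta 18O of water (VSMOW)}
  d37cl_permil:     {type: float,  required: false, units: permil, description: delta 37Cl (SMOC)}
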