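# Long-format measurement CSV schema (one row per well).
# Concentrations are normalized to mol/L on read; `conc_unit` declares the
# unit used in the file (M, uM, nM, pM, or IU_per_ml for gonadotropin doses,
# converted at 3.9e-6 M per IU/ml).
columns:
  plate_id:            {type: str,   required: true,  doc: plate identifier}
  assay:               {type: enum,  values: [H295R, ER_CALUX, AR_CALUX]}
  mode:                {type: enum,  values: [agonist, antagonist, none]}
  row:                 {type: str,   doc: A-H}
  col:                 {type: int,   doc: 1-12}
  role:                {type: enum,  values: [h295r_treated, sham, standard_curve,
                                              vehicle_control, medium_control,
                                              positive_control]}
  has_cells:           {type: bool,  doc: supernatant originates from hormone-producing wells}
  chemical_id:         {type: str,   nullable: true}
  conc_h295r:          {type: float, nullable: true, doc: nominal concentration in the
                                                          hormone-producing plate}
  conc_standard:       {type: float, nullable: true, doc: standard-compound concentration
                                                          (curve wells only)}
  conc_unit:           {type: enum,  values: [M, uM, nM, pM, IU_per_ml], default: M}
  co_agonist_conc:     {type: float, default: 0.0, doc: reference-agonist concentration in
                                                        antagonist-mode wells (mol/L)}
  bio_rep:             {type: int,   doc: biological replicate 1-3}
  tech_rep:            {type: int,   doc: technical replicate 1-3 (curve wells: duplicate index)}
  rlu_reporter:        {type: float, doc: reporter luminescence, >= 0}
  rlu_viability:       {type: float, doc: same-well viability luminescence, >= 0}
  supernatant_vol_ul:  {type: float}
  total_vol_ul:        {type: float}
invariants:
  - (plate_id, row, col) unique
  - rlu_reporter >= 0 and rlu_viability >= 0
  - supernatant_vol_ul <= total_vol_ul
  - treated and sham wells carry exactly one of conc_h295r / conc_standard
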