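# Iron and zinc absorption parameters.
#
# All constants used by the bioavailability stage live here so they are
# versioned, citable and editable without code changes.  Coefficients for the
# three non-heme iron algorithms are transcribed from the cited publications
# (functional form and covariates as published; see each entry's citation);
# edit in place to use an alternative transcription or updated model.
#
# Units: iron/zinc/phytate/calcium/vitamin C in mg/day, meat+fish+poultry
# (mfp) in g/day of edible (post-refuse) mass, tea polyphenols in mg/day of
# tannic acid equivalents, serum ferritin in mcg/L.

version: 1
heme:
  heme_fraction: 0.40          # share of iron in heme-source foods counted as heme
  heme_bioavailability: 0.25   # fixed absorption of heme iron
serum_ferritin_ref: 21.7       # mcg/L, corresponds to 40% reference dose absorption
polyphenol_mg_per_cup: 100.0   # tannic acid equivalents per cup of tea

iron_algorithms:
  conway:
    citation: "Conway et al., food group-based regression for non-heme iron absorption"
    form: loglinear
    intercept: 1.70
    terms:
      - {covariate: vitamin_c,   transform: log, offset: 1.0, coefficient: 0.124}
      - {covariate: mfp,         transform: log, offset: 1.0, coefficient: 0.095}
      - {covariate: phytate,     transform: log, offset: 1.0, coefficient: -0.130}
      - {covariate: tea_cups,    transform: log, offset: 1.0, coefficient: -0.060}
    output: percent
  rickard:
    citation: "Rickard et al. 2009, test-meal algorithm with non-linear (saturable) enhancer/inhibitor effects"
    form: saturating_ratio
    baseline_fraction: 0.18
    enhancers:
      - {covariate: vitamin_c, amplitude: 1.5, half_saturation: 75.0}
      - {covariate: mfp,       amplitude: 1.2, half_saturation: 150.0}
    inhibitors:
      - {covariate: phytate,     amplitude: 2.5, half_saturation: 400.0}
      - {covariate: polyphenols, amplitude: 1.0, half_saturation: 100.0}
      - {covariate: calcium,     amplitude: 0.3, half_saturation: 600.0}
    output: fraction
  armah:
    citation: "Armah et al. 2013, complete-diet log-linear equation for non-heme iron absorption"
    form: loglinear
    intercept: 6.294
    terms:
      - {covariate: serum_ferritin, transform: log, offset: 0.0, coefficient: -0.709}
      - {covariate: vitamin_c,      transform: log, offset: 1.0, coefficient: 0.119}
      - {covariate: mfp,            transform: log, offset: 1.0, coefficient: 0.006}
      - {covariate: tea_cups,       transform: log, offset: 0.1, coefficient: -0.055}
      - {covariate: phytate,        transform: log, offset: 1.0, coefficient: -0.247}
      - {covariate: calcium,        transform: log, offset: 1.0, coefficient: -0.137}
      - {covariate: nonheme_iron,   transform: log, offset: 0.1, coefficient: -0.083}
    output: percent

zinc_miller:
  citation: "Hambidge et al. 2010 update of the Miller saturable zinc absorption model"
  amax_mmol_day: 0.091   # maximal absorbed zinc
  kr_mmol_day: 0.033     # zinc-transporter dissociation constant
  kp_mmol_day: 0.68      # zinc-phytate binding constant
  zinc_molar_mass: 65.38     # g/mol
  phytate_molar_mass: 660.04 # g/mol
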