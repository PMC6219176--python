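# Estimated-foetal-weight (EFW) formula registry.  Output is always grams.
#
# Variable namespace available to formulas (units explicit in the name):
#   FH_cm      maternal symphysis-fundal height, cm
#   GA_weeks   gestational age, decimal weeks
#   HC_est_mm  foetal head circumference imputed from GA via a growth standard
#   AC_est_mm  foetal abdominal circumference imputed from GA
#   HC_cm, AC_cm, HC_m, AC_m
#              ultrasonic HC / AC in cm or metres; resolved from recorded
#              ultrasound columns when present, otherwise from the
#              growth-standard imputation at the record's GA
#
# forms:
#   linear     EFW = sum(coef * var), 'var' omitted for the intercept
#   fh_offset  EFW = scale * (FH_cm - offset[station])   (Johnson-Toshach)
#   logscale   EFW = base ** sum(coef * prod(factors)), factor = var**pow,
#              optionally ln(var)**pow when log: true
#
# provenance 'published' marks formulas transcribed from their primary
# sources; 'reconstructed' marks approximations rebuilt from secondary
# accuracy reports where the original coefficient tables were unavailable.

models:
  # ---- proposed fundal-height models -------------------------------------
  - model_id: proposed_1
    family: proposed
    predictors: [FH_cm]
    form: linear
    provenance: published
    terms:
      - {coef: -1538.3}
      - {coef: 150.3, var: FH_cm}
  - model_id: proposed_2
    family: proposed
    predictors: [FH_cm, GA_weeks]
    form: linear
    provenance: published
    terms:
      - {coef: -959.0}
      - {coef: -15.8, var: GA_weeks}
      - {coef: 151.2, var: FH_cm}
  - model_id: proposed_3
    family: proposed
    predictors: [FH_cm, HC_est_mm]
    form: linear
    provenance: published
    terms:
      - {coef: -634.3}
      - {coef: 151.2, var: FH_cm}
      - {coef: -2.8, var: HC_est_mm}
  - model_id: proposed_4
    family: proposed
    predictors: [FH_cm, AC_est_mm]
    form: linear
    provenance: published
    terms:
      - {coef: -996.8}
      - {coef: 151.2, var: FH_cm}
      - {coef: -1.6, var: AC_est_mm}

  # ---- clinical comparators (fundal height based) ------------------------
  - model_id: johnson_toshach
    family: clinical
    predictors: [FH_cm, FS_category]
    form: fh_offset
    provenance: published
    scale: 155.0
    offsets:
      above_spines: 12.0
      at_or_below_spines: 11.0
  - model_id: risanto_1
    family: clinical
    predictors: [FH_cm]
    form: linear
    provenance: published
    terms:
      - {coef: -880.0}
      - {coef: 125.0, var: FH_cm}
  - model_id: risanto_2
    family: clinical
    predictors: [FH_cm]
    form: linear
    provenance: published
    terms:
      - {coef: -931.5}
      - {coef: 126.7, var: FH_cm}
  - model_id: niswander
    family: clinical
    predictors: [FH_cm]
    form: linear
    provenance: published  # (FH - 13) * 453.6 / 3, pounds converted to grams
    terms:
      - {coef: -1965.6}
      - {coef: 151.2, var: FH_cm}
  - model_id: mod_niswander
    family: clinical
    predictors: [FH_cm]
    form: linear
    provenance: published  # 1.2 * (FH - 7.7) * 100
    terms:
      - {coef: -924.0}
      - {coef: 120.0, var: FH_cm}
  - model_id: mhaskar
    family: clinical
    predictors: [FH_cm]
    form: linear
    provenance: reconstructed
    terms:
      - {coef: -1740.0}
      - {coef: 145.0, var: FH_cm}
  - model_id: gayatri
    family: clinical
    predictors: [FH_cm]
    form: linear
    provenance: reconstructed
    terms:
      - {coef: -1652.4}
      - {coef: 137.7, var: FH_cm}
  - model_id: buchmann_tlale
    family: clinical
    predictors: [FH_cm]
    form: linear
    provenance: reconstructed
    terms:
      - {coef: -600.0}
      - {coef: 100.0, var: FH_cm}
  - model_id: santjaka
    family: clinical
    predictors: [FH_cm]
    form: linear
    provenance: published
    terms:
      - {coef: 175.7, var: FH_cm}
  - model_id: mongelli_gardosi
    family: clinical
    predictors: [FH_cm]
    form: linear
    provenance: reconstructed
    terms:
      - {coef: 59.1, var: FH_cm}
  - model_id: yiheyis
    family: clinical
    predictors: [FH_cm]
    form: linear
    provenance: reconstructed
    terms:
      - {coef: -1300.0}
      - {coef: 130.0, var: FH_cm}

  # ---- ultrasonic comparators --------------------------------------------
  - model_id: hadlock_1984
    family: ultrasonic
    predictors: [HC_us, AC_us]
    form: logscale
    provenance: published
    base: 10.0
    terms:
      - {coef: 1.182, factors: []}
      - {coef: 0.0273, factors: [{var: HC_cm, pow: 1}]}
      - {coef: 0.07057, factors: [{var: AC_cm, pow: 1}]}
      - {coef: -0.00063, factors: [{var: AC_cm, pow: 2}]}
      - {coef: -0.0002184, factors: [{var: HC_cm, pow: 1}, {var: AC_cm, pow: 1}]}
  - model_id: hadlock_1991
    family: ultrasonic
    predictors: [GA_weeks]
    form: logscale
    provenance: published
    base: 2.718281828459045
    terms:
      - {coef: 0.578, factors: []}
      - {coef: 0.332, factors: [{var: GA_weeks, pow: 1}]}
      - {coef: -0.00354, factors: [{var: GA_weeks, pow: 2}]}
  - model_id: jordaan
    family: ultrasonic
    predictors: [AC_us]
    form: logscale
    provenance: reconstructed
    base: 10.0
    terms:
      - {coef: 0.6328, factors: []}
      - {coef: 0.1881, factors: [{var: AC_cm, pow: 1}]}
      - {coef: -0.0043, factors: [{var: AC_cm, pow: 2}]}
      - {coef: 0.000036239, factors: [{var: AC_cm, pow: 3}]}
  - model_id: weiner_2
    family: ultrasonic
    predictors: [HC_us, AC_us]
    form: logscale
    provenance: reconstructed
    base: 10.0
    terms:
      - {coef: 1.9037, factors: []}
      - {coef: 0.025, factors: [{var: HC_cm, pow: 1}]}
      - {coef: 0.020, factors: [{var: AC_cm, pow: 1}]}
  - model_id: stirnemann
    family: ultrasonic
    predictors: [HC_us, AC_us]
    form: logscale
    provenance: published
    base: 2.718281828459045
    terms:
      - {coef: 5.084820, factors: []}
      - {coef: -54.06633, factors: [{var: AC_m, pow: 3}]}
      - {coef: -95.80076, factors: [{var: AC_m, pow: 3}, {var: AC_m, pow: 1, log: true}]}
      - {coef: 3.136370, factors: [{var: HC_m, pow: 1}]}
  - model_id: sotiriadis
    family: ultrasonic
    predictors: [HC_us, AC_us]
    form: logscale
    provenance: reconstructed
    base: 10.0
    terms:
      - {coef: 1.9084, factors: []}
      - {coef: 0.027, factors: [{var: HC_cm, pow: 1}]}
      - {coef: 0.019, factors: [{var: AC_cm, pow: 1}]}
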