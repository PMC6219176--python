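# Ultrasonic growth standards: foetal head circumference (HC) and abdominal
# circumference (AC) medians as functions of gestational age.
#
# Each curve is a sum of terms  coef * GA**pow * ln(GA)**logpow  with GA in
# decimal weeks and the result in millimetres.
#
# The international standard uses the published INTERGROWTH-21st closed-form
# equations (Papageorghiou et al. 2014) verbatim.  The Australian (Westerway
# et al. 2000) and UK (Loughna et al. 2009, after Chitty) curves are quadratic
# representations fitted once to the published chart medians; the source
# papers report low-order polynomial regressions of the same shape but the
# coefficient tables were not redistributable, so these are reconstructions
# of the charts, accurate to a few millimetres over 14-40 weeks.

standards:
  - standard_id: australian
    biometry: HC
    ga_valid_range: [11.0, 41.0]
    output_unit: mm
    provenance: chart-fit quadratic (Westerway 2000 medians)
    terms:
      - {coef: -128.88165, pow: 0, logpow: 0}
      - {coef: 18.70151, pow: 1, logpow: 0}
      - {coef: -0.17030, pow: 2, logpow: 0}
  - standard_id: australian
    biometry: AC
    ga_valid_range: [11.0, 41.0]
    output_unit: mm
    provenance: chart-fit quadratic (Westerway 2000 medians)
    terms:
      - {coef: -104.66246, pow: 0, logpow: 0}
      - {coef: 14.30287, pow: 1, logpow: 0}
      - {coef: -0.07034, pow: 2, logpow: 0}
  - standard_id: uk
    biometry: HC
    ga_valid_range: [13.0, 42.0]
    output_unit: mm
    provenance: chart-fit quadratic (Loughna 2009 / Chitty medians)
    terms:
      - {coef: -129.36134, pow: 0, logpow: 0}
      - {coef: 18.90546, pow: 1, logpow: 0}
      - {coef: -0.18122, pow: 2, logpow: 0}
  - standard_id: uk
    biometry: AC
    ga_valid_range: [13.0, 42.0]
    output_unit: mm
    provenance: chart-fit quadratic (Loughna 2009 / Chitty medians)
    terms:
      - {coef: -107.15336, pow: 0, logpow: 0}
      - {coef: 14.25473, pow: 1, logpow: 0}
      - {coef: -0.07359, pow: 2, logpow: 0}
  - standard_id: international
    biometry: HC
    ga_valid_range: [14.0, 42.0]
    output_unit: mm
    provenance: INTERGROWTH-21st published equation
    terms:
      - {coef: -28.2849, pow: 0, logpow: 0}
      - {coef: 1.69267, pow: 2, logpow: 0}
      - {coef: -0.397485, pow: 2, logpow: 1}
  - standard_id: international
    biometry: AC
    ga_valid_range: [14.0, 42.0]
    output_unit: mm
    provenance: INTERGROWTH-21st published equation
    terms:
      - {coef: -81.3243, pow: 0, logpow: 0}
      - {coef: 11.6772, pow: 1, logpow: 0}
      - {coef: -0.000561865, pow: 3, logpow: 0}
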