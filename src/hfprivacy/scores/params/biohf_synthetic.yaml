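# SYNTHETIC Barcelona BioHF (biomarker-free) parameter set.
#
# The original publication's Cox coefficients and baseline survival are not
# redistributable here; this file is a stand-in that preserves the model
# STRUCTURE (the 11-variable biomarker-free covariate list, clinically
# sensible coefficient signs, nonincreasing baseline survival) so that the
# engine, the pipeline and all distribution-level analyses are exercised
# end to end.  Do not use for clinical prediction.
#
# mortality(t) = 1 - S0(t) ** exp(lp),  lp = sum(beta * (x - center))
score: BioHF
covariates:
  - {variable: age, transform: linear, coefficient: 0.035, center: 67.0}
  - {variable: sex_male, transform: boolean, coefficient: -0.30, center: 0.70}
  - variable: nyha
    transform: categories
    coefficient: 0.55
    center: 0.40
    # indicator for higher severity; generalized labels map consistently
    mapping: {I: 0, II: 0, III: 1, IV: 1, I/II: 0, III/IV: 1}
  - {variable: lvef, transform: linear, coefficient: -0.025, center: 40.0}
  - {variable: sodium, transform: linear, coefficient: -0.05, center: 139.0}
  - {variable: haemoglobin, transform: linear, coefficient: -0.09, center: 13.0}
  - {variable: egfr, transform: linear, coefficient: -0.012, center: 60.0}
  - {variable: beta_blocker, transform: boolean, coefficient: -0.45, center: 0.85}
  - {variable: acei_arb, transform: boolean, coefficient: -0.35, center: 0.75}
  - {variable: statin, transform: boolean, coefficient: -0.20, center: 0.55}
  - {variable: loop_diuretic, transform: boolean, coefficient: 0.40, center: 0.70}
baseline_survival:
  1: 0.93
  2: 0.86
  3: 0.80
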