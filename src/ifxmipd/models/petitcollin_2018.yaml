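# Structure stub for the published model named below. Typical values and
# effect coefficients are placeholders (null) to be transcribed from the
# original publication before use; the loader refuses files with placeholders.

schema_version: 1
name: petitcollin_2018
n_compartments: 1
time_unit: day
typical:
  CL: null
  Vc: null
covariate_effects:
  - {target: CL, covariate: ALB, form: power, coefficient: null, reference: null}
  - {target: CL, covariate: TIME, form: piecewise_time_multiplier, coefficient: null, onset_h: null}
random:
  iiv: {CL: null, Vc: null}
error:
  sigma_prop: null
  sigma_add: null
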