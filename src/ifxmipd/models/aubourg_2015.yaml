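# Structure stub for the published model named below. Typical values and
# effect coefficients are placeholders (null) to be transcribed from the
# original publication before use; the loader refuses files with placeholders.

schema_version: 1
name: aubourg_2015
n_compartments: 2
time_unit: day
typical:
  CL: null
  Vc: null
  Q: null
  Vp: null
covariate_effects:
  - {target: CL, covariate: SEX, form: binary_multiplier, coefficient: null}
  - {target: Vc, covariate: SEX, form: binary_multiplier, coefficient: null}
  - {target: Vc, covariate: WT, form: power, coefficient: null, reference: null}
random:
  iiv: {CL: null, Vc: null}
error:
  sigma_prop: null
  sigma_add: null
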