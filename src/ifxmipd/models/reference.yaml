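# Fully parameterized reference model used by the test suite and examples.
# A generic 2-compartment IV-infusion monoclonal-antibody model with plausible
# infliximab-like values. This is a package-defined construct; it is NOT a
# transcription of any published infliximab model.
schema_version: 1
name: reference
n_compartments: 2
time_unit: day
typical:
  CL: 0.3     # L/day
  Vc: 3.5     # L
  Q: 0.1      # L/day
  Vp: 1.5     # L
covariate_effects:
  - {target: CL, covariate: WT, form: power, coefficient: 0.75, reference: 70.0}
  - {target: Vc, covariate: WT, form: power, coefficient: 1.0, reference: 70.0}
  - {target: Vp, covariate: WT, form: power, coefficient: 1.0, reference: 70.0}
  - {target: CL, covariate: ALB, form: power, coefficient: -1.0, reference: 4.35}
  - {target: CL, covariate: ADA_POS, form: binary_multiplier, coefficient: 1.6}
random:
  iiv: {CL: 0.09, Vc: 0.0625}   # ω² (log scale): 30% / 25% CV
  iov_cl: 0.04                  # π² (log scale): 20% CV per occasion
error:
  sigma_prop: 0.2               # proportional SD
  sigma_add: 0.05               # µg/mL
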