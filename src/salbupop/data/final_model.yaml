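# Final population PK model for oral salbutamol (packaged default).
# Two-compartment disposition, transit-compartment first-order absorption,
# normal interindividual variability, combined residual error on the
# ug/mL concentration scale. Apparent (``/F``) parameterization.
parameters: [Mtt, Ktr, ka, Cl, V1, Q, V2]
theta:
  Mtt: 9.50      # h, mean transit time
  Ktr: 0.15      # 1/h, transit rate
  ka: 2.91       # 1/h, absorption rate constant
  Cl: 140.0      # L/h, apparent clearance Cl/F
  V1: 77.5       # L, apparent central volume V1/F
  Q: 48.9        # L/h, apparent intercompartmental clearance Q/F
  V2: 130.0      # L, apparent peripheral volume V2/F
omega:           # SD of the additive normal random effect, same units as theta
  Mtt: 0.43
  Ktr: 0.32
  ka: 0.41
  Cl: 0.38
  V1: 0.36
  Q: 0.92
  V2: 0.87
error:
  a: 1.9e-05     # ug/mL, additive component
  b: 1.5e-03     # proportional component
  form: combined2   # sd = sqrt(a^2 + b^2 f^2); 'combined1' gives a + b*f
links: []        # covariate links (none in the packaged structural default)
dv_unit: ug/mL
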