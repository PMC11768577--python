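# Salbutamol physicochemical and disposition parameters (packaged default).
# Plasma clearances in L/h; permeability in 1e-4 cm/s; diffusion in 1e-5 cm^2/s.
name: salbutamol
molecular_weight: 239.32        # g/mol
logp: 0.76
pka_basic: 9.34
pka_acidic: 10.52
solubility_mg_ml: 14.47         # at pH 9.93
solubility_ph: 9.93
diffusion_coeff_1e5_cm2_s: 0.804
blood_plasma_ratio: 1.108       # R_bp
peff_1e4_cm_s: 1.21             # effective jejunal permeability
fraction_unbound: 0.7965        # f_up
hepatic_clearance_l_h: 38.06    # plasma terms
renal_clearance_l_h: 16.32      # plasma terms
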