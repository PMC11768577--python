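# Reference whole-body physiology: organ volumes as fractions of body weight
# (density 1 kg/L) and regional blood flows as fractions of cardiac output,
# for a reference adult (male 73 kg / 176 cm, female 60 kg / 163 cm).
# Values are rounded composites of standard reference-man compilations
# (ICRP Publication 89 and common PBPK physiology tables).
#
# The gut wall is not an explicit compartment; splanchnic arterial flow that
# would perfuse it is carried by `liver_arterial` so that total hepatic blood
# flow (arterial + splenic/portal) is ~25.5% of cardiac output.
reference:
  male:
    weight_kg: 73.0
    height_cm: 176.0
  female:
    weight_kg: 60.0
    height_cm: 163.0

cardiac_output_l_h: 336.0        # 5.6 L/min, reference adult male at rest
cardiac_output_ref_bsa_m2: 1.89  # CO scales linearly with BSA relative to this

volume_fractions:                # fraction of body weight (L/kg)
  male:
    lung: 0.0075
    adipose: 0.25
    muscle: 0.40
    liver: 0.025
    spleen: 0.002
    heart: 0.0045
    brain: 0.020
    kidney: 0.0042
    skin: 0.045
    reproductive: 0.0006
    red_marrow: 0.016
    yellow_marrow: 0.034
    venous_blood: 0.054
    arterial_blood: 0.023
    rest_of_body: 0.1142
  female:
    lung: 0.0075
    adipose: 0.32
    muscle: 0.33
    liver: 0.025
    spleen: 0.002
    heart: 0.0045
    brain: 0.020
    kidney: 0.0042
    skin: 0.045
    reproductive: 0.0006
    red_marrow: 0.016
    yellow_marrow: 0.034
    venous_blood: 0.054
    arterial_blood: 0.023
    rest_of_body: 0.1142

flow_fractions:                  # fraction of cardiac output; lung is in
  liver_arterial: 0.225          # series and receives the full output
  spleen: 0.03
  adipose: 0.05
  muscle: 0.17
  heart: 0.04
  brain: 0.12
  kidney: 0.19
  skin: 0.05
  reproductive: 0.0005
  red_marrow: 0.03
  yellow_marrow: 0.01
  rest_of_body: 0.0845

# Disease / body-habitus modifiers (multiplicative), all configurable.
cirrhosis_a:
  hepatic_flow_multiplier: 0.85        # applied to liver arterial inflow
  hepatic_clint_multiplier: 0.80       # applied to hepatic intrinsic clearance
obese:
  adipose_fraction_multiplier: 1.5     # excess taken from muscle + rest_of_body

# Height reference curves: piecewise linear from age 5 to 20, flat after.
height_model:
  age_knots: [5.0, 20.0, 65.0]
  male_cm: [110.0, 176.0, 176.0]
  female_cm: [110.0, 163.0, 163.0]
  race_offset_cm:
    american: 0.0
    asian: -4.0
    chinese: -3.0
  individual_sd_cm: 5.0
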