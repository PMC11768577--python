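# Default 40-subject virtual cohort: three healthy ethnic groups plus an
# American Child-Pugh A cirrhosis group; 24 male / 16 female overall; BMI-class
# mixes give 4 obese-class subjects among the healthy groups.
seed: 20250101
age_range: [5.0, 65.0]
age_mean: 40.0          # truncated-normal age model within age_range
age_sd: 18.0
groups:
  - name: american_healthy
    race: american
    health_status: healthy
    n: 10
    male_fraction: 0.6
    bmi_class_mix: {normal: 0.6, overweight: 0.2, obese: 0.2}
  - name: asian_healthy
    race: asian
    health_status: healthy
    n: 10
    male_fraction: 0.6
    bmi_class_mix: {normal: 0.6, overweight: 0.3, obese: 0.1}
  - name: chinese_healthy
    race: chinese
    health_status: healthy
    n: 10
    male_fraction: 0.6
    bmi_class_mix: {normal: 0.6, overweight: 0.3, obese: 0.1}
  - name: american_cirrhosis
    race: american
    health_status: cirrhosis_a
    n: 10
    male_fraction: 0.6
    bmi_class_mix: {normal: 0.7, overweight: 0.3, obese: 0.0}
# Opaque CYP expression covariates ("%", lognormal, moments as reported)
cyp2d6: {mean: 1.90, sd: 1.60}
cyp2c19: {mean: 1.30, sd: 1.50}
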