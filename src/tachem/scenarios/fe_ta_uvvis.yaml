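kind: uvvis
wavelength_start: 400.0
wavelength_stop: 900.0
wavelength_step: 2.0
ph_values:
- 4.5
- 4.75
- 5.0
- 5.25
- 5.5
- 5.75
- 6.0
- 6.25
- 6.5
- 6.75
- 7.0
- 7.25
- 7.5
- 7.75
- 8.0
- 8.25
- 8.5
m_total: 2.0e-05
ta_molar_nominal: 2.0e-05
ta_molecular_weight: 1701.2
components:
- name: MTA1
  lambda_max: 580.0
  epsilon_max: 3487.0
  band_fwhm: 150.0
- name: MTA2
  lambda_max: 513.0
  epsilon_max: 7576.0
  band_fwhm: 120.0
k1_ph_profile:
  k_at_ph4: 52.9
  slope: 2.0
  plateau_ph: 5.0
k2_ph_profile:
  k_at_ph4: 3.78
  slope: 1.5
  plateau_ph: 7.0
noise_sd: 0.002
seed: 20210
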