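kind: jobs
total_conc: 2.0e-05
molar_fractions:
- 0.1
- 0.2
- 0.3
- 0.4
- 0.5
- 0.6
- 0.7
- 0.8
- 0.9
n_sites: 4
binding_strength: '.inf'
analytic_wavelength: 570.0
epsilon_per_site: 3472.0
noise_sd: 0.001
seed: 20212
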