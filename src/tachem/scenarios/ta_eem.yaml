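kind: eem
excitation_start: 200.0
excitation_stop: 500.0
excitation_step: 10.0
emission_start: 250.0
emission_stop: 600.0
emission_step: 10.0
components:
- name: peakA
  excitation_peaks:
  - 210.0
  - 260.0
  excitation_widths:
  - 35.0
  - 45.0
  excitation_amplitudes:
  - 1.0
  - 0.45
  emission_peak: 360.0
  emission_width: 80.0
  score_base: 100.0
  score_amplitude: -25.0
  ph_midpoint: 6.5
  ph_scale: 1.0
  quench: true
- name: peakC
  excitation_peaks:
  - 325.0
  excitation_widths:
  - 50.0
  excitation_amplitudes:
  - 1.0
  emission_peak: 405.0
  emission_width: 90.0
  score_base: 1.0
  score_amplitude: 85.0
  ph_midpoint: 7.8
  ph_scale: 0.45
  quench: false
sample_ph_values:
- 3.5
- 4.125
- 4.75
- 5.375
- 6.0
- 6.625
- 7.25
- 7.875
- 8.5
fe_present: false
quench_factor: 0.005
scatter:
  rayleigh1_amp: 2.0
  rayleigh1_width: 4.0
  rayleigh2_amp: 0.6
  rayleigh2_width: 5.0
  raman_amp: 0.08
  raman_width: 4.0
  raman_shift_cm: 3400.0
noise_frac: 0.01
noise_prop: 0.03
seed: 20211
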