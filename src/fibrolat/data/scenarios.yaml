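# The ten canonical internal-lysis modeling scenarios.
# Naming: TN/TK = thin (72.7 nm) / thick (145.4 nm) fibers;
#         L/D  = loose (1.0135 um) / dense (0.22 um) pore size;
#         the trailing number is the tPA molecule count.
# Grid dimensions are near-square best fits to the nominal fiber counts
# (exact for TN-L at 93x93; within 0.5% elsewhere).
# tpa_fibrin_ratio is molecules tPA per fibrin monomer;
# tpa_concentration is molecules per cubic micron (catalog metadata).
- name: TN-L 9350
  fiber_diameter: 72.7
  pore_size: 1.0135
  n_tpa: 9350
  n_fibers: 25761
  grid_nx: 93
  grid_ny: 93
  time_step: 3.424e-4
  record_interval: 10.0
  tpa_fibrin_ratio: 164.0e-6
  tpa_concentration: 0.922
  rng_seed: 1
- name: TN-L 307
  fiber_diameter: 72.7
  pore_size: 1.0135
  n_tpa: 307
  n_fibers: 25761
  grid_nx: 93
  grid_ny: 93
  time_step: 3.424e-4
  record_interval: 10.0
  tpa_fibrin_ratio: 5.40e-6
  tpa_concentration: 0.0303
  rng_seed: 2
- name: TN-D 684
  fiber_diameter: 72.7
  pore_size: 0.22
  n_tpa: 684
  n_fibers: 118558
  grid_nx: 212
  grid_ny: 187
  time_step: 1.613e-5
  record_interval: 100.0
  tpa_fibrin_ratio: 12.0e-6
  tpa_concentration: 0.923
  rng_seed: 3
- name: TN-D 9350
  fiber_diameter: 72.7
  pore_size: 0.22
  n_tpa: 9350
  n_fibers: 118558
  grid_nx: 212
  grid_ny: 187
  time_step: 1.613e-5
  record_interval: 100.0
  tpa_fibrin_ratio: 165.0e-6
  tpa_concentration: 12.6
  rng_seed: 4
- name: TN-D 307
  fiber_diameter: 72.7
  pore_size: 0.22
  n_tpa: 307
  n_fibers: 118558
  grid_nx: 212
  grid_ny: 187
  time_step: 1.613e-5
  record_interval: 100.0
  tpa_fibrin_ratio: 5.40e-6
  tpa_concentration: 0.414
  rng_seed: 5
- name: TK-L 3042
  fiber_diameter: 145.4
  pore_size: 1.0135
  n_tpa: 3042
  n_fibers: 7453
  grid_nx: 55
  grid_ny: 46
  time_step: 3.424e-4
  record_interval: 10.0
  tpa_fibrin_ratio: 53.6e-6
  tpa_concentration: 0.923
  rng_seed: 6
- name: TK-L 9350
  fiber_diameter: 145.4
  pore_size: 1.0135
  n_tpa: 9350
  n_fibers: 7453
  grid_nx: 55
  grid_ny: 46
  time_step: 3.424e-4
  record_interval: 10.0
  tpa_fibrin_ratio: 165.0e-6
  tpa_concentration: 2.84
  rng_seed: 7
- name: TK-L 307
  fiber_diameter: 145.4
  pore_size: 1.0135
  n_tpa: 307
  n_fibers: 7453
  grid_nx: 55
  grid_ny: 46
  time_step: 3.424e-4
  record_interval: 10.0
  tpa_fibrin_ratio: 5.41e-6
  tpa_concentration: 0.0931
  rng_seed: 8
- name: TK-D 307
  fiber_diameter: 145.4
  pore_size: 0.22
  n_tpa: 307
  n_fibers: 34208
  grid_nx: 117
  grid_ny: 98
  time_step: 1.613e-5
  record_interval: 100.0
  tpa_fibrin_ratio: 5.43e-6
  tpa_concentration: 0.923
  rng_seed: 9
- name: TK-D 9350
  fiber_diameter: 145.4
  pore_size: 0.22
  n_tpa: 9350
  n_fibers: 34208
  grid_nx: 117
  grid_ny: 98
  time_step: 1.613e-5
  record_interval: 100.0
  tpa_fibrin_ratio: 165.0e-6
  tpa_concentration: 28.1
  rng_seed: 10
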