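# Default macrophage polarization model parameters.
# Network: transformed Wilson-Cowan circuit for (NFkB, STAT1, STAT6) driven
# by (LPS, IFNg, IL4); unit weights on every interaction arc.
network:
  nodes: [NFkB, STAT1, STAT6]
  stimuli: [LPS, IFNg, IL4]
  act_weights: [[0.0, 1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 0.0]]
  inh_weights: [[0.0, 0.0, 1.0], [0.0, 0.0, 1.0], [0.0, 1.0, 0.0]]
  stim_act_weights: [[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
  stim_inh_weights: [[0.0, 0.0, 0.0], [0.0, 0.0, 0.0], [0.0, 0.0, 0.0]]
  act_offsets: [-1.5, -0.5, 0.0]
  inh_offsets: [-0.1, -0.5, -0.05]
  sigma: [8.0, 8.0, 8.0]
  gamma: [1.0, 1.0, 1.0]
# First-order production/degradation rates (per minute).
rates:
  a: 4.15e-4
  b: 4.15e-4
  c: 1.587e-4
  d: 1.38e-4
  e: 1.157e-5
  f: 9.26e-5
  g: 1.1e-3
  h: 2.0e-3
  i: 5.5e-4
  j: 1.7e-3
# Normal protein abundances (ppm); NFkB is the RELA (p65) value.
abundances:
  STAT1: 531.0
  STAT6: 41.3
  NFkB: 26.5
bifurcation:
  thresholds: [0.25, 0.75]
  sweep_range: [0.0, 2.0]
  n_points: 201
  grid_hi: 2.0
  grid_points: 21
simulation:
  n_agents: 30
  placement_var: 0.25
  move_max: 0.5
  Ts: 0.1
  n_steps: 100
  radius: 4.0
  grid_n: 81
  D: 0.18
  kappa: null
  sensing_reference: 2.0
  stimulus_cap: 4.0
  secretion_scale: 1.0
  deposit_mode: footprint
  source_width: 0.25
  record_fields: false
  use_cache: false
seed: 0
scenario: null
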