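# Study-conditions synthetic run: four-component bilayer around one binding
# pocket, three replicas of 4 us at 1 ns frames, dual-cutoff site detection.
mode: synthetic
seed: 1
output_dir: results/binding_kinetics

synthetic:
  composition: {POPC: 0.45, POPE: 0.30, CDL: 0.20, POPA: 0.05}
  n_lipids: 400            # desk-scale patch; the full system had 8624 lipids
  box: [25.0, 25.0]        # nm
  pocket_center: [12.5, 12.5]
  capture_radius: 1.5      # nm
  diffusion_coeff: {default: 0.05}     # nm^2/ns lateral diffusion
  escape_rate: {CDL: 0.01, default: 0.025}   # 1/ns -> 100 vs 40 ns dwells (2.5x)
  n_frames: 4000           # x 1 ns = 4 us per replica
  frame_interval: 1.0      # ns
  n_replicas: 3

site:
  center: [12.5, 12.5]     # fixed cavity point (float vector); bead indices also accepted
  r_on_nm: 1.8             # entry radius
  r_off_nm: 3.5            # exit buffer radius

bootstrap:
  level: 0.90
  n: 10000
  seed: 0

summary:
  include_truncated: true
  cdl_label: CDL

tau_grid:
  min_ns: 1.0
  max_ns: 3000.0
  n: 24
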