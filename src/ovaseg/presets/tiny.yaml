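# CPU-scale phantom experiment: 10 patients x 2 scans, 2 held-out test
# patients, a narrow (8-filter) four-stage residual U-Net and a short
# schedule. Completes in minutes on one CPU; used by the test suite and
# the acceptance script.
name: tiny
seed: 0
out_root: ./runs
mode: full
phantom:
  n_patients: 10
  scans_per_patient: 2
  n_test_patients: 2
  phantom:
    shape: [24, 96, 96]
    spacing: [5.0, 0.7, 0.7]
preprocess:
  target_spacing: [5.0, 1.4, 1.4]
# rotation/scaling are disabled at phantom resolution: the sparse omental
# deposits are only 2-4 voxels across, and resampling-induced boundary
# label noise of that order suppresses the class entirely
augment:
  p_rotation: 0.0
  p_scaling: 0.0
network:
  variant: resnet_unet
  n_stages: 4
  blocks_per_stage: [1, 2, 6, 3]
  base_filters: 8
  spacing: [5.0, 1.4, 1.4]
train:
  batch_size: 2
  total_steps: 1000
  patch_size: [16, 16, 16]
  n_full_models: 1
  log_every: 50
inference:
  window_size: [16, 16, 16]
evaluate:
  connectivity: 26
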