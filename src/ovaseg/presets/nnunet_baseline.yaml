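# Full-scale baseline recipe as suggested by the self-configuring
# framework: plain six-stage U-Net (two conv-IN-LReLU blocks per stage,
# 32 first-stage filters doubling per stage, capped at 320), 250k batches
# of size 2, SGD with Nesterov momentum 0.99, weight decay 3e-5,
# polynomial learning-rate decay from 0.01 to 0.
name: nnunet_baseline
seed: 0
out_root: ./runs
mode: cv
phantom:
  n_patients: 40
  scans_per_patient: 2
  n_test_patients: 8
preprocess:
  target_spacing: [5.0, 0.7, 0.7]
network:
  variant: baseline_unet
  n_stages: 6
  blocks_per_stage: [2, 2, 2, 2, 2, 2]
  base_filters: 32
  max_filters: 320
  spacing: [5.0, 0.7, 0.7]
train:
  batch_size: 2
  total_steps: 250000
  momentum: 0.99
  weight_decay: 0.00003
  schedule: poly
  peak_lr: 0.01
  patch_size: [32, 128, 128]
  n_full_models: 3
inference:
  window_size: [32, 128, 128]
evaluate:
  connectivity: 26
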