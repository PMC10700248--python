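# Full-scale tuned recipe: four-stage U-Net with a residual encoder of
# 1, 2, 6 and 3 blocks per stage and 32 first-stage filters doubling per
# stage; SGD with Nesterov momentum 0.98, weight decay 1e-4, batch size 4,
# linear warmup + cosine decay peaking at 0.02, 250k steps. Patch and
# window sizes are repo choices (unpublished in the recipe).
name: paper_model
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
  variant: resnet_unet
  n_stages: 4
  blocks_per_stage: [1, 2, 6, 3]
  base_filters: 32
  spacing: [5.0, 0.7, 0.7]
train:
  batch_size: 4
  total_steps: 250000
  momentum: 0.98
  weight_decay: 0.0001
  schedule: warmup_cosine
  peak_lr: 0.02
  patch_size: [32, 128, 128]
  n_full_models: 3
inference:
  window_size: [32, 128, 128]
evaluate:
  connectivity: 26
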