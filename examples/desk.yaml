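# Desk-scale run: 64x64 phantoms, 200 LD/SD pairs, CPU-minutes training.
# Mirrors petcycle.presets.desk_scale_train_config / desk_scale_phantom_spec.

phantom:
  image_size: 64
  pixel_spacing_mm: 2.0
  n_phantoms: 25
  slices_per_phantom: 8
  dose_fraction: 0.2            # 30 s / 150 s frame ratio
  counts_per_suv_standard: 50.0
  psf_fwhm_mm: 6.0
  split: [0.81, 0.14, 0.05]     # train / val / test

train:
  epochs: 8
  batch_size: 2
  lr: 0.003
  sched_T0: 8
  sched_Tmult: 2
  n_critic: 1
  mode: paired
  adv_kind: wgan_gp
  image_side: 64
  perceptual_channels: 8
  generator:
    n_down: 3
    base_channels: 8
    n_residual_blocks: 2
  critic:
    base_channels: 8
    n_layers_per_scale: 3
  loss_weights:
    lambda_idt: 1.0
    lambda_cycle: 1.0
    lambda_pept: 30.0
    lambda_gp: 10.0
  window:
    lo: -15.0
    hi: 30.0
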