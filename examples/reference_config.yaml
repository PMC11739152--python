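# Desk-scale pipeline configuration for the four CLI commands:
#   scoredose synth  -c examples/reference_config.yaml -o runs/data
#   scoredose train  -c examples/reference_config.yaml -d runs/data -o runs/fit
#   scoredose sample -c examples/reference_config.yaml -d runs/data \
#                    -k runs/fit/checkpoint.npz -o runs/pdose
#   scoredose eval   -p runs/pdose -d runs/data -o runs/report
seed: 0

schedule:
  kind: ve          # variance-exploding; "vp" also supported
  N: 300            # reverse-SDE discretization steps
  sigma_min: 0.01
  sigma_max: 0.6    # initial noise scale of the sampler

model:
  in_channels: 2    # noised MDose + RTDose (3 adds the CT channel)
  base_width: 16    # 128 reproduces the full-size published setting
  depth: 2
  width_multipliers: [1, 2]

train:
  epochs: 90
  batch_size: 16
  learning_rate: 0.001
  ema_decay: 0.999

sampler:
  N_steps: 300      # must equal schedule.N
  M_corrector: 3
  snr_r: 0.16

data:
  n_cases: 600
  split_ratio: 0.8  # the 4:1 train/test partition
  grid_size: [32, 32]
  error:            # known planned-to-measured transform of the phantoms
    blur_sigma: 1.5
    shift: [0.5, 0.5]
    calib_amplitude: 0.05
    calib_period: 16.0
    noise_sd: 0.01
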