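# Conflict sweep at a 1:3 sensitivity ratio, run as:
#   proscribe simulate -c examples/configs/conflict_sweep.yaml -o out/
seed: 11
model:
  n_trials: 400
stimulus:
  slant_delta_deg: 0
  slant_chi_deg: 0
  A_delta: 1
  A_chi: 8
conflicts_deg: [0, 10, 20, 30, 40, 50]
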