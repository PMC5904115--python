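# Equal-reliability conflicting cues -> perceptual alternation:
#   proscribe rivalry -c examples/configs/rivalry.yaml -o out/
seed: 21
stimulus:
  slant_delta_deg: -30
  slant_chi_deg: 30
  A_delta: 1
  A_chi: 1
rivalry:
  T: 6250.0
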