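"""Robust cue integration under increasing conflict.

Sweeps the disparity-texture conflict at a 1:3 sensitivity ratio
(A_delta=1, A_chi=8) and prints the decoded bias (relative to the more
reliable texture cue) and the combined-to-single reliability ratio.
Bias should rise away from the texture cue at moderate conflict and revert
to ~0 at large conflict; reliability starts above 1 (fusion benefit), dips
below 1, then recovers — the robust-estimation signature.
"""

import numpy as np

from proscribe import ModelConfig, SlantStimulus, simulate_condition

config = ModelConfig(n_trials=800)
print(f"{'conflict':>8} {'bias (deg)':>11} {'rel. reliability':>17}")
for conflict in (0, 10, 20, 30, 40, 50):
    stimulus = SlantStimulus.from_degrees(-conflict / 2, conflict / 2, 1, 8)
    r = simulate_condition(stimulus, config,
                           rng=np.random.default_rng(40 + conflict))
    rel = r.peak_combined / r.peak_single_chi
    print(f"{conflict:>8} {np.rad2deg(r.bias):>11.2f} {rel:>17.3f}")
print("\nBias returns toward the reliable cue and reliability recovers: the")
print("suppressive readout vetoes the implausible midpoint interpretation.")
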