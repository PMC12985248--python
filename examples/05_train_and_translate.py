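"""The scaled-down end-to-end study: train the small translation model on
synthetic paired windows and compare it against an untrained copy.

Simulates records with heart rates in 60-90 BPM and pulse transit times in
0.2-0.3 s, trains for 500 Adam steps (batch 16, T = 50), then reports RMSE,
heart-rate MAE and Fréchet distance on 32 held-out windows.  Takes a few
minutes on one CPU.
"""

import json

from hemodiff.experiments import scaled_down_experiment

res = scaled_down_experiment(seed=1)
print(json.dumps({k: round(v, 4) if isinstance(v, float) else v for k, v in res.items()}, indent=1))
print()
print("rmse_trained below rmse_untrained -> training moved the sampler's")
print("output distribution toward the paired ECGs; hr_mae_trained is the")
print("mean heart-rate error (BPM) of the generated windows.")
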