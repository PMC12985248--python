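"""Simulate one paired PPG-ECG recording and verify its ground truth.

Generates 30 s of a regular 72-BPM rhythm with a 0.25 s pulse transit time,
then recovers the PTT from the signals alone via cross-correlation of the
R-peak and pulse-onset impulse trains.
"""

import numpy as np
from scipy.signal import correlate

from hemodiff import SimConfig, generate_record
from hemodiff.synthetic import detect_ppg_onsets

cfg = SimConfig(heart_rate_bpm=72, rr_cv=0.03, ptt_s=0.25, duration_s=30.0,
                noise_sd=0.01, baseline_wander_amp=0.02, seed=42)
rec = generate_record(cfg)

rr_s = np.diff(rec.r_peaks) / cfg.fs
onsets = detect_ppg_onsets(rec.ppg, cfg.fs)

n = len(rec.ecg)
train_r = np.zeros(n)
train_r[rec.r_peaks] = 1.0
train_o = np.zeros(n)
train_o[onsets] = 1.0
lag = int(np.argmax(correlate(train_o, train_r, mode="full"))) - (n - 1)

print(f"beats simulated        : {len(rec.r_peaks)}")
print(f"mean heart rate        : {60 / rr_s.mean():.1f} BPM (configured {cfg.heart_rate_bpm})")
print(f"RR coefficient of var. : {rr_s.std() / rr_s.mean():.3f} (configured {cfg.rr_cv})")
print(f"recovered PTT          : {lag / cfg.fs * 1000:.1f} ms (configured {cfg.ptt_s * 1000:.0f} ms)")
# The recovered PTT should match the configured one within ~2 samples
# (±16 ms at 128 Hz): the PPG upstroke is steepest right at pulse onset.
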