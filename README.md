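# hemodiff

Physics-aware conditional diffusion for reconstructing single-lead **ECG**
waveforms from **PPG** (photoplethysmography) windows.

Wearables measure the peripheral blood-volume pulse (PPG) cheaply, but
clinical diagnosis needs the heart's electrical signal (ECG). The mapping
from pulse wave back to electrical activation is an ill-posed inverse
problem: purely data-driven generators tend to hallucinate waveforms that
look plausible but are hemodynamically impossible. `hemodiff` constrains a
denoising diffusion model with an explicit, differentiable model of pulse
propagation:

1. **Lattice-Boltzmann physics encoder (D1Q3).** The PPG window `c ∈ R^L` is
   lifted into three kinetic channels `F_i = softplus(W_i c + b_i)`
   (velocities `e ∈ {−1, 0, +1}`), evolved by K rounds of a *learned*
   channel-mixing collision followed by streaming (circular shift by `e_i`).
   The collision residual is moment-projected so every lattice site conserves
   mass and momentum exactly:
   `C_i = C̃_i − Δρ/Q − e_i Δm / Σ_j e_j²`. The macroscopic moments
   `ρ = Σ_i F_i`, `ρu = Σ_i e_i F_i` form the conditioning embedding
   `h_phys = [ρ, ρu]`.
2. **Region-disentangled denoising U-Net.** A shared 1-D encoder–decoder over
   the noisy ECG `x_t` with sinusoidal timestep embeddings; cross-attention at
   the bottleneck, `Z' = Z + softmax(QKᵀ/√d_k)V` with queries from the ECG
   latents and keys/values from (pooled) `h_phys`, lets the model compensate
   for the pulse transit time. A geometry head predicts the diffusion noise
   `ε̂`; a topology head predicts a QRS-region probability mask `r̂`.
3. **Physics-consistent objective.** With
   `x_t = √ᾱ_t x_0 + √(1−ᾱ_t) ε` and the Tweedie single-step estimate
   `x̂_0 = (x_t − √(1−ᾱ_t) ε̂)/√ᾱ_t`, training minimizes
   `L = λ_diff‖ε − ε̂‖² + λ_reg BCE(r, r̂) + λ_phys‖∂x̂_0/∂τ − P_φ(h_phys)‖²`,
   tying the generated waveform's temporal derivative to the encoded
   momentum flux.

Everything runs on plain numpy/scipy with an in-repo reverse-mode autodiff
tape (`hemodiff.autodiff`) — no deep-learning framework required — and a
synthetic paired PPG–ECG generator with known R-peaks, pulse transit time
and rhythm labels makes the full system trainable and testable on one CPU.

## Worked example

```python
import numpy as np
from hemodiff import SimConfig, generate_record, windows_from_record

rec = generate_record(SimConfig(heart_rate_bpm=72, ptt_s=0.25,
                                duration_s=30.0, seed=42))
windows = windows_from_record(rec)
w = windows[0]
print(len(windows), w.length)      # 7 512
print(w.ecg.min(), w.ecg.max())    # -1.0 1.0
print(w.r_peaks)                   # [ 54 161 265 374 484]  true R-peak indices
print(int(w.mask.sum()))           # 165 = 5 peaks x 33 mask samples
```

The `examples/` directory contains one short narrative script per
capability; each prints the quantities it computes and what they mean:

```
$ python examples/01_simulate_paired_recording.py
beats simulated        : 36
mean heart rate        : 71.9 BPM (configured 72)
RR coefficient of var. : 0.025 (configured 0.03)
recovered PTT          : 257.8 ms (configured 250 ms)
```

`03_lattice_encoder_conservation.py` verifies the collision projection
(mass/momentum residuals at ~1e−16), `04_diffusion_algebra.py` the
forward/Tweedie inversion (~1e−15), and `05_train_and_translate.py` runs the
scaled-down training study end to end.

A thin CLI wraps the same pipeline:

```bash
hemodiff --seed 1 simulate --out runs/ds
hemodiff preprocess --data runs/ds --out runs/wins
hemodiff train --data runs/wins --out runs/ckpt
hemodiff translate --checkpoint runs/ckpt/ckpt_final.npz --data runs/wins --out runs/gen
hemodiff evaluate --real runs/wins --generated runs/gen
```

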