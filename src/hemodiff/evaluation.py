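"""Evaluation metrics for generated ECG windows.

Three complementary views of quality:

* **RMSE** — point-wise waveform fidelity, √mean((x − x̂)²) per paired window.
* **HR-MAE** — clinical validity: heart rate (BPM) is derived from each
  window via the Pan–Tompkins detector and compared as a mean absolute
  deviation; windows with fewer than two detected peaks carry no rate and
  are excluded.
* **Fréchet Distance (FD)** — distributional realism: each window is treated
  as an L-dimensional vector, Gaussians are fit to the real and generated
  sets, and FD is the squared Wasserstein-2 distance
  ‖μ_r − μ_g‖² + tr(Σ_r + Σ_g − 2(Σ_r Σ_g)^{1/2}).

Metrics operate on the normalized [−1, 1] domain by default (the domain the
model is trained in); de-normalized evaluation is available by passing
de-normalized arrays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla

from .preprocessing import detect_rpeaks

__all__ = ["MetricsReport", "rmse", "hr_from_window", "hr_mae", "frechet_distance", "evaluate_windows"]


@dataclass
class MetricsReport:
    rmse: float
    hr_mae: float | None
    fd: float
    n_windows: int
    n_windows_hr: int

    def to_dict(self) -> dict:
        return {
            "rmse": self.rmse,
            "hr_mae": self.hr_mae,
            "fd": self.fd,
            "n_windows": self.n_windows,
            "n_windows_hr": self.n_windows_hr,
        }


def rmse(x: np.ndarray, x_hat: np.ndarray) -> float:
    x = np.asarray(x, dtype=np.float64)
    x_hat = np.asarray(x_hat, dtype=np.float64)
    if x.shape != x_hat.shape:
        raise ValueError("shapes differ")
    return float(np.sqrt(np.mean((x - x_hat) ** 2)))


def hr_from_window(window: np.ndarray, fs: float) -> float | None:
    """Heart rate in BPM from the span between first and last detected peak.

    Returns None when fewer than two peaks are found (rate undefined).
    """
    peaks = detect_rpeaks(np.asarray(window, dtype=np.float64), fs)
    return hr_from_peaks(peaks, fs)


def hr_from_peaks(peaks: np.ndarray, fs: float) -> float | None:
    peaks = np.asarray(peaks)
    if peaks.size < 2:
        return None
    span = float(peaks[-1] - peaks[0])
    if span <= 0:
        return None
    return 60.0 * fs * (len(peaks) - 1) / span


def hr_mae(true_windows, generated_windows, fs: float) -> tuple[float | None, int]:
    """Mean |BPM_true − BPM_gen| over pairs where both rates are defined.

    Returns ``(mae, n_used)``; mae is None (with a warning) when no pair has
    a defined rate on both sides.
    """
    if len(true_windows) != len(generated_windows):
        raise ValueError("window lists must be paired")
    diffs = []
    for xt, xg in zip(true_windows, generated_windows):
        bt = hr_from_window(xt, fs)
        bg = hr_from_window(xg, fs)
        if bt is not None and bg is not None:
            diffs.append(abs(bt - bg))
    if not diffs:
        warnings.warn("no window pair had >=2 detected peaks on both sides; HR-MAE undefined")
        return None, 0
    return float(np.mean(diffs)), len(diffs)


def frechet_distance(real: np.ndarray, generated: np.ndarray, ridge: float = 1e-6) -> float:
    """Fréchet distance between Gaussian fits of two window sets (n×L, m×L).

    A ridge ε·I stabilizes the covariances at large L with finite samples;
    the matrix square root is computed on the symmetrized product and a tiny
    negative trace residue (> −1e−6) from rounding is clamped to zero.
    """
    real = np.atleast_2d(np.asarray(real, dtype=np.float64))
    generated = np.atleast_2d(np.asarray(generated, dtype=np.float64))
    if real.shape[0] < 2 or generated.shape[0] < 2:
        raise ValueError("need at least 2 windows per set")
    if real.shape[1] != generated.shape[1]:
        raise ValueError("window lengths differ")
    mu_r, mu_g = real.mean(axis=0), generated.mean(axis=0)
    d = real.shape[1]
    eye = ridge * np.eye(d)
    cov_r = np.cov(real, rowvar=False).reshape(d, d) + eye
    cov_g = np.cov(generated, rowvar=False).reshape(d, d) + eye

    prod = cov_r @ cov_g
    sqrt_prod = sla.sqrtm(prod)
    if isinstance(sqrt_prod, tuple):
        sqrt_prod = sqrt_prod[0]
    sqrt_prod = np.real(sqrt_prod)
    sqrt_prod = (sqrt_prod + sqrt_prod.T) / 2.0

    mean_term = float(np.sum((mu_r - mu_g) ** 2))
    trace_term = float(np.trace(cov_r) + np.trace(cov_g) - 2.0 * np.trace(sqrt_prod))
    if -1e-6 < trace_term < 0:
        trace_term = 0.0
    return mean_term + trace_term


def evaluate_windows(true_ecg: np.ndarray, generated_ecg: np.ndarray, fs: float) -> MetricsReport:
    """Assemble the full report over paired window stacks (n × L)."""
    true_ecg = np.atleast_2d(np.asarray(true_ecg, dtype=np.float64))
    generated_ecg = np.atleast_2d(np.asarray(generated_ecg, dtype=np.float64))
    if true_ecg.shape != generated_ecg.shape:
        raise ValueError("paired stacks must have equal shape")
    point = rmse(true_ecg, generated_ecg)
    mae, n_hr = hr_mae(list(true_ecg), list(generated_ecg), fs)
    fd = frechet_distance(true_ecg, generated_ecg)
    return MetricsReport(rmse=point, hr_mae=mae, fd=fd,
                         n_windows=len(true_ecg), n_windows_hr=n_hr)
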