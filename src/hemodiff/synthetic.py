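"""Synthetic paired PPG–ECG generator with known ground truth.

The generator emulates the statistical structure the PPG-to-ECG translation
model assumes, at desk scale and with every latent quantity known by
construction:

* a quasi-periodic ECG built from per-beat Gaussian wave templates
  (P, Q, R, S, T; R dominant positive), so true R-peak indices are exact;
* RR intervals drawn i.i.d. Gaussian with a configurable coefficient of
  variation, truncated to [0.3 s, 2.0 s]; an ``af_like`` rhythm forces
  CV >= 0.15, mimicking the irregularly irregular RR sequence of atrial
  fibrillation;
* a PPG in which each heartbeat launches a smooth unimodal pressure pulse
  whose onset lags the R-peak by a configurable pulse transit time (PTT),
  plus low-frequency baseline wander and white noise.

All randomness flows through one ``numpy`` generator seeded per record, so a
config (including its seed) pins every output bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

__all__ = [
    "SimConfig",
    "PairedRecording",
    "generate_ecg",
    "generate_ppg",
    "generate_record",
    "generate_dataset",
    "detect_ppg_onsets",
    "save_dataset",
    "load_dataset",
]

# Per-beat wave template: offsets/widths are fractions of the local RR interval,
# amplitudes in normalized units. R is the dominant positive deflection.
_WAVES = {  # name: (offset_frac, width_frac, amplitude)
    "P": (-0.20, 0.025, 0.15),
    "Q": (-0.035, 0.010, -0.12),
    "R": (0.0, 0.012, 1.00),
    "S": (0.035, 0.010, -0.25),
    "T": (0.30, 0.060, 0.35),
}

_RR_MIN_S = 0.3
_RR_MAX_S = 2.0


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic paired recording."""

    heart_rate_bpm: float = 70.0
    rr_cv: float = 0.03
    rhythm: str = "regular"  # "regular" | "af_like"
    ptt_s: float = 0.25
    fs: float = 128.0
    duration_s: float = 60.0
    noise_sd: float = 0.02
    baseline_wander_amp: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.heart_rate_bpm <= 0:
            raise ValueError("heart_rate_bpm must be positive")
        if not 0 <= self.rr_cv < 1:
            raise ValueError("rr_cv must lie in [0, 1)")
        if self.ptt_s < 0:
            raise ValueError("ptt_s must be non-negative")
        if self.rhythm not in ("regular", "af_like"):
            raise ValueError(f"unknown rhythm {self.rhythm!r}")
        if self.fs < 64:
            # template width down to ~0.01 * RR_min ≈ 4 ms sigma; 64 Hz is the
            # floor at which the narrow QRS bumps remain resolvable
            raise ValueError("fs must be at least 64 Hz")
        if self.rhythm == "af_like" and self.rr_cv < 0.15:
            object.__setattr__(self, "rr_cv", 0.15)


@dataclass
class PairedRecording:
    """One synthetic record: ECG, PPG, true R-peaks and rhythm label."""

    ecg: np.ndarray
    ppg: np.ndarray
    r_peaks: np.ndarray
    rhythm: str
    ptt_s: float
    fs: float
    record_id: int = 0

    def __post_init__(self):
        if len(self.ecg) != len(self.ppg):
            raise ValueError("ecg and ppg must have equal length")
        rp = np.asarray(self.r_peaks)
        if rp.size and (np.any(np.diff(rp) <= 0) or rp[0] < 0 or rp[-1] >= len(self.ecg)):
            raise ValueError("r_peaks must be strictly increasing and in bounds")


class EmptyRecordError(ValueError):
    """Raised when the requested duration cannot hold a single beat."""


def _draw_rr_intervals(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    mean_rr = 60.0 / config.heart_rate_bpm
    n_max = int(np.ceil(config.duration_s / _RR_MIN_S)) + 2
    rr = rng.normal(mean_rr, config.rr_cv * mean_rr, size=n_max)
    return np.clip(rr, _RR_MIN_S, _RR_MAX_S)


def generate_ecg(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Build a clean ECG trace and its exact R-peak sample indices.

    Beats are placed sequentially: the first R falls half an RR interval into
    the record, subsequent R times accumulate the drawn RR sequence.  Each beat
    contributes five Gaussian bumps with offsets and widths scaled by its own
    RR interval, so slower beats have proportionally wider waves.
    """
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration_s * config.fs))
    t = np.arange(n) / config.fs
    rr = _draw_rr_intervals(config, rng)

    r_times = []
    cursor = 0.5 * rr[0]
    for interval in rr:
        if cursor >= config.duration_s:
            break
        r_times.append((cursor, interval))
        cursor += interval
    if not r_times:
        raise EmptyRecordError(
            f"duration {config.duration_s}s too short for one beat at "
            f"{config.heart_rate_bpm} BPM"
        )

    ecg = np.zeros(n)
    peaks = []
    for r_time, interval in r_times:
        idx = int(round(r_time * config.fs))
        if idx >= n:
            continue
        peaks.append(idx)
        for off_frac, width_frac, amp in _WAVES.values():
            center = r_time + off_frac * interval
            sigma = max(width_frac * interval, 1.0 / config.fs)
            lo = max(0, int((center - 5 * sigma) * config.fs))
            hi = min(n, int((center + 5 * sigma) * config.fs) + 1)
            if hi > lo:
                ecg[lo:hi] += amp * np.exp(-0.5 * ((t[lo:hi] - center) / sigma) ** 2)
    return ecg, np.asarray(peaks, dtype=np.int64)


def _pulse_kernel(fs: float, t_peak_s: float = 0.18, tail_s: float = 1.2) -> np.ndarray:
    """Unimodal pressure-pulse kernel: gamma shape t·exp(1 − t/t_peak).

    Normalized to unit peak; its derivative is maximal at t = 0+, so the
    steepest upstroke coincides with the pulse onset sample.
    """
    n = int(round(tail_s * fs))
    tk = np.arange(n) / fs
    return (tk / t_peak_s) * np.exp(1.0 - tk / t_peak_s)


def generate_ppg(
    r_peaks: np.ndarray, config: SimConfig, length: int
) -> np.ndarray:
    """Superpose one pressure pulse per R-peak, delayed by the PTT.

    Pulse onsets sit at ``peak + round(ptt_s * fs)``; baseline wander (a
    low-frequency sinusoid) and white noise are added last.
    """
    r_peaks = np.asarray(r_peaks, dtype=np.int64)
    if r_peaks.size and length < r_peaks.max():
        raise ValueError("length must cover the last R-peak")
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
    ppg = np.zeros(length)
    kernel = _pulse_kernel(config.fs)
    lag = int(round(config.ptt_s * config.fs))
    for p in r_peaks:
        start = p + lag
        if start >= length:
            continue
        end = min(length, start + len(kernel))
        ppg[start:end] += kernel[: end - start]
    if config.baseline_wander_amp > 0:
        t = np.arange(length) / config.fs
        phase = rng.uniform(0, 2 * np.pi)
        ppg += config.baseline_wander_amp * np.sin(2 * np.pi * 0.2 * t + phase)
    if config.noise_sd > 0:
        ppg += rng.normal(0.0, config.noise_sd, size=length)
    return ppg


def detect_ppg_onsets(ppg: np.ndarray, fs: float, min_rr_s: float = _RR_MIN_S) -> np.ndarray:
    """Locate pulse onsets as maxima of the first difference (steepest upstroke)."""
    from scipy.signal import find_peaks

    slope = np.gradient(ppg)
    if slope.max() <= 0:
        return np.asarray([], dtype=np.int64)
    onsets, _ = find_peaks(
        slope, height=0.3 * slope.max(), distance=max(1, int(min_rr_s * fs))
    )
    return onsets.astype(np.int64)


def generate_record(config: SimConfig, record_id: int = 0) -> PairedRecording:
    ecg, peaks = generate_ecg(config)
    ppg = generate_ppg(peaks, config, len(ecg))
    return PairedRecording(
        ecg=ecg, ppg=ppg, r_peaks=peaks, rhythm=config.rhythm,
        ptt_s=config.ptt_s, fs=config.fs, record_id=record_id,
    )


def generate_dataset(
    n_records: int,
    config: SimConfig,
    seed: int | None = None,
    af_fraction: float = 0.0,
) -> list[PairedRecording]:
    """Generate ``n_records`` records; record ``i`` is seeded with ``seed + i``.

    ``af_fraction`` is the per-record probability of flipping the rhythm to
    ``af_like`` (Bernoulli draw from a dedicated label generator).
    """
    if n_records < 1:
        raise ValueError("n_records must be >= 1")
    base_seed = config.seed if seed is None else seed
    label_rng = np.random.default_rng(np.random.SeedSequence([int(base_seed), 2]))
    records = []
    for i in range(n_records):
        cfg = replace(config, seed=int(base_seed) + i)
        if af_fraction > 0 and label_rng.random() < af_fraction:
            cfg = replace(cfg, rhythm="af_like", rr_cv=max(cfg.rr_cv, 0.2))
        records.append(generate_record(cfg, record_id=i))
    return records


# -- container I/O --------------------------------------------------------


def save_dataset(records: list[PairedRecording], path: str | Path) -> None:
    """Write records to a compressed array container plus a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays: dict[str, np.ndarray] = {}
    meta = []
    for rec in records:
        arrays[f"ecg_{rec.record_id}"] = rec.ecg
        arrays[f"ppg_{rec.record_id}"] = rec.ppg
        arrays[f"peaks_{rec.record_id}"] = rec.r_peaks
        meta.append(
            {"record_id": rec.record_id, "rhythm": rec.rhythm,
             "ptt_s": rec.ptt_s, "fs": rec.fs, "n_peaks": int(len(rec.r_peaks))}
        )
    np.savez_compressed(path.with_suffix(".npz"), **arrays)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_dataset(path: str | Path) -> list[PairedRecording]:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    records = []
    with np.load(path.with_suffix(".npz")) as npz:
        for m in meta:
            rid = m["record_id"]
            records.append(
                PairedRecording(
                    ecg=npz[f"ecg_{rid}"], ppg=npz[f"ppg_{rid}"],
                    r_peaks=npz[f"peaks_{rid}"], rhythm=m["rhythm"],
                    ptt_s=m["ptt_s"], fs=m["fs"], record_id=rid,
                )
            )
    return records
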