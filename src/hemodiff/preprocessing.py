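"""Window preparation: resampling, segmentation, normalization, R-peak
detection and QRS region-of-interest masks.

Recordings are resampled to a common rate (default 128 Hz), cut into
non-overlapping 4-s windows (L = 512), and each window is min-max scaled to
[-1, 1] per channel.  The QRS mask marks every sample within 16 samples of an
R-peak (|t - t_p| <= 16, i.e. 33 samples for an interior peak) and supervises
the topology branch of the backbone.  All indices are 0-based and windows are
half-open [start, stop).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .synthetic import PairedRecording

__all__ = [
    "SignalWindow",
    "resample",
    "segment",
    "minmax_normalize",
    "minmax_denormalize",
    "detect_rpeaks",
    "build_roi_mask",
    "windows_from_record",
    "windows_from_records",
    "save_windows",
    "load_windows",
    "DEFAULT_FS",
    "DEFAULT_WINDOW_S",
    "DEFAULT_ROI_HALF_WIDTH",
]

DEFAULT_FS = 128.0
DEFAULT_WINDOW_S = 4.0
DEFAULT_ROI_HALF_WIDTH = 16


@dataclass
class SignalWindow:
    """One paired, normalized PPG/ECG window with supervision targets.

    ``norm_params`` holds the per-channel (min, max) of the raw window so
    either channel can be de-normalized exactly; ``degenerate`` flags
    constant channels that were zeroed instead of scaled.
    """

    ppg: np.ndarray
    ecg: np.ndarray
    mask: np.ndarray
    r_peaks: np.ndarray
    fs: float
    norm_params: dict[str, tuple[float, float]]
    window_index: int = 0
    degenerate: dict[str, bool] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return len(self.ecg)


def resample(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Band-limited (polyphase) resampling; output length = round(n·fs_out/fs_in)."""
    if fs_in <= 0 or fs_out <= 0:
        raise ValueError("sampling rates must be positive")
    x = np.asarray(x, dtype=np.float64)
    if x.size < 2:
        raise ValueError("signal must have at least 2 samples")
    if fs_in == fs_out:
        return x.copy()
    frac = Fraction(fs_out / fs_in).limit_denominator(1000)
    y = sps.resample_poly(x, frac.numerator, frac.denominator, padtype="line")
    n_out = int(round(len(x) * fs_out / fs_in))
    if len(y) > n_out:
        y = y[:n_out]
    elif len(y) < n_out:
        y = np.pad(y, (0, n_out - len(y)), mode="edge")
    return y


def segment(x: np.ndarray, window_len: int) -> list[np.ndarray]:
    """Non-overlapping consecutive windows; trailing remainder dropped."""
    if window_len < 1:
        raise ValueError("window_len must be >= 1")
    x = np.asarray(x)
    n_win = len(x) // window_len
    return [x[i * window_len : (i + 1) * window_len].copy() for i in range(n_win)]


def minmax_normalize(x: np.ndarray) -> tuple[np.ndarray, tuple[float, float], bool]:
    """Scale a window to [-1, 1]: x̃ = 2·(x − min)/(max − min) − 1.

    Returns ``(x̃, (min, max), degenerate)``; a constant window maps to zeros
    with the degenerate flag set (the affine map is not invertible there).
    """
    x = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("window contains non-finite values")
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        return np.zeros_like(x), (lo, hi), True
    return 2.0 * (x - lo) / (hi - lo) - 1.0, (lo, hi), False


def minmax_denormalize(x_norm: np.ndarray, params: tuple[float, float]) -> np.ndarray:
    lo, hi = params
    if hi == lo:
        return np.full_like(np.asarray(x_norm, dtype=np.float64), lo)
    return (np.asarray(x_norm, dtype=np.float64) + 1.0) * (hi - lo) / 2.0 + lo


def detect_rpeaks(ecg: np.ndarray, fs: float) -> np.ndarray:
    """Simplified Pan–Tompkins QRS detector.

    Chain: 5–15 Hz band-pass → derivative → squaring → 150 ms moving-window
    integration → adaptive signal/noise threshold with a 200 ms refractory
    period → refinement of each detection to the local ECG maximum within
    ±25 ms.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    ecg = np.asarray(ecg, dtype=np.float64)
    if len(ecg) < fs:
        return np.asarray([], dtype=np.int64)
    if np.allclose(ecg, ecg[0]):
        return np.asarray([], dtype=np.int64)

    nyq = fs / 2.0
    b, a = sps.butter(2, [5.0 / nyq, min(15.0, 0.95 * nyq) / nyq], btype="band")
    filtered = sps.filtfilt(b, a, ecg)
    squared = np.gradient(filtered) ** 2
    win = int(round(0.150 * fs))
    if win < 1 or win > len(squared):
        return np.asarray([], dtype=np.int64)
    integrated = np.convolve(squared, np.ones(win) / win, mode="same")

    refractory = int(round(0.200 * fs))
    candidates, _ = sps.find_peaks(integrated, distance=max(1, refractory))
    if candidates.size == 0:
        return np.asarray([], dtype=np.int64)

    # adaptive threshold: running signal/noise level estimates
    spk = float(integrated[candidates].max()) * 0.5
    npk = float(np.median(integrated))
    detections = []
    for c in candidates:
        v = integrated[c]
        thr = npk + 0.25 * (spk - npk)
        if v > thr:
            detections.append(c)
            spk = 0.125 * v + 0.875 * spk
        else:
            npk = 0.125 * v + 0.875 * npk

    # refine each detection to the local ECG maximum within ±25 ms
    half = max(1, int(round(0.025 * fs)))
    refined = []
    for c in detections:
        lo = max(0, c - half)
        hi = min(len(ecg), c + half + 1)
        refined.append(lo + int(np.argmax(ecg[lo:hi])))
    refined = np.unique(np.asarray(refined, dtype=np.int64))
    # re-apply refractory after refinement
    keep: list[int] = []
    for r in refined:
        if not keep or r - keep[-1] >= refractory:
            keep.append(int(r))
    return np.asarray(keep, dtype=np.int64)


def build_roi_mask(
    r_peaks: np.ndarray | list[int], length: int, half_width: int = DEFAULT_ROI_HALF_WIDTH
) -> np.ndarray:
    """Binary QRS mask: 1 where some peak p satisfies |t − p| <= half_width."""
    r_peaks = np.asarray(r_peaks, dtype=np.int64)
    if r_peaks.size and (r_peaks.min() < 0 or r_peaks.max() >= length):
        raise ValueError("r_peaks must lie in [0, length)")
    mask = np.zeros(length, dtype=np.float64)
    for p in r_peaks:
        mask[max(0, p - half_width) : min(length, p + half_width + 1)] = 1.0
    return mask


def windows_from_record(
    record: PairedRecording,
    target_fs: float = DEFAULT_FS,
    window_s: float = DEFAULT_WINDOW_S,
    roi_half_width: int = DEFAULT_ROI_HALF_WIDTH,
    use_true_peaks: bool = True,
) -> list[SignalWindow]:
    """Resample, segment and normalize one paired record into model windows.

    When the record carries ground-truth R-peaks (simulator output) they are
    mapped into window coordinates for the mask; otherwise peaks come from
    :func:`detect_rpeaks` on the window.
    """
    ecg = resample(record.ecg, record.fs, target_fs)
    ppg = resample(record.ppg, record.fs, target_fs)
    L = int(round(window_s * target_fs))
    ecg_wins = segment(ecg, L)
    ppg_wins = segment(ppg, L)

    if use_true_peaks and record.r_peaks is not None and len(record.r_peaks):
        peaks_global = np.round(
            np.asarray(record.r_peaks, dtype=np.float64) * target_fs / record.fs
        ).astype(np.int64)
    else:
        peaks_global = None

    windows = []
    for i, (ew, pw) in enumerate(zip(ecg_wins, ppg_wins)):
        start = i * L
        if peaks_global is not None:
            local = peaks_global[(peaks_global >= start) & (peaks_global < start + L)] - start
        else:
            local = detect_rpeaks(ew, target_fs)
        ecg_n, ecg_p, ecg_d = minmax_normalize(ew)
        ppg_n, ppg_p, ppg_d = minmax_normalize(pw)
        windows.append(
            SignalWindow(
                ppg=ppg_n, ecg=ecg_n,
                mask=build_roi_mask(local, L, roi_half_width),
                r_peaks=np.asarray(local, dtype=np.int64),
                fs=target_fs,
                norm_params={"ecg": ecg_p, "ppg": ppg_p},
                window_index=i,
                degenerate={"ecg": ecg_d, "ppg": ppg_d},
            )
        )
    return windows


def windows_from_records(records, **kwargs) -> list[SignalWindow]:
    out = []
    for rec in records:
        wins = windows_from_record(rec, **kwargs)
        for w in wins:
            w.window_index = len(out)
            out.append(w)
    return out


def save_windows(windows: list[SignalWindow], path: str | Path) -> None:
    """Single-container export: stacked arrays plus ragged peak indices."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    peaks_flat = np.concatenate([w.r_peaks for w in windows]) if windows else np.asarray([], dtype=np.int64)
    offsets = np.cumsum([0] + [len(w.r_peaks) for w in windows])
    np.savez_compressed(
        path.with_suffix(".npz"),
        ppg=np.stack([w.ppg for w in windows]),
        ecg=np.stack([w.ecg for w in windows]),
        mask=np.stack([w.mask for w in windows]),
        peaks_flat=peaks_flat,
        peak_offsets=offsets,
        fs=np.asarray([windows[0].fs]),
        norm_ecg=np.asarray([w.norm_params["ecg"] for w in windows]),
        norm_ppg=np.asarray([w.norm_params["ppg"] for w in windows]),
    )


def load_windows(path: str | Path) -> list[SignalWindow]:
    path = Path(path)
    with np.load(path.with_suffix(".npz")) as npz:
        fs = float(npz["fs"][0])
        offsets = npz["peak_offsets"]
        out = []
        for i in range(len(npz["ecg"])):
            out.append(
                SignalWindow(
                    ppg=npz["ppg"][i], ecg=npz["ecg"][i], mask=npz["mask"][i],
                    r_peaks=npz["peaks_flat"][offsets[i] : offsets[i + 1]],
                    fs=fs,
                    norm_params={
                        "ecg": tuple(npz["norm_ecg"][i]),
                        "ppg": tuple(npz["norm_ppg"][i]),
                    },
                    window_index=i,
                )
            )
    return out
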