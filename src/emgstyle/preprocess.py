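"""Denoising and band-limiting of raw multi-channel sEMG recordings.

The pipeline applied before feature extraction is the standard offline sEMG
chain: per-channel wavelet denoising (symlet family, soft thresholding with a
SURE-based level-wise threshold, approximation band zeroed to remove baseline
drift) followed by a zero-phase Butterworth band-pass that keeps the
physiologically informative 20-500 Hz band.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import pywt
from scipy import signal

from .errors import ConfigurationError, SignalLengthError

__all__ = [
    "Recording",
    "denoise_wavelet",
    "bandpass_filter",
    "read_recording_csv",
    "write_recording_csv",
]


@dataclass
class Recording:
    """One multi-channel sEMG trial.

    Parameters
    ----------
    samples
        Array of shape ``(n_channels, n_samples)`` in acquisition units.
    fs
        Sampling rate in Hz.
    motion_label
        Integer motion class of the trial (1-based).
    user_id
        Subject identifier.
    channel_names
        One name per channel (muscle names in the acquisition montage).
    """

    samples: np.ndarray
    fs: float = 2000.0
    motion_label: int = 1
    user_id: str = "user"
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ConfigurationError(f"sampling rate must be positive, got {self.fs}")
        if not self.channel_names:
            self.channel_names = [f"ch{i + 1}" for i in range(self.n_channels)]
        if len(self.channel_names) != self.n_channels:
            raise ConfigurationError(
                f"{len(self.channel_names)} channel names for {self.n_channels} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


def _mad_sigma(coeffs: np.ndarray) -> float:
    """Robust noise-level estimate from wavelet coefficients (MAD / 0.6745)."""
    return float(np.median(np.abs(coeffs)) / 0.6745)


def _threshold_sqtwolog(x: np.ndarray) -> float:
    return float(np.sqrt(2.0 * np.log(max(x.size, 2))))


def _threshold_rigrsure(x: np.ndarray) -> float:
    """SURE-minimizing soft threshold for unit-variance coefficients.

    Candidate thresholds are the coefficient magnitudes plus zero; the zero
    candidate (risk 1) matters when a band is signal-dominated and any
    shrinkage would bias every coefficient.
    """
    n = x.size
    s = np.sort(x**2)
    cs = np.cumsum(s)
    k = np.arange(1, n + 1)
    # Stein risk of soft thresholding at sqrt(s_k), vectorized over k
    risk = (n - 2.0 * k + cs + (n - k) * s) / n
    best = int(np.argmin(risk))
    if risk[best] >= 1.0:  # identity (t = 0) estimator has unit risk
        return 0.0
    return float(np.sqrt(s[best]))


def _threshold_heursure(x: np.ndarray) -> float:
    """Heuristic SURE: universal threshold for sparse levels, else min(SURE, universal)."""
    n = x.size
    t_univ = _threshold_sqtwolog(x)
    eta = (np.sum(x**2) - n) / n
    crit = np.log2(max(n, 2)) ** 1.5 / np.sqrt(n)
    if eta < crit:
        return t_univ
    return min(t_univ, _threshold_rigrsure(x))


_THRESHOLD_RULES = {
    "heursure": _threshold_heursure,
    "rigrsure": _threshold_rigrsure,
    "sqtwolog": _threshold_sqtwolog,
}


def denoise_wavelet(
    rec: Recording,
    wavelet_name: str = "sym5",
    levels: int = 5,
    threshold_rule: str = "heursure",
) -> Recording:
    """Wavelet-denoise every channel of a recording.

    Each channel is decomposed to ``levels`` levels, the detail coefficients are
    soft-thresholded with a per-level threshold selected by ``threshold_rule``
    (scaled by a global noise estimate from the finest detail level), the
    approximation band is zeroed to suppress baseline drift, and the channel is
    reconstructed. Output shape equals input shape and total energy never
    increases.
    """
    if threshold_rule not in _THRESHOLD_RULES:
        raise ConfigurationError(
            f"unknown threshold rule {threshold_rule!r}; "
            f"choose from {sorted(_THRESHOLD_RULES)}"
        )
    if wavelet_name not in pywt.wavelist(kind="discrete"):
        raise ConfigurationError(f"unknown wavelet {wavelet_name!r}")
    if levels < 1:
        raise ConfigurationError(f"levels must be >= 1, got {levels}")
    min_len = 2**levels
    if rec.n_samples < min_len:
        raise SignalLengthError(
            f"signal of length {rec.n_samples} is shorter than the minimum "
            f"{min_len} samples required for {levels} decomposition levels"
        )
    rule = _THRESHOLD_RULES[threshold_rule]
    out = np.empty_like(rec.samples)
    for ch in range(rec.n_channels):
        x = rec.samples[ch]
        coeffs = pywt.wavedec(x, wavelet_name, level=levels, mode="periodization")
        approx, details = coeffs[0], coeffs[1:]
        sigma = _mad_sigma(details[-1])  # finest level carries mostly noise
        new_coeffs = [np.zeros_like(approx)]  # drop the drift/baseline band
        for d in details:
            if sigma <= 0:
                new_coeffs.append(np.zeros_like(d))
                continue
            t = sigma * rule(d / sigma)
            new_coeffs.append(pywt.threshold(d, t, mode="soft"))
        rebuilt = pywt.waverec(new_coeffs, wavelet_name, mode="periodization")
        out[ch] = rebuilt[: rec.n_samples]
    return replace(rec, samples=out)


def bandpass_filter(
    rec: Recording,
    low_hz: float = 20.0,
    high_hz: float = 500.0,
    order: int = 4,
) -> Recording:
    """Zero-phase Butterworth band-pass applied per channel.

    The forward-backward (``sosfiltfilt``) pass doubles the effective filter
    order but keeps windows aligned with motion timing, which matters for
    windowed feature extraction offline.
    """
    nyq = rec.fs / 2.0
    if not 0 < low_hz < high_hz:
        raise ConfigurationError(
            f"need 0 < low_hz < high_hz, got ({low_hz}, {high_hz})"
        )
    if high_hz >= nyq:
        raise ConfigurationError(
            f"high cutoff {high_hz} Hz must be below the Nyquist frequency {nyq} Hz"
        )
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=rec.fs, output="sos")
    out = signal.sosfiltfilt(sos, rec.samples, axis=1)
    return replace(rec, samples=np.ascontiguousarray(out))


def read_recording_csv(
    path,
    fs: float = 2000.0,
    motion_label: int = 1,
    user_id: str = "user",
) -> Recording:
    """Read one action repetition from a CSV file (one column per channel)."""
    df = pd.read_csv(path)
    return Recording(
        samples=df.to_numpy(dtype=float).T,
        fs=fs,
        motion_label=motion_label,
        user_id=user_id,
        channel_names=[str(c) for c in df.columns],
    )


def write_recording_csv(rec: Recording, path) -> None:
    """Write a recording as a CSV file with one column per channel."""
    pd.DataFrame(rec.samples.T, columns=rec.channel_names).to_csv(path, index=False)
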