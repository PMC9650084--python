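"""Sliding-window segmentation and the 8-features-per-channel sEMG descriptor.

Per channel and window the descriptor stacks six time-domain statistics —
mean absolute value (MAV), root mean square (RMS), sample variance (VAR), and
their sub-window maxima MMAV / MRMS / MVAR — with two scalar frequency-domain
features: the band power of an order-4 autoregressive (Burg) spectral estimate
and the mean frequency of the Welch periodogram.  With 8 channels this yields
the 64-dimensional per-window feature vector used throughout the framework.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .canonical import FeatureMatrix
from .errors import ConfigurationError, SignalLengthError
from .preprocess import Recording

__all__ = [
    "FEATURE_NAMES",
    "WindowSet",
    "segment_windows",
    "extract_features",
    "window_features",
]

#: Fixed per-channel feature order; column j of a channel block is FEATURE_NAMES[j].
FEATURE_NAMES = ("mav", "rms", "var", "mmav", "mrms", "mvar", "ar4_power", "mnf")

_N_SUBWINDOWS = 3  # sub-window count for the max-statistics MMAV/MRMS/MVAR
_AR_ORDER = 4
_BAND = (20.0, 500.0)  # Hz band over which AR power is integrated


@dataclass
class WindowSet:
    """Overlapping windows cut from one recording.

    ``windows`` has shape ``(n_windows, n_channels, window_length)``; every
    window inherits the source recording's motion label and user id.
    """

    windows: np.ndarray
    window_length: int
    shift: int
    fs: float
    motion_label: int
    user_id: str
    channel_names: list[str] = field(default_factory=list)

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    @property
    def n_channels(self) -> int:
        return self.windows.shape[1]


def segment_windows(rec: Recording, window_length: int = 300, shift: int = 50) -> WindowSet:
    """Cut a recording into overlapping windows.

    Windows start ``shift`` samples apart; a trailing partial window is
    discarded, so the count is ``floor((L - window_length) / shift) + 1``.
    """
    if shift < 1:
        raise ConfigurationError(f"shift must be >= 1, got {shift}")
    L = rec.n_samples
    if window_length > L:
        raise SignalLengthError(
            f"recording has {L} samples but one window needs {window_length}"
        )
    n_windows = (L - window_length) // shift + 1
    starts = np.arange(n_windows) * shift
    windows = np.stack([rec.samples[:, s : s + window_length] for s in starts])
    return WindowSet(
        windows=windows,
        window_length=window_length,
        shift=shift,
        fs=rec.fs,
        motion_label=rec.motion_label,
        user_id=rec.user_id,
        channel_names=list(rec.channel_names),
    )


def _mav(x: np.ndarray) -> float:
    return float(np.mean(np.abs(x)))


def _rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(x**2)))


def _var(x: np.ndarray) -> float:
    if x.size < 2:
        return 0.0
    return float(np.var(x, ddof=1))


def _burg_ar(x: np.ndarray, order: int) -> tuple[np.ndarray, float]:
    """Burg-method AR coefficients and driving-noise variance.

    Returns ``a`` such that the model is ``x[t] + sum_k a[k] x[t-k] = e[t]``.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    f = x.copy()  # forward prediction errors
    b = x.copy()  # backward prediction errors
    a = np.zeros(order)
    e = float(np.dot(x, x)) / n
    for m in range(order):
        fs = f[m + 1 :]
        bs = b[m : n - 1]
        den = float(np.dot(fs, fs) + np.dot(bs, bs))
        if den <= 0:
            break
        k = -2.0 * float(np.dot(fs, bs)) / den
        a_prev = a[:m].copy()
        a[m] = k
        if m > 0:
            a[:m] = a_prev + k * a_prev[::-1]
        f_new = fs + k * bs
        b_new = bs + k * fs
        f[m + 1 :] = f_new
        b[m + 1 : n] = b_new
        e *= 1.0 - k * k
    return a, max(e, 0.0)


def _ar4_band_power(x: np.ndarray, fs: float) -> float:
    """Total power of the order-4 Burg AR spectrum over the 20-500 Hz band."""
    if np.ptp(x) == 0:  # constant window: AR model undefined, define as 0
        return 0.0
    a, e = _burg_ar(x, _AR_ORDER)
    low, high = _BAND
    high = min(high, fs / 2.0 * 0.999)
    freqs = np.linspace(low, high, 128)
    _, h = signal.freqz(1.0, np.r_[1.0, a], worN=freqs, fs=fs)
    psd = e / fs * np.abs(h) ** 2
    return float(np.trapezoid(psd, freqs))


def _mean_frequency(x: np.ndarray, fs: float) -> float:
    """Mean frequency of the Welch periodogram (spectral centroid)."""
    nperseg = min(256, x.size)
    freqs, psd = signal.welch(x, fs=fs, nperseg=nperseg)
    total = float(np.sum(psd))
    if total <= 0:
        return 0.0
    return float(np.sum(freqs * psd) / total)


def window_features(window: np.ndarray, fs: float) -> np.ndarray:
    """Compute the 8-feature descriptor for every channel of one window.

    ``window`` has shape ``(n_channels, window_length)``; the result is the
    flat row ``[ch1 features..., ch2 features..., ...]`` of length
    ``8 * n_channels`` in :data:`FEATURE_NAMES` order.
    """
    window = np.atleast_2d(window)
    row = np.empty(window.shape[0] * len(FEATURE_NAMES))
    for ch, x in enumerate(window):
        subs = np.array_split(x, _N_SUBWINDOWS)
        row[ch * 8 : ch * 8 + 8] = (
            _mav(x),
            _rms(x),
            _var(x),
            max(_mav(s) for s in subs),
            max(_rms(s) for s in subs),
            max(_var(s) for s in subs),
            _ar4_band_power(x, fs),
            _mean_frequency(x, fs),
        )
    return row


def extract_features(ws: WindowSet) -> FeatureMatrix:
    """Extract one feature row per window of a window set."""
    if ws.n_windows == 0:
        raise ConfigurationError("window set is empty")
    values = np.stack([window_features(w, ws.fs) for w in ws.windows])
    names = [
        f"{ch}_{feat}" for ch in ws.channel_names for feat in FEATURE_NAMES
    ]
    return FeatureMatrix(
        values=values,
        labels=np.full(ws.n_windows, ws.motion_label, dtype=int),
        column_names=names,
        user_id=ws.user_id,
        n_channels=ws.n_channels,
    )
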