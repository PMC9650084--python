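"""Synthetic multi-user sEMG data with the structure the framework assumes.

Two generators are provided.  ``generate_multiuser_features`` emulates the
feature level directly with a bilinear style/content model: every motion class
is a Gaussian cluster around a shared latent mean, and each user observes the
latent space through their own linear "style" transform — the individual
differences (electrode placement, tissue, muscle strength) that make a
classifier trained on one person fail on another.  ``generate_raw_semg``
emulates the signal level: band-limited Gaussian carriers amplitude-modulated
by per-class per-channel activation envelopes, contaminated with mains
interference and baseline drift, at the acquisition geometry of a typical
8-channel 2 kHz upper-limb montage with 3 s activity holds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .canonical import FeatureMatrix
from .errors import ConfigurationError
from .preprocess import Recording

__all__ = [
    "StyleModel",
    "make_style_model",
    "generate_multiuser_features",
    "generate_raw_semg",
    "drop_channels",
]


@dataclass
class StyleModel:
    """Bilinear style/content model shared by all synthetic users.

    ``class_means`` (c x latent_dim) carry the motion content; each user gets
    a ``feature_dim x latent_dim`` style transform mixing the shared latent
    space into that user's observed feature space.
    """

    latent_dim: int
    class_means: np.ndarray
    within_class_sd: float
    noise_sd: float


def make_style_model(
    c: int,
    latent_dim: int = 8,
    within_class_sd: float = 1.0,
    noise_sd: float = 0.1,
    rng: np.random.Generator | None = None,
) -> StyleModel:
    """Draw class means separated by at least 3 within-class SDs pairwise."""
    rng = rng or np.random.default_rng(0)
    # sparse activation patterns: each motion recruits 2-3 of the latent
    # "muscles", so some class pairs are told apart by few channels only
    means = np.zeros((c, latent_dim))
    supports = set()
    for k in range(c):
        for _ in range(200):
            size = int(rng.integers(2, min(4, latent_dim + 1)))
            sup = tuple(sorted(rng.choice(latent_dim, size=size, replace=False).tolist()))
            if sup not in supports:
                supports.add(sup)
                break
        means[k, list(sup)] = (0.5 + np.abs(rng.normal(size=len(sup)))) * 2.0 * within_class_sd
    d = np.linalg.norm(means[:, None] - means[None, :], axis=-1)
    min_dist = d[np.triu_indices(c, 1)].min() if c > 1 else np.inf
    floor = 3.0 * within_class_sd
    if min_dist < floor:
        means *= floor * 1.05 / min_dist
    return StyleModel(
        latent_dim=latent_dim,
        class_means=means,
        within_class_sd=within_class_sd,
        noise_sd=noise_sd,
    )


def _style_transform(
    feature_dim: int,
    latent_dim: int,
    rng: np.random.Generator,
    cond_max: float = 100.0,
    cross_talk: float = 0.02,
) -> np.ndarray:
    """Random well-conditioned feature_dim x latent_dim mixing matrix.

    The matrix is block-dominant: the rows are split into ``latent_dim``
    contiguous blocks (the per-channel feature blocks when latent dims are
    muscles) and block ``i`` loads with unit scale on latent dim ``i`` but
    only ``cross_talk`` scale on the others — each electrode channel mainly
    sees its own muscle, with faint cross-talk.  Dropping channels
    therefore removes real information rather than redundant mixture.
    """
    block = feature_dim // latent_dim
    scale = np.full((feature_dim, latent_dim), cross_talk)
    for i in range(latent_dim):
        hi = (i + 1) * block if i < latent_dim - 1 else feature_dim
        scale[i * block : hi, i] = 1.0
    for _ in range(100):
        S = rng.normal(size=(feature_dim, latent_dim)) * scale
        if np.linalg.cond(S) < cond_max:
            return S
    raise RuntimeError("could not draw a well-conditioned style transform")


def generate_multiuser_features(
    n_users: int = 8,
    c: int = 12,
    n_per_class: int = 20,
    feature_dim: int = 64,
    style_strength: float = 1.0,
    latent_dim: int = 8,
    within_class_sd: float = 1.0,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> dict[str, FeatureMatrix]:
    """Generate per-user labeled feature matrices with shared class structure.

    Every user's features are ``F_u = Z S_u' + noise`` where the latent rows
    ``Z`` are class means plus within-class Gaussian spread and ``S_u`` is the
    user's style transform.  ``style_strength`` interpolates between one
    transform shared by all users (0: no individual differences) and a fresh
    random transform per user (1: full domain shift).  Deterministic per seed.
    """
    if c < 2:
        raise ConfigurationError("need at least 2 motion classes")
    if feature_dim < latent_dim:
        raise ConfigurationError(
            f"feature_dim {feature_dim} must be >= latent_dim {latent_dim}"
        )
    if style_strength < 0:
        raise ConfigurationError("style_strength must be non-negative")
    rng = np.random.default_rng(seed)
    model = make_style_model(c, latent_dim, within_class_sd, noise_sd, rng)
    base = _style_transform(feature_dim, latent_dim, rng)
    users: dict[str, FeatureMatrix] = {}
    for u in range(n_users):
        fresh = _style_transform(feature_dim, latent_dim, rng)
        S_u = (1.0 - style_strength) * base + style_strength * fresh
        labels = np.repeat(np.arange(1, c + 1), n_per_class)
        Z = model.class_means[labels - 1] + rng.normal(
            scale=within_class_sd, size=(labels.size, latent_dim)
        )
        F = Z @ S_u.T + rng.normal(scale=noise_sd, size=(labels.size, feature_dim))
        reps = np.tile(np.arange(n_per_class), c)
        users[f"N{u + 1}"] = FeatureMatrix(
            values=F,
            labels=labels,
            user_id=f"N{u + 1}",
            n_channels=feature_dim // 8 if feature_dim % 8 == 0 else None,
            groups=reps,
        )
    return users


def _bandlimited_noise(
    n: int, fs: float, rng: np.random.Generator, low: float = 20.0, high: float = 450.0
) -> np.ndarray:
    sos = signal.butter(4, [low, min(high, fs / 2 * 0.98)], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, rng.standard_normal(n))


def _activation_envelope(n: int, fs: float, ramp_s: float = 0.25) -> np.ndarray:
    """Smooth rise / hold / release profile of an isometric contraction."""
    t = np.arange(n) / fs
    total = n / fs
    ramp = np.clip(t / ramp_s, 0, 1) * np.clip((total - t) / ramp_s, 0, 1)
    return np.clip(ramp, 0, 1)


def generate_raw_semg(
    n_channels: int = 8,
    n_classes: int = 2,
    fs: float = 2000.0,
    hold_seconds: float = 3.0,
    reps: int = 4,
    seed: int = 0,
    class_activations: np.ndarray | None = None,
    interference_amp: float = 0.05,
    drift_amp: float = 0.2,
) -> list[Recording]:
    """Generate raw recordings: one per (class, repetition).

    Each channel is a 20-450 Hz Gaussian carrier scaled by that channel's
    class-specific activation gain and a rise/hold/release envelope, plus
    50 Hz mains interference and slow baseline drift (both of which the
    preprocessing stage is expected to remove).  ``class_activations``
    (n_classes x n_channels, gains in [0, 1]) overrides the random per-class
    activation pattern — a zero row yields a silent-muscle recording.
    """
    if fs < 1000:
        raise ConfigurationError(f"fs must be >= 1000 Hz, got {fs}")
    rng = np.random.default_rng(seed)
    n = int(round(hold_seconds * fs))
    if class_activations is None:
        class_activations = 0.2 + 0.8 * rng.random((n_classes, n_channels))
    class_activations = np.asarray(class_activations, dtype=float)
    if class_activations.shape != (n_classes, n_channels):
        raise ConfigurationError(
            f"class_activations must be {(n_classes, n_channels)}, "
            f"got {class_activations.shape}"
        )
    env = _activation_envelope(n, fs)
    t = np.arange(n) / fs
    recordings = []
    for k in range(n_classes):
        for _ in range(reps):
            samples = np.empty((n_channels, n))
            for ch in range(n_channels):
                carrier = _bandlimited_noise(n, fs, rng)
                mains = interference_amp * np.sin(
                    2 * np.pi * 50.0 * t + rng.uniform(0, 2 * np.pi)
                )
                drift = drift_amp * np.sin(
                    2 * np.pi * rng.uniform(0.1, 0.5) * t + rng.uniform(0, 2 * np.pi)
                )
                samples[ch] = class_activations[k, ch] * env * carrier + mains + drift
            recordings.append(
                Recording(samples=samples, fs=fs, motion_label=k + 1, user_id="sim")
            )
    return recordings


def drop_channels(data, n_drop: int, seed: int = 0, n_channels: int | None = None):
    """Remove ``n_drop`` whole channels, chosen uniformly at random.

    For a :class:`FeatureMatrix` the per-channel feature column blocks are
    removed and the matrix rebuilt (remove-and-retrain convention); for a list
    of :class:`Recording` the channel rows are removed.  The same seed always
    selects the same channels.
    """
    if isinstance(data, FeatureMatrix):
        ch = n_channels or data.n_channels
        if ch is None:
            raise ConfigurationError("FeatureMatrix has no channel count; pass n_channels")
        if n_drop >= ch:
            raise ConfigurationError(f"cannot drop {n_drop} of {ch} channels")
        if n_drop == 0:
            return data
        if data.n_features % ch:
            raise ConfigurationError(
                f"{data.n_features} feature columns not divisible into {ch} channels"
            )
        per = data.n_features // ch
        rng = np.random.default_rng(seed)
        dropped = set(rng.choice(ch, size=n_drop, replace=False).tolist())
        keep_cols = [
            c * per + j for c in range(ch) if c not in dropped for j in range(per)
        ]
        return replace(
            data,
            values=data.values[:, keep_cols],
            column_names=[data.column_names[j] for j in keep_cols],
            n_channels=ch - n_drop,
        )
    # sequence of recordings: drop the same channels from every recording
    recs = list(data)
    if not recs:
        return recs
    ch = recs[0].n_channels
    if n_drop >= ch:
        raise ConfigurationError(f"cannot drop {n_drop} of {ch} channels")
    if n_drop == 0:
        return recs
    rng = np.random.default_rng(seed)
    dropped = set(rng.choice(ch, size=n_drop, replace=False).tolist())
    keep = [c for c in range(ch) if c not in dropped]
    return [
        replace(
            r,
            samples=r.samples[keep],
            channel_names=[r.channel_names[c] for c in keep],
        )
        for r in recs
    ]
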