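"""Seeded synthetic benches with known ground truth.

Two generators:

* :func:`make_regression` — sparse linear-score classification problems
  with a known coefficient support, for studying support recovery and
  estimation bias of the penalties.
* :func:`make_eeg` — two-class oscillatory EEG whose class-discriminative
  band-power difference is confined to designated time-frequency units,
  emulating the event-related (de)synchronization mechanism motor-imagery
  decoding relies on.  Sources are band-pass-filtered white noise (not
  sinusoids) so that variance, not phase, carries the class information;
  trials are mixed to sensors through a random mixing matrix and overlaid
  with 1/f background noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import EEGTrialSet, TimeFrequencyUnit, bandpass

__all__ = [
    "SynthRegressionTruth",
    "SynthEEGTruth",
    "make_regression",
    "make_eeg",
]

#: Source amplitudes for make_eeg, chosen once: background rhythms and the
#: discriminative rhythm share unit variance so the class contrast is purely
#: the `effect` variance ratio; 1/f noise at 0.5 and sensor noise at 0.1
#: leave the easy bench (effect=3) decodable while a weak bench
#: (effect=1.5) stays away from ceiling.
BACKGROUND_STD = 1.0
SOURCE_STD = 1.0
PINK_STD = 0.5
SENSOR_STD = 0.1


@dataclass
class SynthRegressionTruth:
    w_true: np.ndarray
    support: np.ndarray
    snr: float
    n: int
    p: int
    seed: int


@dataclass
class SynthEEGTruth:
    mixing: np.ndarray
    discriminative_units: list[TimeFrequencyUnit]
    effect: float
    noise_color: float
    seed: int
    source_bands: list[tuple[float, float]] = field(default_factory=list)


def make_regression(
    n: int,
    p: int,
    k: int,
    effect: float = 1.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, SynthRegressionTruth]:
    """Sparse-score binary classification bench.

    X has i.i.d. standard-normal columns; k coefficients of magnitude
    ``effect`` (random signs, random positions) define a latent score
    ``X w + noise_sd * eps`` whose sign gives the labels (sign(0) -> +1).
    """
    if k > p:
        raise ValueError(f"k={k} informative columns exceed p={p}")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    support = np.sort(rng.choice(p, size=k, replace=False))
    w_true = np.zeros(p)
    w_true[support] = effect * rng.choice([-1.0, 1.0], size=k)
    latent = X @ w_true + noise_sd * rng.standard_normal(n)
    y = np.where(latent >= 0, 1, -1)
    sig = float(effect * np.sqrt(k))
    truth = SynthRegressionTruth(
        w_true=w_true,
        support=support,
        snr=(sig / noise_sd) if noise_sd > 0 else np.inf,
        n=n, p=p, seed=seed,
    )
    return X, y, truth


def _pink_noise(rng: np.random.Generator, shape: tuple, exponent: float) -> np.ndarray:
    """1/f^exponent power-spectrum noise along the last axis (FFT shaping)."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]  # keep DC finite
    spec *= f ** (-exponent / 2)
    out = np.fft.irfft(spec, n=n, axis=-1)
    return out / out.std(axis=-1, keepdims=True)


def _on_grid(u: TimeFrequencyUnit, dur: float) -> bool:
    w0, w1 = u.window
    b0, b1 = u.band
    return (
        0 <= w0 < w1 <= dur
        and abs(w0 / 0.5 - round(w0 / 0.5)) < 1e-9
        and abs((w1 - w0) - 2.0) < 1e-9
        and 4 <= b0 < b1 <= 40
        and abs((b1 - b0) - 4.0) < 1e-9
        and abs((b0 - 4) / 2 - round((b0 - 4) / 2)) < 1e-9
    )


def make_eeg(
    n_trials: int,
    channels: int = 8,
    fs: float = 250.0,
    dur: float = 4.0,
    discriminative_units: list[TimeFrequencyUnit] | None = None,
    effect: float = 3.0,
    noise_color: float = 1.0,
    seed: int = 0,
) -> tuple[EEGTrialSet, SynthEEGTruth]:
    """Two-class synthetic EEG with unit-confined band-power contrast.

    ``n_trials`` trials (balanced classes, interleaved labels) of
    ``dur`` seconds at ``fs`` Hz.  One band-limited noise source per
    discriminative unit has its variance scaled by ``effect`` for class +1
    trials inside the unit's time window only; ``channels - 1`` further
    band-limited background sources are class-independent.  effect=1
    reproduces the null (no separable unit).
    """
    units = discriminative_units or [TimeFrequencyUnit((1.0, 3.0), (10.0, 14.0))]
    for u in units:
        if not _on_grid(u, dur):
            raise ValueError(f"unit {u} is off the 2s/0.5s x 4Hz/2Hz grid")
    rng = np.random.default_rng(seed)
    n_samp = int(round(dur * fs))
    n_bg = max(channels - len(units), 1)
    # fixed pool of background rhythm bands (class-independent)
    bg_bands = [(6.0, 10.0), (8.0, 12.0), (12.0, 16.0), (18.0, 22.0),
                (24.0, 28.0), (30.0, 34.0), (14.0, 18.0), (20.0, 24.0)]
    bg_bands = [bg_bands[i % len(bg_bands)] for i in range(n_bg)]

    labels = np.where(np.arange(n_trials) % 2 == 0, 1, -1)
    n_src = len(units) + n_bg
    mixing = rng.standard_normal((channels, n_src))
    mixing /= np.linalg.norm(mixing, axis=0, keepdims=True)

    data = np.empty((n_trials, channels, n_samp))
    scale = np.sqrt(effect)
    for t in range(n_trials):
        sources = np.empty((n_src, n_samp))
        for j, u in enumerate(units):
            s = bandpass(rng.standard_normal((1, n_samp)), u.band, fs)[0]
            s = SOURCE_STD * s / s.std()
            if labels[t] == 1:
                i0 = int(round(u.window[0] * fs))
                i1 = int(round(u.window[1] * fs))
                s[i0:i1] *= scale
            sources[j] = s
        for j, band in enumerate(bg_bands):
            s = bandpass(rng.standard_normal((1, n_samp)), band, fs)[0]
            sources[len(units) + j] = BACKGROUND_STD * s / s.std()
        x = mixing @ sources
        x += PINK_STD * _pink_noise(rng, (channels, n_samp), noise_color)
        x += SENSOR_STD * rng.standard_normal((channels, n_samp))
        data[t] = x

    trials = EEGTrialSet(data=data, fs=fs, labels=labels, trial_window=(0.0, dur))
    truth = SynthEEGTruth(
        mixing=mixing,
        discriminative_units=list(units),
        effect=effect,
        noise_color=noise_color,
        seed=seed,
        source_bands=bg_bands,
    )
    return trials, truth
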