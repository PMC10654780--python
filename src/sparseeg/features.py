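"""Temporal-frequency-spatial feature extraction for motor-imagery EEG.

Each trial is cut into overlapping time windows, every window is band-pass
filtered with a Butterworth filter bank, and common spatial patterns (CSP)
are fitted per (window, band) time-frequency unit.  With one CSP filter
pair per unit, the cascaded feature vector has 2 features per unit; the
defaults — 2 s windows stepped by 0.5 s over a 4 s trial and 4 Hz-wide
bands stepped by 2 Hz over 4-40 Hz — yield 5 windows x 17 bands = 85 units
and 170 features.

CSP solves the generalized eigenproblem C+ u = mu (C+ + C-) u on the
trace-normalized class-average covariances; the eigenvectors with the
largest and smallest mu maximize the between-class variance ratio in
opposite directions.  Features are log band-power ratios
``log(var_j / sum_k var_k)`` over the unit's filter pair, the standard CSP
convention for event-related (de)synchronization contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.signal

__all__ = [
    "EEGTrialSet",
    "TimeFrequencyUnit",
    "CSPModel",
    "FeatureMatrix",
    "ExtractionConfig",
    "make_windows",
    "make_bands",
    "bandpass",
    "csp_fit",
    "csp_transform",
    "build_features",
]


@dataclass
class EEGTrialSet:
    """Epoched multichannel EEG trials with labels.

    data : (trials, channels, samples) array, volts or arbitrary units.
    fs : sampling rate in Hz.
    labels : per-trial class labels in {-1, +1}.
    trial_window : (start, end) seconds of each epoch relative to the cue.
    """

    data: np.ndarray
    fs: float
    labels: np.ndarray
    trial_window: tuple[float, float] = (0.0, 4.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        if self.labels.shape != (self.data.shape[0],):
            raise ValueError("labels length must match number of trials")
        if not np.all(np.isin(self.labels, (-1, 1))):
            raise ValueError("labels must be -1 or +1")
        if np.isnan(self.data).any():
            raise ValueError("NaN in trial data")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.data.shape[2] / self.fs


@dataclass(frozen=True)
class TimeFrequencyUnit:
    """One (time window, frequency band) cell of the extraction grid.

    Windows are half-open [start, end) in seconds; bands are (low, high) Hz.
    """

    window: tuple[float, float]
    band: tuple[float, float]

    def __post_init__(self) -> None:
        if not 0 <= self.window[0] < self.window[1]:
            raise ValueError(f"bad window {self.window}")
        if not 0 < self.band[0] < self.band[1]:
            raise ValueError(f"bad band {self.band}")


@dataclass
class CSPModel:
    """Fitted spatial filters, one (2 x channels) block per unit."""

    units: list[TimeFrequencyUnit]
    filters: list[np.ndarray]  # per unit: (2*n_pairs, channels)
    eigvals: list[np.ndarray]  # per unit: generalized eigenvalues kept
    n_pairs: int = 1


@dataclass
class FeatureMatrix:
    """Samples x features with per-column extraction metadata."""

    X: np.ndarray
    y: np.ndarray
    meta: list[dict] = field(repr=False)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if len(self.meta) != self.X.shape[1]:
            raise ValueError("meta length must equal number of columns")


@dataclass
class ExtractionConfig:
    """Extraction grid parameters (defaults follow the 85-unit layout)."""

    win_len_s: float = 2.0
    win_step_s: float = 0.5
    band_lo: float = 4.0
    band_hi: float = 40.0
    band_width: float = 4.0
    band_step: float = 2.0
    filter_order: int = 6
    n_pairs: int = 1


def make_windows(
    trial_len_s: float, win_len_s: float, step_s: float
) -> list[tuple[float, float]]:
    """Sliding windows [k*step, k*step + win_len) while they fit the trial."""
    if win_len_s > trial_len_s:
        raise ValueError(f"window {win_len_s}s longer than trial {trial_len_s}s")
    if step_s <= 0:
        raise ValueError("step must be > 0")
    out = []
    k = 0
    # small epsilon so 0.5-step arithmetic does not drop the last window
    while k * step_s + win_len_s <= trial_len_s + 1e-9:
        out.append((k * step_s, k * step_s + win_len_s))
        k += 1
    return out


def make_bands(
    lo: float, hi: float, width: float, step: float
) -> list[tuple[float, float]]:
    """Overlapping bands (lo + k*step, lo + k*step + width) within [lo, hi]."""
    if width <= 0 or step <= 0:
        raise ValueError("width and step must be > 0")
    if lo + width > hi:
        raise ValueError(f"first band ({lo}, {lo + width}) exceeds hi={hi}")
    out = []
    k = 0
    while lo + k * step + width <= hi + 1e-9:
        out.append((lo + k * step, lo + k * step + width))
        k += 1
    return out


def bandpass(
    segment: np.ndarray, band: tuple[float, float], fs: float, order: int = 6
) -> np.ndarray:
    """Zero-phase Butterworth band-pass of a (channels, samples) segment.

    ``order`` is the transfer-function order of the underlying band-pass
    (order 6 = 3 pole pairs); filtering is forward-backward (sosfiltfilt)
    with default odd-reflection padding, so the effective attenuation is
    doubled and the phase response is zero.
    """
    lo, hi = band
    if not 0 < lo < hi < fs / 2:
        raise ValueError(f"band {band} outside (0, fs/2={fs / 2})")
    sos = scipy.signal.butter(
        max(1, order // 2), [lo, hi], btype="bandpass", fs=fs, output="sos"
    )
    return scipy.signal.sosfiltfilt(sos, np.asarray(segment, dtype=float), axis=-1)


def _trial_cov(seg: np.ndarray) -> np.ndarray:
    """Trace-normalized covariance of a (channels, samples) segment."""
    c = seg @ seg.T
    tr = np.trace(c)
    if tr <= 0:
        raise np.linalg.LinAlgError("zero-power segment")
    return c / tr


def _shrink(c: np.ndarray, alpha: float) -> np.ndarray:
    """Shrink toward the scaled identity (Ledoit-Wolf-style target)."""
    n = c.shape[0]
    return (1 - alpha) * c + alpha * (np.trace(c) / n) * np.eye(n)


def csp_fit(
    segs_pos: np.ndarray, segs_neg: np.ndarray, n_pairs: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Fit CSP filters for one time-frequency unit.

    Parameters
    ----------
    segs_pos, segs_neg : (trials, channels, samples) filtered segments of
        the +1 and -1 classes; at least 2 trials each.
    n_pairs : number of eigenvector pairs to keep (1 -> 2 filters).

    Returns
    -------
    (filters, eigvals): (2*n_pairs, channels) filter rows sorted so the
    first half maximizes class +1 variance and the second half class -1;
    eigenvalues of C+ u = mu (C+ + C-) u in [0, 1] for the kept rows.
    """
    if len(segs_pos) < 2 or len(segs_neg) < 2:
        raise ValueError("need >= 2 trials per class for CSP")
    cp = np.mean([_trial_cov(s) for s in segs_pos], axis=0)
    cn = np.mean([_trial_cov(s) for s in segs_neg], axis=0)
    for alpha in (0.0, 1e-6, 1e-3, 1e-1):
        try:
            mu, u = scipy.linalg.eigh(_shrink(cp, alpha), _shrink(cp + cn, alpha))
            break
        except np.linalg.LinAlgError:
            continue
    else:
        raise np.linalg.LinAlgError("rank-deficient covariance despite shrinkage")
    order = np.argsort(mu)[::-1]  # descending: top = class +1 variance
    keep = np.concatenate([order[:n_pairs], order[-n_pairs:]])
    return u[:, keep].T.copy(), mu[keep]


def csp_transform(segment: np.ndarray, unit_filters: np.ndarray) -> np.ndarray:
    """Normalized log-variance features of one segment under unit filters.

    f_j = log( var(u_j' s) / sum_k var(u_k' s) ).
    """
    proj = unit_filters @ segment
    var = proj.var(axis=-1)
    tot = var.sum()
    if tot <= 0 or np.any(var <= 0):
        raise FloatingPointError("zero-variance CSP projection")
    return np.log(var / tot)


def _unit_grid(cfg: ExtractionConfig, trial_len_s: float) -> list[TimeFrequencyUnit]:
    wins = make_windows(trial_len_s, cfg.win_len_s, cfg.win_step_s)
    bands = make_bands(cfg.band_lo, cfg.band_hi, cfg.band_width, cfg.band_step)
    # window-major order: all bands of window 1, then window 2, ...
    return [TimeFrequencyUnit(w, b) for w in wins for b in bands]


def _segment(trials: np.ndarray, fs: float, window: tuple[float, float]) -> np.ndarray:
    i0 = int(round(window[0] * fs))
    i1 = int(round(window[1] * fs))
    return trials[:, :, i0:i1]


def build_features(
    train: EEGTrialSet,
    test: EEGTrialSet | None = None,
    cfg: ExtractionConfig | None = None,
) -> tuple[FeatureMatrix, FeatureMatrix | None, CSPModel]:
    """Extract the cascaded temporal-frequency-spatial feature matrix.

    Windows are cut first, then band-pass filtered, then CSP is fitted per
    unit on the *training* trials only and applied to both sets (test
    trials never influence the filters).  Columns are ordered window-major,
    then band, then CSP index; P = 2 * n_pairs * n_units.
    """
    cfg = cfg or ExtractionConfig()
    if test is not None and (
        test.fs != train.fs or test.n_channels != train.n_channels
    ):
        raise ValueError("train/test sampling rate or channel count mismatch")
    if not (np.any(train.labels == 1) and np.any(train.labels == -1)):
        raise ValueError("both classes must be present in training trials")

    units = _unit_grid(cfg, train.duration)
    pos = train.labels == 1
    filters, eigvals = [], []
    cols_train = []
    cols_test = [] if test is not None else None
    for unit in units:
        seg_tr = bandpass(
            _segment(train.data, train.fs, unit.window),
            unit.band, train.fs, cfg.filter_order,
        )
        f, mu = csp_fit(seg_tr[pos], seg_tr[~pos], cfg.n_pairs)
        filters.append(f)
        eigvals.append(mu)
        cols_train.append(
            np.stack([csp_transform(s, f) for s in seg_tr])
        )
        if test is not None:
            seg_te = bandpass(
                _segment(test.data, test.fs, unit.window),
                unit.band, test.fs, cfg.filter_order,
            )
            cols_test.append(np.stack([csp_transform(s, f) for s in seg_te]))

    meta = [
        {
            "window_start": u.window[0],
            "window_end": u.window[1],
            "band_lo": u.band[0],
            "band_hi": u.band[1],
            "csp_index": j,
        }
        for u in units
        for j in range(2 * cfg.n_pairs)
    ]
    model = CSPModel(units=units, filters=filters, eigvals=eigvals, n_pairs=cfg.n_pairs)
    fm_train = FeatureMatrix(np.hstack(cols_train), train.labels, meta)
    fm_test = (
        FeatureMatrix(np.hstack(cols_test), test.labels, meta)
        if test is not None
        else None
    )
    return fm_train, fm_test, model


def apply_features(
    trials: EEGTrialSet, model: CSPModel, cfg: ExtractionConfig | None = None
) -> FeatureMatrix:
    """Apply an already-fitted CSP model to new trials."""
    cfg = cfg or ExtractionConfig()
    cols = []
    for unit, f in zip(model.units, model.filters):
        seg = bandpass(
            _segment(trials.data, trials.fs, unit.window),
            unit.band, trials.fs, cfg.filter_order,
        )
        cols.append(np.stack([csp_transform(s, f) for s in seg]))
    meta = [
        {
            "window_start": u.window[0],
            "window_end": u.window[1],
            "band_lo": u.band[0],
            "band_hi": u.band[1],
            "csp_index": j,
        }
        for u in model.units
        for j in range(2 * model.n_pairs)
    ]
    return FeatureMatrix(np.hstack(cols), trials.labels, meta)
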