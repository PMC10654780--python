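"""Windowing, filter bank, CSP and the cascaded feature matrix."""

import numpy as np
import pytest
import scipy.linalg

from sparseeg.features import (
    EEGTrialSet,
    ExtractionConfig,
    bandpass,
    build_features,
    csp_fit,
    csp_transform,
    make_bands,
    make_windows,
)


def test_default_window_layout():
    wins = make_windows(4.0, 2.0, 0.5)
    assert wins == [(0.0, 2.0), (0.5, 2.5), (1.0, 3.0), (1.5, 3.5), (2.0, 4.0)]


@pytest.mark.parametrize("trial_len,expected", [(2.0, 1), (3.0, 3)])
def test_window_count_edge_cases(trial_len, expected):
    assert len(make_windows(trial_len, 2.0, 0.5)) == expected


def test_window_longer_than_trial_rejected():
    with pytest.raises(ValueError):
        make_windows(1.0, 2.0, 0.5)


def test_default_band_layout():
    bands = make_bands(4.0, 40.0, 4.0, 2.0)
    assert len(bands) == 17
    assert bands[0] == (4.0, 8.0)
    assert bands[1] == (6.0, 10.0)
    assert bands[-1] == (36.0, 40.0)


def test_band_edge_cases():
    assert make_bands(4.0, 8.0, 4.0, 2.0) == [(4.0, 8.0)]
    assert make_bands(4.0, 12.0, 4.0, 4.0) == [(4.0, 8.0), (8.0, 12.0)]
    with pytest.raises(ValueError):
        make_bands(4.0, 40.0, 0.0, 2.0)


def _tone(freq, fs=250.0, dur=4.0):
    t = np.arange(int(fs * dur)) / fs
    return np.sin(2 * np.pi * freq * t)[None, :]


def test_bandpass_passes_center_tone_and_rejects_out_of_band():
    fs = 250.0
    inband = bandpass(_tone(10, fs), (8, 12), fs)
    out = bandpass(_tone(30, fs), (8, 12), fs)
    core = slice(100, -100)  # ignore filter edges
    amp_in = np.abs(inband[0, core]).max()
    amp_out = np.abs(out[0, core]).max()
    assert amp_in == pytest.approx(1.0, rel=0.1)
    assert amp_out < 0.1


def test_bandpass_kills_dc():
    fs = 250.0
    dc = bandpass(np.ones((2, 1000)), (8, 12), fs)
    assert np.abs(dc).max() < 1e-6


def test_bandpass_rejects_band_at_nyquist():
    with pytest.raises(ValueError):
        bandpass(np.zeros((1, 100)), (100, 130), 250.0)


def test_csp_diagonal_covariances_pick_coordinate_axes():
    rng = np.random.default_rng(0)
    # class +: variance (4,1); class -: variance (1,4); 200 samples/trial
    pos = np.stack([np.diag([2.0, 1.0]) @ rng.standard_normal((2, 400))
                    for _ in range(30)])
    neg = np.stack([np.diag([1.0, 2.0]) @ rng.standard_normal((2, 400))
                    for _ in range(30)])
    filters, mu = csp_fit(pos, neg)
    assert mu[0] == pytest.approx(0.8, abs=0.05)
    assert mu[1] == pytest.approx(0.2, abs=0.05)
    # filters align with the coordinate axes
    for row, axis in zip(filters, ([1, 0], [0, 1])):
        d = np.abs(row / np.linalg.norm(row))
        assert d[np.argmax(axis)] > 0.99


def test_csp_equal_covariances_are_uninformative():
    rng = np.random.default_rng(1)
    trials = np.stack([rng.standard_normal((3, 500)) for _ in range(40)])
    _, mu = csp_fit(trials[:20], trials[20:])
    assert np.allclose(mu, 0.5, atol=0.05)


def test_csp_recovers_known_discriminative_direction():
    rng = np.random.default_rng(2)
    n_ch, n_s = 8, 500
    mixing = rng.standard_normal((n_ch, n_ch))
    d = mixing[:, 0]  # sensor pattern of the discriminative source
    pos, neg = [], []
    for _ in range(40):
        src = rng.standard_normal((n_ch, n_s))
        src[0] *= 3.0  # class + has high variance in source 0
        pos.append(mixing @ src)
        src = rng.standard_normal((n_ch, n_s))
        neg.append(mixing @ src)
    filters, _ = csp_fit(np.stack(pos), np.stack(neg))
    # the top filter's spatial pattern (via pseudo-inverse on the pooled
    # covariance) should align with the true source pattern
    w = filters[0]
    proj_pos = np.array([w @ s for s in pos])
    proj_src = np.array([(np.linalg.pinv(mixing) @ s)[0] for s in pos])
    r = np.corrcoef(proj_pos.ravel(), proj_src.ravel())[0, 1]
    assert abs(r) > 0.95


def test_csp_transform_variance_arithmetic():
    rng = np.random.default_rng(3)
    seg = rng.standard_normal((2, 1000))
    filters = np.eye(2)
    f = csp_transform(seg, filters)
    var = seg.var(axis=1)
    want = np.log(var / var.sum())
    assert np.allclose(f, want)
    # equal variances -> both features log(0.5)
    seg2 = np.stack([seg[0], seg[0][::-1]])
    f2 = csp_transform(seg2, np.eye(2))
    assert np.allclose(f2, np.log(0.5), atol=1e-12)


def test_feature_count_identity(small_eeg):
    trials, _ = small_eeg
    fm, _, model = build_features(trials)
    # default grid: 5 windows x 17 bands = 85 units, 2 features each
    assert len(model.units) == 85
    assert fm.X.shape == (trials.n_trials, 170)
    assert len(fm.meta) == 170
    # window-major order, then band, then CSP index
    assert fm.meta[0]["window_start"] == 0.0 and fm.meta[0]["band_lo"] == 4.0
    assert fm.meta[2]["band_lo"] == 6.0
    assert fm.meta[34]["window_start"] == 0.5


def test_single_unit_yields_two_columns(small_eeg):
    trials, _ = small_eeg
    cfg = ExtractionConfig(win_len_s=4.0, win_step_s=1.0,
                           band_lo=8.0, band_hi=12.0, band_width=4.0,
                           band_step=2.0)
    fm, _, model = build_features(trials, cfg=cfg)
    assert fm.X.shape[1] == 2
    assert len(model.units) == 1


def test_no_test_set_leakage(small_eeg):
    trials, _ = small_eeg
    train = EEGTrialSet(trials.data[:30], trials.fs, trials.labels[:30])
    test = EEGTrialSet(trials.data[30:], trials.fs, trials.labels[30:])
    perm = np.random.default_rng(0).permutation(10)
    test_perm = EEGTrialSet(test.data[perm], test.fs, test.labels[perm])
    cfg = ExtractionConfig(band_lo=8.0, band_hi=16.0)  # small grid for speed
    fm1, fmt1, m1 = build_features(train, test, cfg)
    fm2, fmt2, m2 = build_features(train, test_perm, cfg)
    for a, b in zip(m1.filters, m2.filters):
        assert np.array_equal(a, b)
    assert np.array_equal(fm1.X, fm2.X)
    assert np.array_equal(fmt1.X[perm], fmt2.X)


def test_separability_concentrates_in_designated_unit(small_eeg):
    """Two-sample t statistic of CSP features peaks in the planted unit."""
    trials, truth = small_eeg
    fm, _, model = build_features(trials)
    y = fm.y
    t_per_unit = np.zeros(len(model.units))
    for u in range(len(model.units)):
        cols = fm.X[:, 2 * u:2 * u + 2]
        tvals = []
        for j in range(2):
            a, b = cols[y == 1, j], cols[y == -1, j]
            s = np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
            tvals.append(abs(a.mean() - b.mean()) / s)
        t_per_unit[u] = max(tvals)
    planted = truth.discriminative_units[0]
    best = model.units[int(np.argmax(t_per_unit))]
    # the best unit overlaps the planted window and band
    assert best.window[0] < planted.window[1] and best.window[1] > planted.window[0]
    assert best.band[0] < planted.band[1] and best.band[1] > planted.band[0]
    # most non-overlapping units are near chance
    overlap = np.array([
        u.window[0] < planted.window[1] and u.window[1] > planted.window[0]
        and u.band[0] < planted.band[1] and u.band[1] > planted.band[0]
        for u in model.units
    ])
    frac_quiet = np.mean(t_per_unit[~overlap] < t_per_unit.max() / 2)
    assert frac_quiet >= 0.9


def test_trial_set_validation():
    with pytest.raises(ValueError):
        EEGTrialSet(np.zeros((2, 3, 4)), fs=0.0, labels=np.array([1, -1]))
    with pytest.raises(ValueError):
        EEGTrialSet(np.zeros((2, 3, 4)), fs=250.0, labels=np.array([1, 2]))
    bad = np.zeros((2, 3, 4))
    bad[0, 0, 0] = np.nan
    with pytest.raises(ValueError):
        EEGTrialSet(bad, fs=250.0, labels=np.array([1, -1]))
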