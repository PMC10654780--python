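import numpy as np
import pytest

from sparseeg.features import EEGTrialSet, TimeFrequencyUnit
from sparseeg.synthetic import make_eeg, make_regression


@pytest.fixture(scope="session")
def small_eeg():
    """40-trial synthetic EEG cohort with one discriminative unit."""
    trials, truth = make_eeg(40, channels=6, effect=3.0, seed=5)
    return trials, truth


@pytest.fixture(scope="session")
def regression_bench():
    """Seeded sparse-score classification problem."""
    return make_regression(80, 60, 5, effect=1.5, noise_sd=1.0, seed=3)


def brute_prox_1d(v, lam, beta, phi, span=1.0, n_grid=100_001):
    """Dense-grid + local-refinement argmin of (beta/2)(w-v)^2 + phi(w).

    The independent scalar oracle for every proximity operator.
    """
    from scipy.optimize import minimize_scalar

    g = np.linspace(-abs(v) - span, abs(v) + span, n_grid)
    h = beta / 2 * (g - v) ** 2 + phi(g)
    i = int(np.argmin(h))
    lo, hi = g[max(i - 2, 0)], g[min(i + 2, n_grid - 1)]
    res = minimize_scalar(
        lambda w: beta / 2 * (w - v) ** 2 + phi(np.asarray(w)),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-12},
    )
    return float(res.x), float(res.fun)
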