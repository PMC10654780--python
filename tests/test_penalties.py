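"""Penalty values and proximity operators against independent 1-D oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sparseeg.penalties import (
    PenaltyError,
    PenaltySpec,
    penalty_value,
    prox,
    prox_cauchy,
    prox_group,
    prox_l1,
    prox_mcp,
    prox_scad,
    _mcp_phi,
    _scad_phi,
)

from conftest import brute_prox_1d

GAMMAS = {"l1": None, "scad": 3.0, "mcp": 2.0, "cauchy": 0.007}


def scalar_phi(spec):
    """Scalar penalty phi(w) for the 1-D oracle."""
    lam, gam = spec.lam, spec.gamma
    if spec.family == "l1":
        return lambda w: lam * np.abs(w)
    if spec.family == "scad":
        return lambda w: _scad_phi(np.abs(w), lam, gam)
    if spec.family == "mcp":
        return lambda w: _mcp_phi(np.abs(w), lam, gam)
    return lambda w: lam * np.log((gam**2 + w**2) / gam)


# ---------------------------------------------------------------------------
# penalty values


def test_penalty_of_zero_vector_is_zero_for_l1():
    assert penalty_value(np.zeros(7), PenaltySpec("l1", 1.0)) == 0.0


def test_scad_plateau_contribution():
    # |w| = 5 >= gamma*lam puts the coefficient on the constant branch
    spec = PenaltySpec("scad", 1.0, gamma=3.0)
    assert penalty_value(np.array([5.0]), spec) == pytest.approx((3 + 1) * 1.0 / 2)


def test_cauchy_penalty_offset_and_nonnegativity_of_increment():
    spec = PenaltySpec("cauchy", 1.3, gamma=0.007)
    p0 = penalty_value(np.zeros(4), spec)
    assert p0 == pytest.approx(1.3 * 4 * np.log(0.007))
    rng = np.random.default_rng(0)
    for _ in range(20):
        w = rng.standard_normal(4) * 3
        assert penalty_value(w, spec) - p0 >= 0


@pytest.mark.parametrize("family,gamma,bad", [
    ("scad", 2.0, True), ("scad", 2.01, False),
    ("mcp", 1.0, True), ("mcp", 1.5, False),
    ("cauchy", 0.0, True), ("cauchy", 0.1, False),
])
def test_gamma_validation(family, gamma, bad):
    if bad:
        with pytest.raises(PenaltyError):
            PenaltySpec(family, 1.0, gamma=gamma)
    else:
        PenaltySpec(family, 1.0, gamma=gamma)


@pytest.mark.parametrize("theta", [1.0, 3.0])  # breakpoints lam, gamma*lam
def test_scad_continuity_at_breakpoints(theta):
    lam, gam = 1.0, 3.0
    eps = 1e-13
    below = _scad_phi(np.array([theta - eps]), lam, gam)[0]
    above = _scad_phi(np.array([theta + eps]), lam, gam)[0]
    assert abs(below - above) < 1e-12


def test_mcp_continuity_at_breakpoint():
    lam, gam = 0.7, 2.0
    eps = 1e-13
    t = gam * lam
    below = _mcp_phi(np.array([t - eps]), lam, gam)[0]
    above = _mcp_phi(np.array([t + eps]), lam, gam)[0]
    assert abs(below - above) < 1e-12


# ---------------------------------------------------------------------------
# soft threshold


def test_soft_threshold_closed_form():
    assert prox_l1(np.array([1.5]), 1.0)[0] == pytest.approx(0.5)
    v = np.array([-0.4, 0.0, 2.2])
    assert np.allclose(prox_l1(v, 0.0), v)
    assert prox_l1(np.array([-0.3]), 1.0)[0] == 0.0
    with pytest.raises(PenaltyError):
        prox_l1(v, -0.1)


# ---------------------------------------------------------------------------
# scalar prox families vs the brute-force oracle


@pytest.mark.parametrize("family", ["l1", "scad", "mcp", "cauchy"])
@pytest.mark.parametrize("lam", [0.01, 0.5])
@pytest.mark.parametrize("beta", [1.0, 10.0])
def test_prox_matches_scalar_oracle(family, lam, beta):
    """Each prox coincides with dense-grid + refined 1-D minimization.

    Objective values are compared where the scalar problem is degenerate
    (flat branches admit a continuum of minimizers); argmins elsewhere.
    """
    spec = PenaltySpec(family, lam, gamma=GAMMAS[family])
    phi = scalar_phi(spec)
    for v in np.arange(-3.0, 3.01, 0.25):
        got = float(prox(np.array([v]), spec, beta)[0])
        want, fval = brute_prox_1d(v, lam, beta, phi)
        hgot = beta / 2 * (got - v) ** 2 + float(phi(np.asarray(got)))
        assert hgot <= fval + 1e-8, f"v={v}: prox objective above oracle"
        assert abs(got - want) < 1e-4 or abs(hgot - fval) < 1e-10


def test_cauchy_prox_trivial_cases():
    spec = PenaltySpec("cauchy", 0.0, gamma=0.007)
    v = np.array([-1.2, 0.0, 3.4])
    assert np.allclose(prox_cauchy(v, spec, 1.0), v)  # lam=0 -> identity
    spec = PenaltySpec("cauchy", 0.8, gamma=0.007)
    assert prox_cauchy(np.array([0.0]), spec, 1.0)[0] == 0.0


def test_cauchy_stationarity_cubic_residual():
    """Every returned root satisfies the stationarity cubic."""
    rng = np.random.default_rng(1)
    for _ in range(200):
        v = rng.uniform(-3, 3)
        lam = rng.uniform(0.01, 1.0)
        beta = rng.uniform(0.5, 10.0)
        gam = rng.choice([0.007, 0.1, 1.0])
        spec = PenaltySpec("cauchy", lam, gamma=gam)
        r = float(prox_cauchy(np.array([v]), spec, beta)[0])
        resid = r**3 - v * r**2 + (gam**2 + 2 * lam / beta) * r - v * gam**2
        assert abs(resid) < 1e-8 * max(1.0, abs(v) ** 3)


def test_scad_no_shrinkage_zone_and_identity():
    spec = PenaltySpec("scad", 1.0, gamma=3.0)
    assert prox_scad(np.array([4.0]), spec, 1.0)[0] == pytest.approx(4.0)
    spec0 = PenaltySpec("scad", 0.0, gamma=3.0)
    v = np.array([0.3, -2.0])
    assert np.allclose(prox_scad(v, spec0, 1.0), v)


def test_mcp_flat_region_identity():
    spec = PenaltySpec("mcp", 1.0, gamma=2.0)
    assert prox_mcp(np.array([5.0]), spec, 1.0)[0] == pytest.approx(5.0)


def test_scad_degenerate_gamma_warns():
    spec = PenaltySpec("scad", 1.0, gamma=2.5)
    with pytest.warns(RuntimeWarning):
        prox_scad(np.array([1.0]), spec, beta=0.5)  # gamma <= 1 + 1/beta


# ---------------------------------------------------------------------------
# group prox


def test_group_prox_block_kill_and_identity():
    groups = np.zeros(3, dtype=int)
    spec = PenaltySpec("group", 10.0, groups=groups)
    v = np.array([0.3, -0.2, 0.1])
    assert np.allclose(prox_group(v, spec, 1.0), 0.0)  # ||v|| < lam*sqrt(3)
    spec0 = PenaltySpec("group", 0.0, groups=groups)
    assert np.allclose(prox_group(v, spec0, 1.0), v)


def test_group_prox_matches_numeric_block_oracle():
    from scipy.optimize import minimize

    rng = np.random.default_rng(7)
    groups = np.array([0, 0, 1, 1])
    lam = 0.3
    for beta in (1.0, 2.5):
        v = rng.standard_normal(4)
        spec = PenaltySpec("group", lam, groups=groups)
        got = prox_group(v, spec, beta)
        for b in ([0, 1], [2, 3]):
            vb = v[b]

            def h(w):
                return beta / 2 * np.sum((w - vb) ** 2) + lam * np.sqrt(2) * np.linalg.norm(w)

            res = minimize(h, vb * 0.5, method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-14})
            assert np.allclose(got[b], res.x, atol=1e-4)


def test_sparse_group_prox_composition():
    groups = np.array([0, 0, 1, 1])
    spec = PenaltySpec("sparse_group", 0.2, lam_group=0.3, groups=groups)
    v = np.array([1.0, -0.1, 0.05, 0.08])
    got = prox_group(v, spec, 1.0)
    # elementwise soft-threshold first: second block dies entirely
    assert got[2] == 0.0 and got[3] == 0.0
    assert got[0] > 0 and got[1] == 0.0


def test_empty_group_rejected():
    spec = PenaltySpec("group", 1.0, groups=np.array([0, 0, 2, 2]))
    # ids {0,2} partition all 4 features: fine
    prox_group(np.ones(4), spec, 1.0)
    with pytest.raises(PenaltyError):
        spec.group_blocks(5)  # length mismatch


# ---------------------------------------------------------------------------
# property tests


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    v=st.floats(-5, 5),
    lam=st.floats(0.01, 1.0),
    beta=st.sampled_from([0.5, 1.0, 10.0]),
    family=st.sampled_from(["l1", "scad", "mcp", "cauchy"]),
)
def test_odd_symmetry_and_shrinkage(v, lam, beta, family):
    import warnings

    spec = PenaltySpec(family, lam, gamma=GAMMAS[family])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = float(prox(np.array([v]), spec, beta)[0])
        m = float(prox(np.array([-v]), spec, beta)[0])
    assert p == pytest.approx(-m, abs=1e-12)
    assert abs(p) <= abs(v) + 1e-12
    assert p == 0 or np.sign(p) == np.sign(v)


@pytest.mark.parametrize("family", ["l1", "scad", "mcp", "cauchy"])
def test_prox_monotone_in_magnitude(family):
    spec = PenaltySpec(family, 0.4, gamma=GAMMAS[family])
    v = np.linspace(0, 4, 400)
    p = prox(v, spec, 1.0)
    assert np.all(np.diff(p) >= -1e-10)


def test_cauchy_near_unbiasedness_of_retained_coefficients():
    """Above the selection threshold the Cauchy prox shrinks relatively
    less than the soft threshold; below it, coefficients are discarded
    outright (near-zero root) rather than biased."""
    lam, beta, gam = 0.2, 1.0, 0.007
    spec = PenaltySpec("cauchy", lam, gamma=gam)
    for v in np.arange(2.5, 6.0, 0.25):
        p = float(prox_cauchy(np.array([v]), spec, beta)[0])
        rel = (v - abs(p)) / v
        assert rel < lam / v
    # sub-threshold regime: global minimizer sits in the near-zero basin
    p = float(prox_cauchy(np.array([1.0]), spec, beta)[0])
    assert abs(p) < 0.01
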