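"""Proximal-gradient solver for penalized least squares.

Minimizes ``(1/2)||y - Xw||^2 + P(w)`` for any :class:`~sparseeg.penalties.
PenaltySpec` by iterating a gradient step on the differentiable fidelity
term through an intermediate point

    v_t = w_t - (1/beta) X'(X w_t - y),      beta = ||X'X||_2,

followed by the penalty's proximity operator, ``w_{t+1} = prox(v_t, beta)``.
The fixed step 1/beta (no backtracking, no momentum) makes the scheme ISTA
with the spectral-norm Lipschitz constant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .penalties import PenaltySpec, penalty_value, prox

__all__ = ["SolverConfig", "SolverState", "spectral_step", "objective", "fit"]

logger = logging.getLogger(__name__)


@dataclass
class SolverConfig:
    """Iteration cap, relative-change tolerance and initial point."""

    max_iter: int = 1000
    tol: float = 1e-6
    init: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")


@dataclass
class SolverState:
    """Result of a proximal-gradient run.

    Attributes
    ----------
    w : final weight vector.
    v : last intermediate (pre-prox) point.
    tau : number of iterations performed.
    objective_trace : objective value at w^0 .. w^tau (length tau + 1).
    beta : spectral step scale ||X'X||_2 used.
    converged : whether the relative-change criterion was met.
    """

    w: np.ndarray
    v: np.ndarray
    tau: int
    objective_trace: list[float] = field(repr=False)
    beta: float
    converged: bool


def spectral_step(X: np.ndarray, tol: float = 1e-8, max_iter: int = 5000) -> float:
    """Largest eigenvalue of X'X (= squared spectral norm of X).

    Power iteration on the map ``b -> X'(Xb)`` to relative tolerance,
    avoiding forming the P x P Gram matrix.
    """
    X = np.asarray(X, dtype=float)
    if X.size == 0 or not np.any(X):
        raise ValueError("degenerate input: X is empty or all zeros")
    rng = np.random.default_rng(0)
    b = rng.standard_normal(X.shape[1])
    b /= np.linalg.norm(b)
    lam_old = 0.0
    for _ in range(max_iter):
        z = X.T @ (X @ b)
        nrm = np.linalg.norm(z)
        if nrm == 0:  # b landed in the null space; restart
            b = rng.standard_normal(X.shape[1])
            b /= np.linalg.norm(b)
            continue
        b = z / nrm
        lam = float(b @ (X.T @ (X @ b)))
        if abs(lam - lam_old) <= tol * max(1.0, abs(lam)):
            return lam
        lam_old = lam
    return lam_old


def objective(X: np.ndarray, y: np.ndarray, w: np.ndarray, spec: PenaltySpec) -> float:
    """Full objective (1/2)||y - Xw||^2 + P(w)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    w = np.asarray(w, dtype=float).ravel()
    if X.shape != (y.size, w.size):
        raise ValueError(
            f"shape mismatch: X {X.shape}, y {y.shape}, w {w.shape}"
        )
    r = y - X @ w
    return 0.5 * float(r @ r) + penalty_value(w, spec)


def fit(
    X: np.ndarray,
    y: np.ndarray,
    spec: PenaltySpec,
    cfg: SolverConfig | None = None,
    beta: float | None = None,
) -> SolverState:
    """Run proximal gradient to convergence or the iteration cap.

    Parameters
    ----------
    X : (N, P) sample matrix.
    y : length-N labels in {-1, +1} (accepted as reals).
    spec : penalty family and parameters.
    cfg : stopping rule and initialization; defaults to w0 = 0,
        tol 1e-6 on relative iterate change, 1000 iterations.
    beta : precomputed spectral step scale, to amortize across
        regularization-path fits on the same X.

    Returns
    -------
    SolverState with the final weights and the full objective trace.
    """
    cfg = cfg or SolverConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite rows in X")
    n, p = X.shape
    if beta is None:
        beta = spectral_step(X)
    w = np.zeros(p) if cfg.init is None else np.asarray(cfg.init, dtype=float).copy()

    trace = [objective(X, y, w, spec)]
    v = w.copy()
    converged = False
    tau = 0
    for tau in range(1, cfg.max_iter + 1):
        v = w - (X.T @ (X @ w - y)) / beta
        w_new = prox(v, spec, beta)
        obj = objective(X, y, w_new, spec)
        if not np.isfinite(obj):
            raise FloatingPointError(
                f"solver diverged at iteration {tau} (family={spec.family}, "
                f"lam={spec.lam}, gamma={spec.gamma})"
            )
        trace.append(obj)
        delta = np.linalg.norm(w_new - w)
        rel = delta / max(1.0, np.linalg.norm(w))
        w = w_new
        if logger.isEnabledFor(logging.DEBUG):
            logger.debug(
                "tau=%d obj=%.6e |dw|=%.3e active=%d",
                tau, obj, delta, int(np.count_nonzero(w)),
            )
        if rel < cfg.tol:
            converged = True
            break
    return SolverState(
        w=w, v=v, tau=tau, objective_trace=trace, beta=beta, converged=converged
    )
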