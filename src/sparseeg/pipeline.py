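"""Embedded feature-selection-and-classification pipeline.

Sparse regularization performs feature selection and classification in one
model: the fitted weight vector w both selects features (exact zeros drop
columns) and classifies by sign(Xw).  The regularization weight lambda is
chosen by stratified 10-fold cross-validation over the 51-point grid
{2^e : e = -5, -4.8, ..., 5}, taking the lambda with the best mean fold
accuracy (ties break toward the largest lambda, i.e. the sparsest model).

Features are z-scored with training-set statistics and no intercept is
fitted, so sign(Xw) is taken about the training-feature center.  In
cross-validation the standardizer is refit per fold; CSP filters (fitted
once on the full training set, upstream of this module) are reused across
folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from . import solver
from .features import (
    CSPModel,
    EEGTrialSet,
    ExtractionConfig,
    FeatureMatrix,
    build_features,
)
from .penalties import DEFAULT_GAMMA, PenaltySpec

__all__ = [
    "Standardizer",
    "DecodingModel",
    "CVResult",
    "DecodingConfig",
    "lambda_grid",
    "select_lambda",
    "fit_model",
    "predict",
    "decode",
    "evaluate_subject_dependent",
    "evaluate_subject_independent",
]


@dataclass
class Standardizer:
    """Per-column mean/scale learned from training rows only."""

    mean: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale = np.where(scale > 0, scale, 1.0)
        return cls(mean=mean, scale=scale)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.scale


@dataclass
class DecodingModel:
    """Fitted sparse decoding model: standardizer, penalty, weights."""

    standardizer: Standardizer
    spec: PenaltySpec
    w: np.ndarray
    selected: np.ndarray  # indices with w != 0
    extraction: ExtractionConfig | None = None
    csp: CSPModel | None = None
    meta: list = field(default=None, repr=False)


@dataclass
class CVResult:
    """Cross-validation path over the lambda grid."""

    grid: np.ndarray
    fold_accuracies: np.ndarray  # (len(grid), folds)
    mean_accuracy: np.ndarray
    chosen_lam: float

    @property
    def best_accuracy(self) -> float:
        return float(self.mean_accuracy.max())


@dataclass
class DecodingConfig:
    """End-to-end decoding settings."""

    family: str = "cauchy"
    gamma: float | None = None
    lam: float | None = None  # None -> choose by CV
    lam_group: float = 0.5
    folds: int = 10
    seed: int = 0
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    solver_cfg: solver.SolverConfig = field(default_factory=solver.SolverConfig)
    grid: np.ndarray | None = None


def lambda_grid() -> np.ndarray:
    """The 51-value grid {2^e : e = -5, -4.8, ..., 4.8, 5}."""
    return 2.0 ** np.linspace(-5.0, 5.0, 51)


def _default_groups(p: int) -> np.ndarray:
    """Default group map: one group per time-frequency unit (2 features)."""
    return np.repeat(np.arange((p + 1) // 2), 2)[:p]


def effective_weights(w: np.ndarray, spec: PenaltySpec) -> np.ndarray:
    """Model weights after deselection.

    The convex and SCAD/MCP proximity operators produce exact zeros, so
    their weights pass through unchanged.  The Cauchy prox never does: its
    stationarity cubic has constant term -v*gamma^2, so deselected
    coordinates land on a near-zero root of magnitude O(gamma^2) instead of
    0.  Coefficients below the penalty's own scale gamma sit in that
    near-zero basin (where the penalty is locally quadratic and the
    coordinate carries no selected signal) and are treated as deselected:
    the decoding model zeroes them.
    """
    if spec.family != "cauchy":
        return w
    return np.where(np.abs(w) > spec.gamma, w, 0.0)


def make_spec(cfg: DecodingConfig, p: int, lam: float) -> PenaltySpec:
    """PenaltySpec for cfg's family at a given lambda and dimension."""
    family = cfg.family
    groups = None
    if family in ("group", "sparse_group"):
        groups = _default_groups(p)
    return PenaltySpec(
        family=family,
        lam=lam,
        gamma=cfg.gamma if cfg.gamma is not None else DEFAULT_GAMMA.get(family),
        lam_group=cfg.lam_group,
        groups=groups,
    )


def _path_fit(
    X: np.ndarray,
    y: np.ndarray,
    spec_template: PenaltySpec,
    grid: np.ndarray,
    solver_cfg: solver.SolverConfig,
    beta: float,
) -> list[np.ndarray]:
    """Warm-started fits along the grid (descending lambda), returned in
    grid order."""
    order = np.argsort(grid)[::-1]
    w = np.zeros(X.shape[1])
    out = [None] * len(grid)
    for i in order:
        spec = replace(spec_template, lam=float(grid[i]))
        st = solver.fit(
            X, y, spec,
            cfg=replace(solver_cfg, init=w),
            beta=beta,
        )
        w = st.w
        out[i] = st.w
    return out


def select_lambda(
    X: np.ndarray,
    y: np.ndarray,
    spec_template: PenaltySpec,
    folds: int = 10,
    seed: int = 0,
    grid: np.ndarray | None = None,
    solver_cfg: solver.SolverConfig | None = None,
) -> CVResult:
    """Stratified k-fold CV accuracy over the lambda grid.

    Per fold the standardizer is refit on the training rows, the solver is
    warm-started along the descending grid, and held-out accuracy is
    sign(Xw) agreement.  Deterministic given the seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present in y")
    grid = lambda_grid() if grid is None else np.asarray(grid, dtype=float)
    solver_cfg = solver_cfg or solver.SolverConfig()
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    acc = np.zeros((len(grid), folds))
    for f, (tr, te) in enumerate(skf.split(X, y)):
        std = Standardizer.fit(X[tr])
        Xtr, Xte = std.transform(X[tr]), std.transform(X[te])
        beta = solver.spectral_step(Xtr)
        ws = _path_fit(Xtr, y[tr], spec_template, grid, solver_cfg, beta)
        for i, w in enumerate(ws):
            w_eff = effective_weights(w, replace(spec_template, lam=float(grid[i])))
            pred = np.where(Xte @ w_eff >= 0, 1, -1)
            acc[i, f] = np.mean(pred == y[te])
    mean = acc.mean(axis=1)
    best = mean.max()
    chosen = float(grid[np.flatnonzero(mean >= best - 1e-12)].max())
    return CVResult(grid=grid, fold_accuracies=acc, mean_accuracy=mean,
                    chosen_lam=chosen)


def fit_model(
    X: np.ndarray,
    y: np.ndarray,
    spec: PenaltySpec,
    solver_cfg: solver.SolverConfig | None = None,
) -> DecodingModel:
    """Standardize, solve the penalized model, record the support."""
    X = np.asarray(X, dtype=float)
    std = Standardizer.fit(X)
    st = solver.fit(std.transform(X), np.asarray(y, dtype=float), spec,
                    cfg=solver_cfg or solver.SolverConfig())
    w = effective_weights(st.w, spec)
    return DecodingModel(
        standardizer=std,
        spec=spec,
        w=w,
        selected=np.flatnonzero(w),
    )


def predict(model: DecodingModel, X_new: np.ndarray) -> np.ndarray:
    """Labels sign(X_std w) in {-1, +1}; sign(0) -> +1."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.shape[1] != model.w.size:
        raise ValueError(
            f"feature count mismatch: model has {model.w.size}, "
            f"input has {X_new.shape[1]}"
        )
    score = model.standardizer.transform(X_new) @ model.w
    return np.where(score >= 0, 1, -1)


def decode(
    fm_train: FeatureMatrix,
    fm_test: FeatureMatrix,
    cfg: DecodingConfig,
) -> tuple[float, DecodingModel, CVResult | None]:
    """CV-select lambda (unless fixed), fit, and score test accuracy."""
    p = fm_train.X.shape[1]
    cv = None
    if cfg.lam is None:
        template = make_spec(cfg, p, lam=1.0)
        cv = select_lambda(
            fm_train.X, fm_train.y, template,
            folds=cfg.folds, seed=cfg.seed, grid=cfg.grid,
            solver_cfg=cfg.solver_cfg,
        )
        lam = cv.chosen_lam
    else:
        lam = cfg.lam
    model = fit_model(fm_train.X, fm_train.y, make_spec(cfg, p, lam),
                      cfg.solver_cfg)
    model.meta = fm_train.meta
    acc = float(np.mean(predict(model, fm_test.X) == fm_test.y))
    return acc, model, cv


def evaluate_subject_dependent(
    subjects: dict[str, tuple[EEGTrialSet, EEGTrialSet]],
    cfg: DecodingConfig,
) -> pd.DataFrame:
    """Per-subject decoding with one model per subject.

    ``subjects`` maps subject id -> (train trials, test trials).  Returns a
    table of per-subject test accuracies plus mean/SD rows.
    """
    rows = []
    for name, split in subjects.items():
        if not (isinstance(split, tuple) and len(split) == 2):
            raise ValueError(f"subject {name!r}: expected a (train, test) split")
        train, test = split
        fm_tr, fm_te, csp = build_features(train, test, cfg.extraction)
        acc, model, cv = decode(fm_tr, fm_te, cfg)
        rows.append({
            "subject": name,
            "accuracy": acc,
            "lam": model.spec.lam,
            "n_selected": model.selected.size,
        })
    df = pd.DataFrame(rows)
    summary = pd.DataFrame([
        {"subject": "mean", "accuracy": df["accuracy"].mean(),
         "lam": np.nan, "n_selected": df["n_selected"].mean()},
        {"subject": "sd", "accuracy": df["accuracy"].std(ddof=1) if len(df) > 1 else 0.0,
         "lam": np.nan, "n_selected": df["n_selected"].std(ddof=1) if len(df) > 1 else 0.0},
    ])
    return pd.concat([df, summary], ignore_index=True)


def evaluate_subject_independent(
    subjects: dict[str, tuple[EEGTrialSet, EEGTrialSet]],
    target: str,
    cfg: DecodingConfig,
) -> float:
    """Leave-one-subject-out decoding accuracy for the target subject.

    All non-target subjects' train+test trials form the training pool; the
    target's test trials are scored.
    """
    if len(subjects) < 2:
        raise ValueError("subject-independent decoding needs >= 2 subjects")
    if target not in subjects:
        raise ValueError(f"unknown target subject {target!r}")
    pool_data, pool_labels = [], []
    fs = None
    for name, (train, test) in subjects.items():
        if name == target:
            continue
        for ts in (train, test):
            pool_data.append(ts.data)
            pool_labels.append(ts.labels)
            fs = ts.fs
    pool = EEGTrialSet(
        data=np.concatenate(pool_data),
        fs=fs,
        labels=np.concatenate(pool_labels),
    )
    target_test = subjects[target][1]
    fm_tr, fm_te, _ = build_features(pool, target_test, cfg.extraction)
    acc, _, _ = decode(fm_tr, fm_te, cfg)
    return acc
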