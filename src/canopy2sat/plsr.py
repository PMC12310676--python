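"""Partial least squares regression by NIPALS, written from scratch.

The implementation is the classical single-response NIPALS: X is autoscaled
(centered, unit sd) and y centered; each component extracts a weight vector
w ∝ Xᵀy, scores t = Xw, loadings p = Xᵀt/tᵀt and q = yᵀt/tᵀt, then deflates
X ← X − t pᵀ and y ← y − q t.  Regression coefficients on the original
predictor scale come from B = W (PᵀW)⁻¹ q.  Successive score vectors are
mutually orthogonal, and predicting through the coefficients reproduces the
deflation recursion — both are asserted as model invariants in the tests.

With one response the power iteration converges in a single pass; the
iteration loop and its tolerance are retained defensively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .metrics import r_squared
from .sensors import SimulatedBandTable

NIPALS_TOL = 1e-10
NIPALS_MAX_ITER = 500


@dataclass
class PLSRModel:
    n_components: int
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    weights: np.ndarray      # (p, k) — component weight vectors on scaled X
    x_loadings: np.ndarray   # (p, k)
    y_loadings: np.ndarray   # (k,)
    x_scores: np.ndarray     # (n, k) — training scores, for diagnostics
    coefficients: np.ndarray  # (p,) — on the original predictor scale
    intercept: float
    predictor_names: list[str] = field(default_factory=list)


def fit_plsr(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    predictor_names: Sequence[str] | None = None,
) -> PLSRModel:
    """Fit a NIPALS PLSR model of ``y`` on autoscaled ``X``."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples × predictors)")
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError("y length must match X rows")
    if n < 3:
        raise ValueError("need at least 3 samples")
    if not (1 <= n_components <= p):
        raise ValueError(f"n_components must be in [1, {p}]")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("X and y must be finite")
    names = list(predictor_names) if predictor_names is not None else [
        f"x{j}" for j in range(p)
    ]

    x_mean = X.mean(axis=0)
    x_sd = X.std(axis=0, ddof=1)
    # tolerance absorbs rounding in numerically-constant columns
    zero_var = np.flatnonzero(x_sd <= 1e-12 * (np.abs(X).max(axis=0) + 1.0))
    if zero_var.size:
        raise ValueError(f"zero-variance predictor: {names[zero_var[0]]!r}")
    Xc = (X - x_mean) / x_sd
    y_mean = float(y.mean())
    yc = y - y_mean

    ws, ps, qs, ts = [], [], [], []
    Xd, yd = Xc.copy(), yc.copy()
    for _ in range(n_components):
        w = Xd.T @ yd
        norm = np.linalg.norm(w)
        if norm < NIPALS_TOL:  # y fully deflated; further components carry no signal
            break
        w /= norm
        for _ in range(NIPALS_MAX_ITER):
            t = Xd @ w
            tt = float(t @ t)
            if tt == 0:
                break
            q = float(yd @ t) / tt
            w_new = Xd.T @ (yd * q)
            n_new = np.linalg.norm(w_new)
            if n_new == 0:
                break
            w_new /= n_new
            if np.linalg.norm(w_new - w) < NIPALS_TOL:
                w = w_new
                break
            w = w_new
        t = Xd @ w
        tt = float(t @ t)
        if tt == 0:
            break
        pvec = Xd.T @ t / tt
        q = float(yd @ t) / tt
        ws.append(w)
        ps.append(pvec)
        qs.append(q)
        ts.append(t)
        Xd = Xd - np.outer(t, pvec)
        yd = yd - q * t
    if not ws:
        raise ValueError("no PLS component could be extracted (y uncorrelated with X)")
    W = np.column_stack(ws)
    P = np.column_stack(ps)
    Q = np.asarray(qs)
    T = np.column_stack(ts)
    k_used = W.shape[1]

    # B on the scaled X, then back-transform to original units.
    B_scaled = W @ np.linalg.solve(P.T @ W, Q)
    coefficients = B_scaled / x_sd
    intercept = y_mean - float(x_mean @ coefficients)
    return PLSRModel(
        n_components=k_used,
        x_mean=x_mean,
        x_sd=x_sd,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=Q,
        x_scores=T,
        coefficients=coefficients,
        intercept=intercept,
        predictor_names=names,
    )


def predict_plsr(model: PLSRModel, X: np.ndarray) -> np.ndarray:
    """Predict through the back-transformed coefficients."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.coefficients.size:
        raise ValueError(
            f"predictor count {X.shape[1]} does not match model ({model.coefficients.size})"
        )
    return X @ model.coefficients + model.intercept


@dataclass(frozen=True)
class CombinationReport:
    sensor: str
    stage: str
    band_combination: tuple[str, ...]
    r2_train: float
    n_components: int
    delta_r2: float | None = None  # vs. the base combination, in ablation runs


def evaluate_combination(
    table: SimulatedBandTable,
    bands: Sequence[str],
    y: np.ndarray | None = None,
    n_components: int | None = None,
    r2_mode: str = "std",
) -> CombinationReport:
    """Fit PLSR on the selected bands and report the training-set R².

    ``n_components`` defaults to min(3, number of bands in the combination).
    """
    y = table.nitrogen if y is None else np.asarray(y, dtype=float)
    X = table.select(list(bands))
    k = min(3, len(bands)) if n_components is None else n_components
    model = fit_plsr(X, y, k, predictor_names=list(bands))
    y_hat = predict_plsr(model, X)
    return CombinationReport(
        sensor=table.sensor,
        stage=table.stage,
        band_combination=tuple(bands),
        r2_train=r_squared(y, y_hat, mode=r2_mode),
        n_components=model.n_components,
    )


def ablation_table(
    table: SimulatedBandTable,
    base_bands: Sequence[str],
    removable: Sequence[str],
    y: np.ndarray | None = None,
    n_components: int | None = None,
) -> list[CombinationReport]:
    """Base combination plus one single-band-removal report per removable band.

    Each removal report carries ΔR² = R²(base) − R²(base minus band).
    """
    extra = [b for b in removable if b not in base_bands]
    if extra:
        raise ValueError(f"removable bands not in base combination: {extra}")
    base = evaluate_combination(table, base_bands, y=y, n_components=n_components)
    reports = [base]
    for band in removable:
        rest = [b for b in base_bands if b != band]
        if not rest:
            raise ValueError("cannot remove the only band in the combination")
        rep = evaluate_combination(table, rest, y=y, n_components=n_components)
        reports.append(
            CombinationReport(
                sensor=rep.sensor,
                stage=rep.stage,
                band_combination=rep.band_combination,
                r2_train=rep.r2_train,
                n_components=rep.n_components,
                delta_r2=base.r2_train - rep.r2_train,
            )
        )
    return reports


def combination_reports_frame(reports: Sequence[CombinationReport]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sensor": [r.sensor for r in reports],
            "stage": [r.stage for r in reports],
            "band_combination": [", ".join(r.band_combination) for r in reports],
            "r2": [r.r2_train for r in reports],
            "n_components": [r.n_components for r in reports],
            "delta_r2": [r.delta_r2 for r in reports],
        }
    )
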