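"""Accuracy metrics: coefficient of determination and root-mean-square error.

Two R² conventions are provided.  The default is the standard
1 − Σ(y−ŷ)²/Σ(y−ȳ)².  The alternative (``mode="eq3"``) is the
explained-variance ratio Σ(ŷ−ȳ)²/Σ(y−ȳ)², which equals the default for
least-squares fits with an intercept but can exceed 1 for biased nonlinear
predictors; it is kept selectable because some reporting conventions use it.
Both give 1 for perfect predictions.
"""

from __future__ import annotations

import numpy as np

from .errors import UndefinedCorrelationError


def _check(y: np.ndarray, y_hat: np.ndarray, min_len: int) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.shape != y_hat.shape:
        raise ValueError("y and y_hat must have equal length")
    if y.size < min_len:
        raise ValueError(f"need at least {min_len} observations")
    return y, y_hat


def r_squared(y: np.ndarray, y_hat: np.ndarray, mode: str = "std") -> float:
    """Coefficient of determination of predictions ``y_hat`` for ``y``."""
    y, y_hat = _check(y, y_hat, min_len=2)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise UndefinedCorrelationError("y has zero variance")
    if mode == "std":
        return 1.0 - float(np.sum((y - y_hat) ** 2)) / ss_tot
    if mode == "eq3":
        return float(np.sum((y_hat - y.mean()) ** 2)) / ss_tot
    raise ValueError(f"unknown r_squared mode {mode!r}")


def rmse(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Root-mean-square error √(Σ(y−ŷ)²/n), in the units of y."""
    y, y_hat = _check(y, y_hat, min_len=1)
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))
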