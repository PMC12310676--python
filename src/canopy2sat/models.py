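"""SVM and BPNN nitrogen estimators over all VNIR bands per sensor × stage.

Each 100-sample stage library is split 60/40 into training and validation
sets; predictors are standardized with statistics from the training split
only.  The SVM is epsilon-support-vector regression with a radial-basis
kernel, its penalty C and kernel width chosen by 5-fold cross-validated
grid search on the training set.  The BPNN is a single-hidden-layer
backpropagation network (2·B+1 logistic units for B bands, linear output)
with early stopping on a 20% internal holdout.  The same train/validation
partition is reused for every sensor and model at a given stage, so sensor
comparisons are paired.  Accuracy is reported as R² and RMSE on both splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .errors import AlignmentError
from .metrics import r_squared, rmse
from .sensors import SimulatedBandTable

#: Default SVM grid on standardized predictors.
SVM_C_GRID = (0.1, 1.0, 10.0, 100.0)
SVM_GAMMA_GRID = (0.01, 0.1, 1.0)
SVM_EPSILON = 0.1


@dataclass(frozen=True)
class SplitSpec:
    """A seeded 60/40 random train/validation partition."""

    n_train: int = 60
    n_validation: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_train < 1 or self.n_validation < 1:
            raise ValueError("both split sizes must be at least 1")


@dataclass(frozen=True)
class ModelConfig:
    """Estimator family plus hyperparameters and seed.

    ``model_type`` is ``"SVM"`` or ``"BPNN"``.  Hyperparameters omitted from
    ``hyperparameters`` fall back to the documented defaults.
    """

    model_type: str
    hyperparameters: Mapping = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_type not in ("SVM", "BPNN"):
            raise ValueError(f"unknown model_type {self.model_type!r}")


def split_train_validation(
    n_samples: int, spec: SplitSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform seeded partition of ``range(n_samples)`` into train/validation.

    Disjoint, exhaustive, and identical for identical specs.
    """
    if spec.n_train + spec.n_validation != n_samples:
        raise ValueError(
            f"split sizes {spec.n_train}+{spec.n_validation} != {n_samples} samples"
        )
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 17]))
    perm = rng.permutation(n_samples)
    return np.sort(perm[: spec.n_train]), np.sort(perm[spec.n_train :])


def fit_model(X_train: np.ndarray, y_train: np.ndarray, config: ModelConfig):
    """Fit one estimator; deterministic under ``config.seed``.

    Returns a fitted sklearn pipeline (scaler + regressor) exposing
    ``predict``.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float).ravel()
    if not (np.all(np.isfinite(X_train)) and np.all(np.isfinite(y_train))):
        raise ValueError("X and y must be finite")
    hp = dict(config.hyperparameters)
    seed = int(config.seed) % (2**31)
    if config.model_type == "SVM":
        pipe = Pipeline(
            [
                ("scale", StandardScaler()),
                ("svr", SVR(kernel="rbf", epsilon=hp.get("epsilon", SVM_EPSILON))),
            ]
        )
        grid = {
            "svr__C": list(hp.get("C_grid", SVM_C_GRID)),
            "svr__gamma": list(hp.get("gamma_grid", SVM_GAMMA_GRID)),
        }
        search = GridSearchCV(
            pipe,
            grid,
            cv=KFold(n_splits=5, shuffle=True, random_state=seed),
            scoring="neg_mean_squared_error",
            n_jobs=None,
        )
        search.fit(X_train, y_train)
        return search.best_estimator_
    # BPNN: single hidden layer of 2·B+1 units (classical heuristic).
    hidden = int(hp.get("hidden_size", 2 * X_train.shape[1] + 1))
    pipe = Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "mlp",
                MLPRegressor(
                    hidden_layer_sizes=(hidden,),
                    activation="logistic",
                    solver="adam",
                    learning_rate_init=float(hp.get("learning_rate", 0.01)),
                    max_iter=int(hp.get("max_epochs", 2000)),
                    early_stopping=True,
                    validation_fraction=0.2,
                    n_iter_no_change=int(hp.get("patience", 50)),
                    random_state=seed,
                ),
            ),
        ]
    )
    pipe.fit(X_train, y_train)
    return pipe


@dataclass
class EvaluationReport:
    """R²/RMSE per (sensor, model, stage, split) plus prediction scatter data."""

    table: pd.DataFrame
    predictions: dict = field(default_factory=dict)

    def row(self, sensor: str, model: str, stage: str, split: str) -> pd.Series:
        t = self.table
        mask = (
            (t["sensor"] == sensor)
            & (t["model"] == model)
            & (t["stage"] == stage)
            & (t["split"] == split)
        )
        return t[mask].iloc[0]


def evaluate_all(
    tables: Mapping[str, Mapping[str, SimulatedBandTable]],
    spec: SplitSpec,
    model_types: Sequence[str] = ("SVM", "BPNN"),
    r2_mode: str = "std",
) -> EvaluationReport:
    """Train and evaluate every sensor × model × stage combination.

    ``tables`` maps sensor name → stage name → band table; all sensor tables
    at a stage must share sample ids (they derive from one library), and one
    split per stage is reused across sensors and models so comparisons are
    paired.  Returns the full (sensors × models × stages × 2 splits) report.
    """
    sensors = list(tables)
    if not sensors:
        raise ValueError("no sensor tables given")
    stage_names = list(tables[sensors[0]])
    rows = []
    predictions: dict = {}
    for s_idx, stage in enumerate(stage_names):
        ref_ids = tables[sensors[0]][stage].sample_ids
        for sensor in sensors:
            if stage not in tables[sensor]:
                raise AlignmentError(f"sensor {sensor!r} missing stage {stage!r}")
            if tables[sensor][stage].sample_ids != ref_ids:
                raise AlignmentError(
                    f"sample ids differ between sensors at stage {stage!r}"
                )
        stage_spec = SplitSpec(
            n_train=spec.n_train,
            n_validation=spec.n_validation,
            seed=int(
                np.random.SeedSequence([int(spec.seed), 23, s_idx]).generate_state(1)[0]
                % (2**31)
            ),
        )
        train_idx, val_idx = split_train_validation(len(ref_ids), stage_spec)
        for sensor in sensors:
            table = tables[sensor][stage]
            X, y = table.values, table.nitrogen
            for model_type in model_types:
                model_seed = int(
                    np.random.SeedSequence(
                        [int(spec.seed), 29, s_idx, sensors.index(sensor),
                         list(model_types).index(model_type)]
                    ).generate_state(1)[0]
                    % (2**31)
                )
                est = fit_model(
                    X[train_idx], y[train_idx], ModelConfig(model_type, seed=model_seed)
                )
                for split_name, idx in (("training", train_idx), ("validation", val_idx)):
                    y_hat = est.predict(X[idx])
                    rows.append(
                        {
                            "sensor": sensor,
                            "model": model_type,
                            "stage": stage,
                            "split": split_name,
                            "r2": r_squared(y[idx], y_hat, mode=r2_mode),
                            "rmse": rmse(y[idx], y_hat),
                        }
                    )
                    predictions[(sensor, model_type, stage, split_name)] = (
                        y[idx].copy(),
                        np.asarray(y_hat, dtype=float),
                    )
    return EvaluationReport(table=pd.DataFrame(rows), predictions=predictions)
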