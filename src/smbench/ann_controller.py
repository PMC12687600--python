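"""ANN effort regressors and velocity-controller wrapping.

A controller maps a frame of WFL features (14, 10 or 8 channels) through a
single-hidden-layer neural network (hidden width = input width, tanh
hidden units, linear outputs) to a 4-element effort estimate, which a
per-DOF deadzone threshold and velocity gain turn into joint-angle
velocities for the virtual hand, updated every 50 ms.

Training minimizes MSE on the training split with early stopping on the
validation split (patience on the epochs without improvement); test-split
R^2 per DOF is reported as the offline accuracy metric.  Inputs are
z-scored with training-split statistics before the network.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPRegressor

from .emg_features import TrainingSet

__all__ = [
    "AnnModel",
    "ControllerSpec",
    "train_ann",
    "predict_effort",
    "predict_velocity",
    "integrate_hand",
    "save_model",
    "load_model",
]

DT = 0.05  # controller update interval, s (20 Hz)


@dataclass
class AnnModel:
    """Trained single-hidden-layer regressor with its input scaler."""

    n_inputs: int
    W_hidden: np.ndarray   # n_inputs x n_hidden
    b_hidden: np.ndarray
    W_out: np.ndarray      # n_hidden x 4
    b_out: np.ndarray
    x_mean: np.ndarray
    x_std: np.ndarray
    seed: int = 0
    n_epochs: int = 0
    patience: int = 10
    test_r2: np.ndarray | None = None  # per-DOF R^2 on the test split

    def __post_init__(self):
        if self.W_hidden.shape != (self.n_inputs, self.n_inputs):
            raise ValueError(
                "hidden layer must have the same width as the input layer"
            )
        if self.W_out.shape != (self.n_inputs, 4):
            raise ValueError("output layer must map hidden units to 4 DOFs")

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Effort estimates for one frame (1-D) or a batch (2-D)."""
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        X = np.atleast_2d(X)
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite input frame")
        Z = (X - self.x_mean) / self.x_std
        H = np.tanh(Z @ self.W_hidden + self.b_hidden)
        out = H @ self.W_out + self.b_out
        return out[0] if single else out


def _r2_per_dof(y_true: np.ndarray, y_pred: np.ndarray) -> np.ndarray:
    """Coefficient of determination per output column; NaN when the
    column is constant (R^2 undefined), with a warning."""
    ss_res = ((y_true - y_pred) ** 2).sum(axis=0)
    ss_tot = ((y_true - y_true.mean(axis=0)) ** 2).sum(axis=0)
    out = np.full(y_true.shape[1], np.nan)
    ok = ss_tot > 0
    out[ok] = 1.0 - ss_res[ok] / ss_tot[ok]
    if not ok.all():
        warnings.warn(
            "constant target column(s): R^2 undefined, reported as NaN",
            RuntimeWarning,
            stacklevel=3,
        )
    return out


def train_ann(
    ts: TrainingSet,
    seed: int = 0,
    *,
    max_epochs: int = 200,
    patience: int = 10,
    learning_rate: float = 1e-3,
) -> AnnModel:
    """Fit the effort regressor with validation-split early stopping.

    One epoch is a full Adam pass over the training split; training stops
    when the validation MSE has not improved for ``patience`` epochs (the
    best-validation weights are kept) or at ``max_epochs``.  Deterministic
    given ``seed``.
    """
    X_tr, Y_tr = ts.subset("train")
    X_val, Y_val = ts.subset("val")
    X_te, Y_te = ts.subset("test")
    if X_tr.size == 0:
        raise ValueError("empty training split")
    if not (np.all(np.isfinite(ts.X)) and np.all(np.isfinite(ts.Y))):
        raise ValueError("training set contains non-finite values")
    n_inputs = X_tr.shape[1]

    x_mean = X_tr.mean(axis=0)
    x_std = X_tr.std(axis=0)
    x_std = np.where(x_std > 0, x_std, 1.0)
    Z_tr = (X_tr - x_mean) / x_std
    Z_val = (X_val - x_mean) / x_std

    net = MLPRegressor(
        hidden_layer_sizes=(n_inputs,),
        activation="tanh",
        solver="adam",
        learning_rate_init=learning_rate,
        random_state=seed,
        max_iter=1,
        warm_start=False,
    )
    best = None
    best_val = np.inf
    best_epoch = 0
    epochs_run = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for epoch in range(1, max_epochs + 1):
            net.partial_fit(Z_tr, Y_tr)
            epochs_run = epoch
            if X_val.size:
                val_mse = float(np.mean((net.predict(Z_val) - Y_val) ** 2))
            else:
                val_mse = float(np.mean((net.predict(Z_tr) - Y_tr) ** 2))
            if val_mse < best_val - 1e-12:
                best_val = val_mse
                best_epoch = epoch
                best = (
                    [w.copy() for w in net.coefs_],
                    [b.copy() for b in net.intercepts_],
                )
            elif epoch - best_epoch >= patience:
                break
    coefs, intercepts = best
    model = AnnModel(
        n_inputs=n_inputs,
        W_hidden=coefs[0],
        b_hidden=intercepts[0],
        W_out=coefs[1],
        b_out=intercepts[1],
        x_mean=x_mean,
        x_std=x_std,
        seed=seed,
        n_epochs=epochs_run,
        patience=patience,
    )
    if X_te.size:
        model.test_r2 = _r2_per_dof(Y_te, model.predict(X_te))
    return model


@dataclass
class ControllerSpec:
    """A trained model plus the gains/thresholds that make it a controller."""

    channel_ids: tuple[int, ...]
    model: AnnModel
    gains: np.ndarray = field(default_factory=lambda: np.ones(4))
    thresholds: np.ndarray = field(default_factory=lambda: np.full(4, 0.1))
    dt: float = DT

    def __post_init__(self):
        self.channel_ids = tuple(self.channel_ids)
        self.gains = np.asarray(self.gains, dtype=float)
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if np.any(self.gains <= 0):
            raise ValueError("velocity gains must be positive")
        if np.any(self.thresholds < 0) or np.any(self.thresholds >= 1):
            raise ValueError("deadzone thresholds must lie in [0, 1)")


def predict_effort(spec: ControllerSpec, wfl_frame: np.ndarray) -> np.ndarray:
    """Raw 4-DOF effort estimate for one WFL frame."""
    return np.asarray(spec.model.predict(np.atleast_2d(wfl_frame)))[0]


def predict_velocity(spec: ControllerSpec, wfl_frame: np.ndarray) -> np.ndarray:
    """Joint-angle velocity command: deadzoned, gain-scaled effort."""
    raw = predict_effort(spec, wfl_frame)
    vel = np.where(np.abs(raw) < spec.thresholds, 0.0, spec.gains * raw)
    if not np.all(np.isfinite(vel)):
        raise FloatingPointError("non-finite velocity command")
    return vel


def integrate_hand(
    state: np.ndarray, velocity: np.ndarray, dt: float = DT
) -> np.ndarray:
    """Advance the 4 normalized joint angles one step, clamped to [-1, 1]."""
    return np.clip(np.asarray(state, dtype=float) + np.asarray(velocity) * dt, -1.0, 1.0)


# -- model serialization (JSON keeps it portable and text-only) -------------

def save_model(model: AnnModel, path: str | Path) -> None:
    payload = {
        "n_inputs": model.n_inputs,
        "W_hidden": model.W_hidden.tolist(),
        "b_hidden": model.b_hidden.tolist(),
        "W_out": model.W_out.tolist(),
        "b_out": model.b_out.tolist(),
        "x_mean": model.x_mean.tolist(),
        "x_std": model.x_std.tolist(),
        "seed": model.seed,
        "n_epochs": model.n_epochs,
        "patience": model.patience,
        "test_r2": None if model.test_r2 is None else np.asarray(model.test_r2).tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> AnnModel:
    payload = json.loads(Path(path).read_text())
    test_r2 = payload.pop("test_r2")
    model = AnnModel(
        **{
            k: (np.array(v) if isinstance(v, list) else v)
            for k, v in payload.items()
        }
    )
    model.test_r2 = None if test_r2 is None else np.array(test_r2)
    return model
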