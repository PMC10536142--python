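"""Single-hidden-layer autoencoder for 90-dimensional action windows.

Architecture: 90 -> hidden (tanh) -> code (linear) on the encoder side and
a mirror-symmetric decoder code -> hidden (tanh) -> 90 (linear) with untied
weights.  Trained to reconstruct its input with mean-squared error under
Adam; the encoder output is the low-dimensional feature handed to the
pairwise-SVM ensemble.  Implemented directly in numpy so the trained model
serializes to plain JSON and the forward pass can be re-implemented on a
microcontroller from the file alone.  All randomness (train/validation
split, weight init, batch order) derives from one integer seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .errors import InputError
from .signals import FEATURE_DIM

_ADAM_B1, _ADAM_B2, _ADAM_EPS = 0.9, 0.999, 1e-8


@dataclass
class AEConfig:
    input_dim: int = FEATURE_DIM
    hidden_dim: int = 40
    code_dim: int = 10
    epochs: int = 500
    batch_size: int = 200
    learning_rate: float = 1e-3
    val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.input_dim, self.hidden_dim, self.code_dim) < 1:
            raise InputError("layer dimensions must be positive")
        if not 0.0 < self.val_fraction < 1.0:
            raise InputError("val_fraction must lie in (0, 1)")
        if self.code_dim >= self.hidden_dim:
            warnings.warn(
                "code_dim >= hidden_dim: the bottleneck is wider than the hidden layer, "
                "which tends to train poorly",
                stacklevel=2,
            )


class AutoencoderModel:
    """Trained (or freshly initialized) autoencoder with its loss history."""

    _LAYERS = ("W1", "b1", "W2", "b2", "W3", "b3", "W4", "b4")

    def __init__(self, config: AEConfig, params: dict[str, np.ndarray], history: dict[str, list]):
        self.config = config
        self.params = params
        self.history = history  # keys: epoch, train_mse, val_mse

    # -- forward passes ----------------------------------------------------
    def _prep(self, x, dim: int) -> tuple[np.ndarray, bool]:
        arr = np.asarray(x, dtype=float)
        single = arr.ndim == 1
        arr = np.atleast_2d(arr)
        if arr.shape[1] != dim:
            raise InputError(f"expected vectors of length {dim}, got {arr.shape[1]}")
        if not np.all(np.isfinite(arr)):
            raise InputError("input contains non-finite values")
        return arr, single

    def encode(self, x) -> np.ndarray:
        X, single = self._prep(x, self.config.input_dim)
        p = self.params
        code = np.tanh(X @ p["W1"] + p["b1"]) @ p["W2"] + p["b2"]
        return code[0] if single else code

    def decode(self, code) -> np.ndarray:
        C, single = self._prep(code, self.config.code_dim)
        p = self.params
        out = np.tanh(C @ p["W3"] + p["b3"]) @ p["W4"] + p["b4"]
        return out[0] if single else out

    def reconstruct(self, x) -> np.ndarray:
        return self.decode(self.encode(x))

    # -- persistence -------------------------------------------------------
    def history_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.history)

    def to_dict(self) -> dict:
        return {
            "config": asdict(self.config),
            "params": {k: v.tolist() for k, v in self.params.items()},
            "history": self.history,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AutoencoderModel":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cfg = AEConfig(**d["config"])
        params = {k: np.asarray(v, dtype=float) for k, v in d["params"].items()}
        return cls(cfg, params, d["history"])

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "AutoencoderModel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def _init_params(cfg: AEConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Symmetric uniform fan-in init: U(-1/sqrt(fan_in), 1/sqrt(fan_in))."""
    dims = [
        (cfg.input_dim, cfg.hidden_dim),
        (cfg.hidden_dim, cfg.code_dim),
        (cfg.code_dim, cfg.hidden_dim),
        (cfg.hidden_dim, cfg.input_dim),
    ]
    params: dict[str, np.ndarray] = {}
    for idx, (fan_in, fan_out) in enumerate(dims, start=1):
        lim = 1.0 / np.sqrt(fan_in)
        params[f"W{idx}"] = rng.uniform(-lim, lim, size=(fan_in, fan_out))
        params[f"b{idx}"] = np.zeros(fan_out)
    return params


def _forward_mse(p: dict, X: np.ndarray) -> float:
    h1 = np.tanh(X @ p["W1"] + p["b1"])
    code = h1 @ p["W2"] + p["b2"]
    h3 = np.tanh(code @ p["W3"] + p["b3"])
    out = h3 @ p["W4"] + p["b4"]
    d = out - X
    return float(np.mean(d * d))


def train_autoencoder(data: np.ndarray, cfg: AEConfig | None = None) -> AutoencoderModel:
    """Train an autoencoder to reconstruct the rows of ``data`` (n, 90).

    The rows are split into train/validation at ``1 - val_fraction`` :
    ``val_fraction`` (default 8:2) after a seeded shuffle; minibatches of
    ``batch_size`` (one full batch when the training set is smaller) are
    re-shuffled every epoch.  Per-epoch train and validation MSE are
    recorded in the returned model's history.
    """
    cfg = cfg or AEConfig()
    X = np.asarray(data, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise InputError("training data must be a 2-D array with at least 2 rows")
    if X.shape[1] != cfg.input_dim:
        raise InputError(f"training vectors must have length {cfg.input_dim}")
    if not np.all(np.isfinite(X)):
        raise InputError("training data contains non-finite values")

    rng = np.random.default_rng(cfg.seed)
    n = X.shape[0]
    perm = rng.permutation(n)
    n_val = min(max(1, int(round(cfg.val_fraction * n))), n - 1)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    X_train, X_val = X[train_idx], X[val_idx]

    params = _init_params(cfg, rng)
    m = {k: np.zeros_like(v) for k, v in params.items()}
    v = {k: np.zeros_like(p) for k, p in params.items()}
    t = 0
    batch = min(cfg.batch_size, X_train.shape[0])
    history: dict[str, list] = {"epoch": [], "train_mse": [], "val_mse": []}

    for epoch in range(cfg.epochs):
        order = rng.permutation(X_train.shape[0])
        for start in range(0, X_train.shape[0], batch):
            xb = X_train[order[start:start + batch]]
            grads = _backward(params, xb)
            t += 1
            for k in params:
                m[k] = _ADAM_B1 * m[k] + (1 - _ADAM_B1) * grads[k]
                v[k] = _ADAM_B2 * v[k] + (1 - _ADAM_B2) * grads[k] ** 2
                mhat = m[k] / (1 - _ADAM_B1 ** t)
                vhat = v[k] / (1 - _ADAM_B2 ** t)
                params[k] -= cfg.learning_rate * mhat / (np.sqrt(vhat) + _ADAM_EPS)
        history["epoch"].append(epoch + 1)
        history["train_mse"].append(_forward_mse(params, X_train))
        history["val_mse"].append(_forward_mse(params, X_val))

    return AutoencoderModel(cfg, params, history)


def _backward(p: dict, X: np.ndarray) -> dict[str, np.ndarray]:
    """Gradients of the mean-squared reconstruction error for one batch."""
    B = X.shape[0]
    z1 = X @ p["W1"] + p["b1"]
    h1 = np.tanh(z1)
    code = h1 @ p["W2"] + p["b2"]
    z3 = code @ p["W3"] + p["b3"]
    h3 = np.tanh(z3)
    out = h3 @ p["W4"] + p["b4"]

    d_out = 2.0 * (out - X) / (B * X.shape[1])
    gW4 = h3.T @ d_out
    gb4 = d_out.sum(axis=0)
    d_h3 = d_out @ p["W4"].T
    d_z3 = d_h3 * (1 - h3 ** 2)
    gW3 = code.T @ d_z3
    gb3 = d_z3.sum(axis=0)
    d_code = d_z3 @ p["W3"].T
    gW2 = h1.T @ d_code
    gb2 = d_code.sum(axis=0)
    d_h1 = d_code @ p["W2"].T
    d_z1 = d_h1 * (1 - h1 ** 2)
    gW1 = X.T @ d_z1
    gb1 = d_z1.sum(axis=0)
    return {"W1": gW1, "b1": gb1, "W2": gW2, "b2": gb2, "W3": gW3, "b3": gb3, "W4": gW4, "b4": gb4}


def initialize_model(cfg: AEConfig | None = None) -> AutoencoderModel:
    """Seeded untrained model (useful for forward-pass contracts and baselines)."""
    cfg = cfg or AEConfig()
    rng = np.random.default_rng(cfg.seed)
    return AutoencoderModel(cfg, _init_params(cfg, rng), {"epoch": [], "train_mse": [], "val_mse": []})
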