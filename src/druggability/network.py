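"""The druggability neural head: a small fully-specified feed-forward net.

Architecture (input dimension k = number of selected features):

    dense(128) -> BN -> ReLU -> dropout(0.5)
    dense(64)  -> BN -> ReLU -> dropout(0.5)
    dense(32)  -> BN -> ReLU
    dense(1)   -> sigmoid

trained with the Adam optimizer on binary cross-entropy plus an L2 weight
penalty (coefficient 0.01 on all dense weights), batch size 32, a learning
rate starting at 2e-4 and halving every 5 epochs down to a floor of
2.5e-5, and early stopping (patience 5) on the loss of a seeded stratified
10% validation split of the training data, restoring the best weights.

Implemented directly on numpy: forward/backward passes for dense layers,
batch normalization (batch statistics in training, running statistics at
inference) and inverted dropout are written out explicitly, so training is
fully deterministic given the seed.  The sigmoid output is a druggability
score in [0, 1]; scores >= 0.5 call the positive class.
"""

from __future__ import annotations

import copy
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9


@dataclass
class DNNConfig:
    """Hyperparameters of the neural head (defaults are the method's)."""

    hidden_units: tuple[int, ...] = (128, 64, 32)
    dropout_rate: float = 0.5
    l2_penalty: float = 0.01
    lr_initial: float = 2e-4
    lr_halving_every: int = 5
    lr_floor: float = 2.5e-5
    batch_size: int = 32
    early_stop_patience: int = 5
    max_epochs: int = 100
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")
        for name in ("lr_initial", "lr_floor", "batch_size", "max_epochs", "lr_halving_every"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        self.hidden_units = tuple(int(u) for u in self.hidden_units)


def lr_schedule(epoch: int, config: DNNConfig) -> float:
    """lr = max(lr_floor, lr_initial / 2 ** floor(epoch / halving_every))."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return max(config.lr_floor, config.lr_initial / 2 ** (epoch // config.lr_halving_every))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def expected_n_parameters(k: int, hidden_units: tuple[int, ...] = (128, 64, 32)) -> int:
    """Closed-form trainable parameter count of the head."""
    dims = [k, *hidden_units]
    total = 0
    for fan_in, fan_out in zip(dims[:-1], dims[1:]):
        total += fan_in * fan_out + fan_out  # dense
        total += 2 * fan_out  # BN gamma + beta
    total += hidden_units[-1] * 1 + 1  # output dense
    return total


class DruggabilityNet(BaseEstimator, ClassifierMixin):
    """sklearn-style binary classifier around the numpy neural head."""

    def __init__(
        self,
        hidden_units: tuple[int, ...] = (128, 64, 32),
        dropout_rate: float = 0.5,
        l2_penalty: float = 0.01,
        lr_initial: float = 2e-4,
        lr_halving_every: int = 5,
        lr_floor: float = 2.5e-5,
        batch_size: int = 32,
        early_stop_patience: int = 5,
        max_epochs: int = 100,
        val_fraction: float = 0.1,
        random_state: int = 0,
    ) -> None:
        self.hidden_units = hidden_units
        self.dropout_rate = dropout_rate
        self.l2_penalty = l2_penalty
        self.lr_initial = lr_initial
        self.lr_halving_every = lr_halving_every
        self.lr_floor = lr_floor
        self.batch_size = batch_size
        self.early_stop_patience = early_stop_patience
        self.max_epochs = max_epochs
        self.val_fraction = val_fraction
        self.random_state = random_state

    # -- configuration plumbing -------------------------------------------

    @classmethod
    def from_config(cls, config: DNNConfig) -> "DruggabilityNet":
        return cls(
            hidden_units=config.hidden_units,
            dropout_rate=config.dropout_rate,
            l2_penalty=config.l2_penalty,
            lr_initial=config.lr_initial,
            lr_halving_every=config.lr_halving_every,
            lr_floor=config.lr_floor,
            batch_size=config.batch_size,
            early_stop_patience=config.early_stop_patience,
            max_epochs=config.max_epochs,
            val_fraction=config.val_fraction,
            random_state=config.seed,
        )

    def _config(self) -> DNNConfig:
        return DNNConfig(
            hidden_units=tuple(self.hidden_units),
            dropout_rate=self.dropout_rate,
            l2_penalty=self.l2_penalty,
            lr_initial=self.lr_initial,
            lr_halving_every=self.lr_halving_every,
            lr_floor=self.lr_floor,
            batch_size=self.batch_size,
            early_stop_patience=self.early_stop_patience,
            max_epochs=self.max_epochs,
            val_fraction=self.val_fraction,
            seed=self.random_state,
        )

    # -- initialization ---------------------------------------------------

    def _init_params(self, k: int, rng: np.random.Generator) -> None:
        hidden = tuple(self.hidden_units)
        dims = [k, *hidden]
        self.params_: dict[str, np.ndarray] = {}
        self.running_: dict[str, np.ndarray] = {}
        for i, (fan_in, fan_out) in enumerate(zip(dims[:-1], dims[1:])):
            # He initialization for ReLU layers
            self.params_[f"W{i}"] = rng.standard_normal((fan_in, fan_out)) * np.sqrt(2.0 / fan_in)
            self.params_[f"b{i}"] = np.zeros(fan_out)
            self.params_[f"g{i}"] = np.ones(fan_out)
            self.params_[f"beta{i}"] = np.zeros(fan_out)
            self.running_[f"mu{i}"] = np.zeros(fan_out)
            self.running_[f"var{i}"] = np.ones(fan_out)
        n_h = len(hidden)
        limit = np.sqrt(6.0 / (hidden[-1] + 1))  # Glorot for the sigmoid output
        self.params_[f"W{n_h}"] = rng.uniform(-limit, limit, size=(hidden[-1], 1))
        self.params_[f"b{n_h}"] = np.zeros(1)

    # -- forward / backward -----------------------------------------------

    def _forward_train(self, X: np.ndarray, rng: np.random.Generator):
        hidden = tuple(self.hidden_units)
        n_h = len(hidden)
        cache = {"h-1": X}
        h = X
        for i in range(n_h):
            z = h @ self.params_[f"W{i}"] + self.params_[f"b{i}"]
            mu = z.mean(axis=0)
            var = z.var(axis=0)
            self.running_[f"mu{i}"] = _BN_MOMENTUM * self.running_[f"mu{i}"] + (1 - _BN_MOMENTUM) * mu
            self.running_[f"var{i}"] = _BN_MOMENTUM * self.running_[f"var{i}"] + (1 - _BN_MOMENTUM) * var
            inv_std = 1.0 / np.sqrt(var + _BN_EPS)
            xhat = (z - mu) * inv_std
            a = self.params_[f"g{i}"] * xhat + self.params_[f"beta{i}"]
            h = np.maximum(a, 0.0)
            cache[f"xhat{i}"], cache[f"inv_std{i}"], cache[f"a{i}"] = xhat, inv_std, a
            if i < n_h - 1 and self.dropout_rate > 0:
                keep = 1.0 - self.dropout_rate
                mask = (rng.random(h.shape) < keep) / keep  # inverted dropout
                h = h * mask
                cache[f"drop{i}"] = mask
            cache[f"h{i}"] = h
        logits = h @ self.params_[f"W{n_h}"] + self.params_[f"b{n_h}"]
        cache["p"] = _sigmoid(logits)
        return cache

    def _backward(self, cache: dict, y: np.ndarray) -> dict[str, np.ndarray]:
        hidden = tuple(self.hidden_units)
        n_h = len(hidden)
        m = y.size
        grads: dict[str, np.ndarray] = {}
        dlogits = (cache["p"] - y.reshape(-1, 1)) / m
        grads[f"W{n_h}"] = cache[f"h{n_h-1}"].T @ dlogits + 2 * self.l2_penalty * self.params_[f"W{n_h}"]
        grads[f"b{n_h}"] = dlogits.sum(axis=0)
        dh = dlogits @ self.params_[f"W{n_h}"].T
        for i in reversed(range(n_h)):
            if i < n_h - 1 and self.dropout_rate > 0:
                dh = dh * cache[f"drop{i}"]
            da = dh * (cache[f"a{i}"] > 0)
            xhat, inv_std = cache[f"xhat{i}"], cache[f"inv_std{i}"]
            grads[f"g{i}"] = (da * xhat).sum(axis=0)
            grads[f"beta{i}"] = da.sum(axis=0)
            dxhat = da * self.params_[f"g{i}"]
            mb = da.shape[0]
            dz = (inv_std / mb) * (
                mb * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0)
            )
            h_prev = cache[f"h{i-1}"]
            grads[f"W{i}"] = h_prev.T @ dz + 2 * self.l2_penalty * self.params_[f"W{i}"]
            grads[f"b{i}"] = dz.sum(axis=0)
            dh = dz @ self.params_[f"W{i}"].T
        return grads

    def _forward_infer(self, X: np.ndarray) -> np.ndarray:
        hidden = tuple(self.hidden_units)
        n_h = len(hidden)
        h = np.asarray(X, dtype=float)
        for i in range(n_h):
            z = h @ self.params_[f"W{i}"] + self.params_[f"b{i}"]
            xhat = (z - self.running_[f"mu{i}"]) / np.sqrt(self.running_[f"var{i}"] + _BN_EPS)
            h = np.maximum(self.params_[f"g{i}"] * xhat + self.params_[f"beta{i}"], 0.0)
        logits = h @ self.params_[f"W{n_h}"] + self.params_[f"b{n_h}"]
        return _sigmoid(logits).ravel()

    @staticmethod
    def _bce(p: np.ndarray, y: np.ndarray) -> float:
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))

    def _penalty(self) -> float:
        return self.l2_penalty * sum(
            float(np.sum(v**2)) for k, v in self.params_.items() if k.startswith("W")
        )

    # -- training ----------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray) -> "DruggabilityNet":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("X must be 2-D with one row per label")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite inputs")
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("both classes must be present to train")
        if not np.all(np.isin(classes, (0.0, 1.0))):
            raise ValueError("labels must be binary 0/1")
        self.classes_ = np.array([0, 1])

        rng = np.random.default_rng(self.random_state)
        self._init_params(X.shape[1], rng)
        self.n_features_in_ = X.shape[1]

        # seeded stratified validation split for early stopping
        use_val = (
            self.val_fraction > 0
            and min(np.sum(y == 0), np.sum(y == 1)) * self.val_fraction >= 1
        )
        if use_val:
            X_tr, X_val, y_tr, y_val = train_test_split(
                X,
                y,
                test_size=self.val_fraction,
                stratify=y,
                random_state=int(self.random_state) % (2**31),
            )
        else:
            X_tr, y_tr, X_val, y_val = X, y, None, None

        adam_m = {k: np.zeros_like(v) for k, v in self.params_.items()}
        adam_v = {k: np.zeros_like(v) for k, v in self.params_.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0

        best_val = np.inf
        best_state = None
        best_epoch = -1
        patience_left = self.early_stop_patience
        self.history_: list[dict] = []
        config = self._config()

        for epoch in range(self.max_epochs):
            lr = lr_schedule(epoch, config)
            order = rng.permutation(X_tr.shape[0])
            batch_losses = []
            for start in range(0, order.size, self.batch_size):
                idx = order[start : start + self.batch_size]
                cache = self._forward_train(X_tr[idx], rng)
                batch_losses.append(self._bce(cache["p"].ravel(), y_tr[idx]) + self._penalty())
                grads = self._backward(cache, y_tr[idx])
                t += 1
                for name, g in grads.items():
                    adam_m[name] = beta1 * adam_m[name] + (1 - beta1) * g
                    adam_v[name] = beta2 * adam_v[name] + (1 - beta2) * g**2
                    m_hat = adam_m[name] / (1 - beta1**t)
                    v_hat = adam_v[name] / (1 - beta2**t)
                    self.params_[name] -= lr * m_hat / (np.sqrt(v_hat) + eps)
            train_loss = float(np.mean(batch_losses))
            if not np.isfinite(train_loss):
                raise FloatingPointError(f"training loss diverged at epoch {epoch}")

            entry = {"epoch": epoch, "lr": lr, "train_loss": train_loss}
            if use_val:
                val_loss = self._bce(self._forward_infer(X_val), y_val)
                entry["val_loss"] = val_loss
                if val_loss < best_val:
                    best_val = val_loss
                    best_epoch = epoch
                    best_state = (
                        copy.deepcopy(self.params_),
                        copy.deepcopy(self.running_),
                    )
                    patience_left = self.early_stop_patience
                else:
                    patience_left -= 1
            self.history_.append(entry)
            if use_val and patience_left <= 0:
                break

        if best_state is not None:
            self.params_, self.running_ = best_state
            self.best_epoch_ = best_epoch
        else:
            self.best_epoch_ = len(self.history_) - 1
        return self

    # -- inference ---------------------------------------------------------

    def _check_fitted_X(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "params_"):
            raise ValueError("model is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[-1]}"
            )
        return X

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        """Druggability scores in [0, 1] (batch-size independent)."""
        return self._forward_infer(self._check_fitted_X(X))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        p = self.predict_scores(X)
        return np.column_stack([1 - p, p])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_scores(X) >= 0.5).astype(int)

    def n_parameters(self) -> int:
        return int(
            sum(v.size for k, v in self.params_.items())
        )

    # -- serialization -----------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Save weights + config; reloading reproduces scores bit-for-bit."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        arrays = {f"param__{k}": v for k, v in self.params_.items()}
        arrays.update({f"running__{k}": v for k, v in self.running_.items()})
        np.savez(path / "weights.npz", **arrays)
        meta = {
            "config": asdict(self._config()),
            "n_features_in": self.n_features_in_,
            "best_epoch": self.best_epoch_,
        }
        (path / "net.json").write_text(json.dumps(meta, indent=2), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "DruggabilityNet":
        path = Path(path)
        meta = json.loads((path / "net.json").read_text(encoding="utf-8"))
        cfg = meta["config"]
        cfg["hidden_units"] = tuple(cfg["hidden_units"])
        net = cls.from_config(DNNConfig(**cfg))
        net.params_, net.running_ = {}, {}
        with np.load(path / "weights.npz") as data:
            for key in data.files:
                kind, name = key.split("__", 1)
                (net.params_ if kind == "param" else net.running_)[name] = data[key]
        net.n_features_in_ = meta["n_features_in"]
        net.best_epoch_ = meta["best_epoch"]
        net.classes_ = np.array([0, 1])
        net.history_ = []
        return net
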