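"""Feed-forward spike/non-spike classifier (35 -> 64 -> 32 -> 1).

A small fully-connected network with ReLU hidden layers, a sigmoid output
read as the spike probability, inverted dropout after the first hidden
layer, and binary cross-entropy

    L = -(1/N) sum_i [ y_i log p_i + (1 - y_i) log(1 - p_i) ]

minimized by Adam (bias-corrected first/second moment estimates).  The
implementation is plain numpy with hand-derived backpropagation, which
keeps the analytic gradients accessible for finite-difference checking
and the whole training run deterministic under a seed.

Features are min-max normalized per feature using *training-split*
statistics only; the normalization parameters travel with the model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from .errors import ClassBalanceError, ConfigError, TrainingDivergenceError

_EPS_P = 1e-12  # probability clipping in the cross-entropy


@dataclass(frozen=True)
class MLPConfig:
    """Architecture and optimizer hyperparameters."""

    input_dim: int = 35
    hidden: tuple[int, ...] = (64, 32)
    dropout_rate: float = 0.5
    dropout_layers: tuple[int, ...] = (0,)  # indices of hidden layers with dropout
    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.dropout_rate < 1):
            raise ConfigError("dropout_rate must lie in [0, 1)")
        if self.epochs < 1:
            raise ConfigError("epochs must be >= 1")
        if self.input_dim < 1 or any(h < 1 for h in self.hidden):
            raise ConfigError("layer sizes must be positive")


@dataclass(frozen=True)
class LabeledDataset:
    """Feature matrix plus binary labels (1 = spike, 0 = false-positive)."""

    features: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        x = np.asarray(self.features, dtype=float)
        y = np.asarray(self.labels).astype(int)
        if x.ndim != 2 or y.ndim != 1 or x.shape[0] != y.shape[0]:
            raise ConfigError("features must be n x d with n matching labels")
        if not np.isin(y, (0, 1)).all():
            raise ConfigError("labels must be binary")
        object.__setattr__(self, "features", x)
        object.__setattr__(self, "labels", y)

    def __len__(self) -> int:
        return len(self.labels)

    def class_counts(self) -> tuple[int, int]:
        return int((self.labels == 0).sum()), int((self.labels == 1).sum())


def undersample_balance(features: np.ndarray, labels: np.ndarray,
                        seed: int = 0) -> LabeledDataset:
    """Randomly subsample the majority class to the minority count.

    In practice the false-positive class vastly outnumbers the spikes, so
    this keeps all spikes and thins the negatives.
    """
    ds = LabeledDataset(features, labels)
    n0, n1 = ds.class_counts()
    if n0 == 0 or n1 == 0:
        raise ClassBalanceError(f"both classes required, got counts ({n0}, {n1})")
    rng = np.random.default_rng(seed)
    minority = 1 if n1 <= n0 else 0
    keep_minor = np.flatnonzero(ds.labels == minority)
    major = np.flatnonzero(ds.labels != minority)
    keep_major = rng.choice(major, size=keep_minor.size, replace=False)
    idx = np.sort(np.concatenate([keep_minor, keep_major]))
    return LabeledDataset(ds.features[idx], ds.labels[idx])


def split_train_test(dataset: LabeledDataset, test_frac: float = 0.2,
                     seed: int = 0) -> tuple[LabeledDataset, LabeledDataset]:
    """Stratified disjoint train/test split (80/20 by default)."""
    n0, n1 = dataset.class_counts()
    if min(n0, n1) < 5:
        raise ClassBalanceError(
            f"need at least 5 samples per class to split, got ({n0}, {n1})"
        )
    xtr, xte, ytr, yte = train_test_split(
        dataset.features, dataset.labels, test_size=test_frac,
        stratify=dataset.labels, random_state=seed % 2**32,
    )
    return LabeledDataset(xtr, ytr), LabeledDataset(xte, yte)


def binary_cross_entropy(p: np.ndarray, y: np.ndarray) -> float:
    """Mean BCE with probability clipping for numerical safety."""
    p = np.clip(p, _EPS_P, 1 - _EPS_P)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


class MLP:
    """The network itself; use :func:`train_mlp` to fit one."""

    def __init__(self, config: MLPConfig):
        self.config = config
        self.feat_min: np.ndarray | None = None
        self.feat_range: np.ndarray | None = None
        rng = np.random.default_rng(config.seed)
        sizes = (config.input_dim, *config.hidden, 1)
        self.weights = [
            rng.standard_normal((sizes[i], sizes[i + 1])) * np.sqrt(2.0 / sizes[i])
            for i in range(len(sizes) - 1)
        ]
        self.biases = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]
        self._adam_m = [np.zeros_like(w) for w in self.weights + self.biases]
        self._adam_v = [np.zeros_like(w) for w in self.weights + self.biases]
        self._adam_t = 0

    # -- normalization -----------------------------------------------------

    def fit_normalization(self, x: np.ndarray) -> None:
        self.feat_min = x.min(axis=0)
        rng_ = np.ptp(x, axis=0)
        self.feat_range = np.where(rng_ > 0, rng_, 1.0)

    def normalize(self, x: np.ndarray) -> np.ndarray:
        if self.feat_min is None:
            return x
        return (x - self.feat_min) / self.feat_range

    # -- forward / backward ------------------------------------------------

    def _forward(self, x: np.ndarray, dropout_rng: np.random.Generator | None):
        """Return (activations per layer, dropout masks).  Dropout is the
        inverted kind: masks scale kept units by 1/(1-rate) at train time so
        inference needs no rescaling."""
        cfg = self.config
        acts = [x]
        masks = [None] * len(cfg.hidden)
        h = x
        for i, (w, b) in enumerate(zip(self.weights[:-1], self.biases[:-1])):
            h = np.maximum(h @ w + b, 0.0)  # ReLU
            if (dropout_rng is not None and cfg.dropout_rate > 0
                    and i in cfg.dropout_layers):
                keep = 1.0 - cfg.dropout_rate
                mask = (dropout_rng.random(h.shape) < keep) / keep
                h = h * mask
                masks[i] = mask
            acts.append(h)
        logits = h @ self.weights[-1] + self.biases[-1]
        p = 1.0 / (1.0 + np.exp(-logits))
        acts.append(p)
        return acts, masks

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Spike probabilities in [0, 1]; dropout disabled."""
        x = np.asarray(x, dtype=float)
        if x.ndim != 2 or x.shape[1] != self.config.input_dim:
            raise ConfigError(
                f"expected n x {self.config.input_dim} features, got {x.shape}"
            )
        acts, _ = self._forward(self.normalize(x), dropout_rng=None)
        return acts[-1][:, 0]

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray,
                       dropout_rng: np.random.Generator | None = None):
        """BCE loss and analytic gradients w.r.t. all weights and biases.

        ``x`` is assumed already normalized.  The BCE+sigmoid gradient at
        the output is (p - y)/N.
        """
        y = np.asarray(y, dtype=float).reshape(-1, 1)
        acts, masks = self._forward(x, dropout_rng)
        p = acts[-1]
        loss = binary_cross_entropy(p[:, 0], y[:, 0])

        n = x.shape[0]
        grads_w = [None] * len(self.weights)
        grads_b = [None] * len(self.biases)
        delta = (np.clip(p, _EPS_P, 1 - _EPS_P) - y) / n
        grads_w[-1] = acts[-2].T @ delta
        grads_b[-1] = delta.sum(axis=0)
        for i in range(len(self.weights) - 2, -1, -1):
            delta = delta @ self.weights[i + 1].T
            if masks[i] is not None:
                delta = delta * masks[i]
            delta = delta * (acts[i + 1] > 0)  # through ReLU (and dropout zeros)
            grads_w[i] = acts[i].T @ delta
            grads_b[i] = delta.sum(axis=0)
        return loss, grads_w, grads_b

    def adam_step(self, grads_w, grads_b) -> None:
        cfg = self.config
        self._adam_t += 1
        t = self._adam_t
        params = self.weights + self.biases
        grads = grads_w + grads_b
        for i, (p, g) in enumerate(zip(params, grads)):
            self._adam_m[i] = cfg.beta1 * self._adam_m[i] + (1 - cfg.beta1) * g
            self._adam_v[i] = cfg.beta2 * self._adam_v[i] + (1 - cfg.beta2) * g**2
            m_hat = self._adam_m[i] / (1 - cfg.beta1**t)
            v_hat = self._adam_v[i] / (1 - cfg.beta2**t)
            p -= cfg.learning_rate * m_hat / (np.sqrt(v_hat) + cfg.eps)

    # -- parameter flattening (for gradient checks and persistence) --------

    def get_params_flat(self) -> np.ndarray:
        return np.concatenate([a.ravel() for a in self.weights + self.biases])

    def set_params_flat(self, flat: np.ndarray) -> None:
        pos = 0
        for arr in self.weights + self.biases:
            arr[...] = flat[pos : pos + arr.size].reshape(arr.shape)
            pos += arr.size

    def save(self, path) -> None:
        """Persist layer shapes, weights and normalization as a portable npz."""
        payload = {f"w{i}": w for i, w in enumerate(self.weights)}
        payload |= {f"b{i}": b for i, b in enumerate(self.biases)}
        payload["hidden"] = np.array(self.config.hidden)
        payload["input_dim"] = np.array(self.config.input_dim)
        if self.feat_min is not None:
            payload["feat_min"] = self.feat_min
            payload["feat_range"] = self.feat_range
        np.savez(path, **payload)

    @classmethod
    def load(cls, path, config: MLPConfig | None = None) -> "MLP":
        data = np.load(path)
        if config is None:
            config = MLPConfig(input_dim=int(data["input_dim"]),
                               hidden=tuple(int(h) for h in data["hidden"]))
        model = cls(config)
        model.weights = [data[f"w{i}"] for i in range(len(model.weights))]
        model.biases = [data[f"b{i}"] for i in range(len(model.biases))]
        if "feat_min" in data:
            model.feat_min = data["feat_min"]
            model.feat_range = data["feat_range"]
        return model


def _fit(model: MLP, x: np.ndarray, y: np.ndarray, config: MLPConfig,
         rng: np.random.Generator,
         val: tuple[np.ndarray, np.ndarray] | None) -> list[dict]:
    """Run the epoch loop on already-normalized data, recording history."""
    history = []
    n = x.shape[0]
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        for i0 in range(0, n, config.batch_size):
            idx = order[i0 : i0 + config.batch_size]
            loss, gw, gb = model.loss_and_grads(x[idx], y[idx], dropout_rng=rng)
            if not np.isfinite(loss):
                raise TrainingDivergenceError(epoch)
            model.adam_step(gw, gb)
        p_tr = model._forward(x, None)[0][-1][:, 0]
        row = {
            "epoch": epoch,
            "train_loss": binary_cross_entropy(p_tr, y),
            "train_acc": float(((p_tr >= 0.5) == (y == 1)).mean()),
        }
        if val is not None:
            p_va = model._forward(val[0], None)[0][-1][:, 0]
            row["val_loss"] = binary_cross_entropy(p_va, val[1])
            row["val_acc"] = float(((p_va >= 0.5) == (val[1] == 1)).mean())
        history.append(row)
    return history


def train_mlp(train: LabeledDataset, config: MLPConfig | None = None,
              cv_folds: int = 5) -> tuple[MLP, pd.DataFrame]:
    """Fit the classifier; returns (model, per-epoch history table).

    With ``cv_folds >= 2`` a stratified cross-validation pass first records
    per-epoch train/validation loss and accuracy (the round-selection
    curves); the returned model is then trained on the full training set
    (history rows tagged fold = "final").  Deterministic under
    ``config.seed``.
    """
    if config is None:
        config = MLPConfig(input_dim=train.features.shape[1])
    if train.features.shape[1] != config.input_dim:
        raise ConfigError(
            f"dataset has {train.features.shape[1]} features, "
            f"config expects {config.input_dim}"
        )
    n0, n1 = train.class_counts()
    if n0 == 0 or n1 == 0:
        raise ClassBalanceError("training set must contain both classes")

    norm = MLP(config)
    norm.fit_normalization(train.features)
    x_all = norm.normalize(train.features)
    y_all = train.labels.astype(float)

    rows = []
    if cv_folds >= 2:
        skf = StratifiedKFold(n_splits=cv_folds, shuffle=True,
                              random_state=config.seed % 2**32)
        for fold, (tr, va) in enumerate(skf.split(x_all, y_all)):
            model = MLP(replace(config, seed=config.seed + fold + 1))
            rng = np.random.default_rng([config.seed, fold + 1])
            hist = _fit(model, x_all[tr], y_all[tr], config, rng,
                        val=(x_all[va], y_all[va]))
            rows.extend({"fold": fold, **row} for row in hist)

    final = MLP(config)
    final.feat_min, final.feat_range = norm.feat_min, norm.feat_range
    rng = np.random.default_rng([config.seed, 0])
    hist = _fit(final, x_all, y_all, config, rng, val=None)
    rows.extend({"fold": "final", **row} for row in hist)
    return final, pd.DataFrame(rows)


def predict(model: MLP, features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(probabilities, hard labels at the 0.5 threshold)."""
    proba = model.predict_proba(features)
    return proba, (proba >= 0.5).astype(int)
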