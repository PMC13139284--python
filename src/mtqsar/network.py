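"""A seeded NumPy feed-forward network with masked-MSE training.

This is the computational core of the multitask models: a shared fully
connected trunk whose final linear layer provides one output head per
task (hard parameter sharing).  The loss is averaged only over observed
cells of the task matrix, so gradients are exactly zero wherever the
observation mask is zero and a single network can train on a sparsely
filled multi-target table.
"""

from __future__ import annotations

import math

import numpy as np

_SELU_ALPHA = 1.6732632423543772
_SELU_LAMBDA = 1.0507009873554805
_SQRT2 = math.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


def _gelu(z):
    from scipy.special import erf
    cdf = 0.5 * (1.0 + erf(z / _SQRT2))
    return z * cdf, cdf + z * np.exp(-0.5 * z * z) * _INV_SQRT_2PI


def _elu(z):
    e = np.exp(np.minimum(z, 0.0))
    return np.where(z > 0, z, e - 1.0), np.where(z > 0, 1.0, e)


def _selu(z):
    e = np.exp(np.minimum(z, 0.0))
    return (
        _SELU_LAMBDA * np.where(z > 0, z, _SELU_ALPHA * (e - 1.0)),
        _SELU_LAMBDA * np.where(z > 0, 1.0, _SELU_ALPHA * e),
    )


def _tanh(z):
    t = np.tanh(z)
    return t, 1.0 - t * t


def _relu(z):
    return np.maximum(z, 0.0), (z > 0).astype(z.dtype)


def _linear(z):
    return z, np.ones_like(z)


ACTIVATIONS = {
    "gelu": _gelu, "elu": _elu, "selu": _selu,
    "tanh": _tanh, "relu": _relu, "linear": _linear,
}


def masked_mse(pred: np.ndarray, values: np.ndarray, mask: np.ndarray) -> float:
    """Mean squared error over observed (mask = 1) cells only."""
    pred = np.asarray(pred, dtype=float)
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask)
    if pred.shape != values.shape or pred.shape != mask.shape:
        raise ValueError(
            f"shape mismatch: pred {pred.shape}, values {values.shape}, "
            f"mask {mask.shape}"
        )
    m = mask.astype(bool)
    n_obs = int(m.sum())
    if n_obs == 0:
        raise ValueError("all cells masked: masked MSE undefined")
    diff = np.where(m, pred - values, 0.0)
    return float((diff * diff).sum() / n_obs)


class _Optimizer:
    """First-order update rules sharing one state container per array."""

    def __init__(self, kind: str, lr: float):
        if kind not in ("adam", "nadam", "sgd", "rmsprop"):
            raise ValueError(f"unknown optimizer: {kind}")
        self.kind = kind
        self.lr = lr
        self.t = 0
        self.state: dict[int, dict] = {}
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            st = self.state.setdefault(
                i, {"m": np.zeros_like(p), "v": np.zeros_like(p)}
            )
            if self.kind == "sgd":
                p -= self.lr * g
                continue
            if self.kind == "rmsprop":
                st["v"] = 0.9 * st["v"] + 0.1 * g * g
                p -= self.lr * g / (np.sqrt(st["v"]) + self.eps)
                continue
            st["m"] = self.beta1 * st["m"] + (1 - self.beta1) * g
            st["v"] = self.beta2 * st["v"] + (1 - self.beta2) * g * g
            m_hat = st["m"] / (1 - self.beta1 ** self.t)
            v_hat = st["v"] / (1 - self.beta2 ** self.t)
            if self.kind == "nadam":
                m_hat = self.beta1 * m_hat + (1 - self.beta1) * g / (
                    1 - self.beta1 ** self.t
                )
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


class FeedForwardNet:
    """Fully connected trunk + linear multi-output head, trained with a
    masked mean-squared-error loss."""

    def __init__(
        self,
        n_in: int,
        hidden: tuple[int, ...],
        n_out: int,
        activation: str = "relu",
        dropout: float = 0.0,
        l1: float = 0.0,
        l2: float = 0.0,
        seed: int = 0,
    ):
        if activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation: {activation}")
        if not 0.0 <= dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        self.activation = activation
        self.dropout = dropout
        self.l1, self.l2 = l1, l2
        rng = np.random.default_rng(seed)
        dims = [n_in, *hidden, n_out]
        self.W = [
            rng.standard_normal((dims[i], dims[i + 1])) * math.sqrt(2.0 / dims[i])
            for i in range(len(dims) - 1)
        ]
        self.b = [np.zeros(dims[i + 1]) for i in range(len(dims) - 1)]

    # -- inference -----------------------------------------------------
    def predict(self, X: np.ndarray) -> np.ndarray:
        act = ACTIVATIONS[self.activation]
        a = np.asarray(X, dtype=float)
        for i in range(len(self.W) - 1):
            a, _ = act(a @ self.W[i] + self.b[i])
        return a @ self.W[-1] + self.b[-1]

    # -- training ------------------------------------------------------
    def _forward_backward(self, X, Y, M, rng):
        """One loss + gradient evaluation on a batch; dropout applied to
        hidden activations when a generator is supplied."""
        act = ACTIVATIONS[self.activation]
        a = np.asarray(X, dtype=float)
        acts, derivs, masks = [a], [], []
        for i in range(len(self.W) - 1):
            h, dh = act(a @ self.W[i] + self.b[i])
            if self.dropout > 0.0 and rng is not None:
                keep = (rng.random(h.shape) >= self.dropout) / (1 - self.dropout)
                h, dh = h * keep, dh * keep
                masks.append(keep)
            a = h
            acts.append(a)
            derivs.append(dh)
        pred = a @ self.W[-1] + self.b[-1]

        m = M.astype(bool)
        n_obs = int(m.sum())
        if n_obs == 0:
            raise ValueError("batch has no observed cells")
        diff = np.where(m, pred - Y, 0.0)
        with np.errstate(over="ignore"):  # divergence is caught as non-finite
            loss = float((diff * diff).sum() / n_obs)

        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        delta = 2.0 * diff / n_obs
        for i in range(len(self.W) - 1, -1, -1):
            gW[i] = acts[i].T @ delta
            gb[i] = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ self.W[i].T) * derivs[i - 1]
        if self.l2 > 0.0:
            loss += self.l2 * sum(float((w * w).sum()) for w in self.W)
            for i, w in enumerate(self.W):
                gW[i] = gW[i] + 2.0 * self.l2 * w
        if self.l1 > 0.0:
            loss += self.l1 * sum(float(np.abs(w).sum()) for w in self.W)
            for i, w in enumerate(self.W):
                gW[i] = gW[i] + self.l1 * np.sign(w)
        return loss, gW, gb

    def fit(
        self,
        X: np.ndarray,
        Y: np.ndarray,
        M: np.ndarray,
        train_idx: np.ndarray,
        val_idx: np.ndarray,
        learning_rate: float = 1e-3,
        batch_size: int = 48,
        optimizer: str = "nadam",
        max_epochs: int = 2000,
        patience: int = 10,
        seed: int = 0,
    ) -> dict:
        """Minibatch training with early stopping on validation masked MSE.

        Returns the training history (per-epoch train/validation loss and
        the epoch at which the best validation loss occurred); the weights
        are restored to that best epoch.  When the validation partition
        holds no observed cells, patience is applied to the training loss.
        """
        rng = np.random.default_rng(seed)
        opt = _Optimizer(optimizer, learning_rate)
        train_idx = np.asarray(train_idx, dtype=int)
        val_idx = np.asarray(val_idx, dtype=int)
        has_val = len(val_idx) > 0 and M[val_idx].sum() > 0
        # only rows with at least one observed cell contribute gradients
        rows = train_idx[M[train_idx].sum(axis=1) > 0]
        if len(rows) == 0:
            raise ValueError("training partition has no observed cells")

        history = {"train_loss": [], "val_loss": [], "best_epoch": 0}
        best = math.inf
        best_W = best_b = None
        wait = 0
        for epoch in range(1, max_epochs + 1):
            order = rng.permutation(rows)
            for start in range(0, len(order), batch_size):
                batch = order[start:start + batch_size]
                if M[batch].sum() == 0:
                    continue
                loss, gW, gb = self._forward_backward(
                    X[batch], Y[batch], M[batch], rng
                )
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch} "
                        f"(learning rate {learning_rate})"
                    )
                opt.step(self.W + self.b, gW + gb)

            train_loss = masked_mse(self.predict(X[rows]), Y[rows], M[rows])
            val_loss = (
                masked_mse(self.predict(X[val_idx]), Y[val_idx], M[val_idx])
                if has_val else train_loss
            )
            history["train_loss"].append(train_loss)
            history["val_loss"].append(val_loss)
            if not (np.isfinite(train_loss) and np.isfinite(val_loss)):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch} "
                    f"(learning rate {learning_rate})"
                )
            if val_loss < best - 1e-12:
                best = val_loss
                best_W = [w.copy() for w in self.W]
                best_b = [b.copy() for b in self.b]
                history["best_epoch"] = epoch
                wait = 0
            else:
                wait += 1
                if wait >= patience:
                    break
        if best_W is not None:
            self.W, self.b = best_W, best_b
        return history
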