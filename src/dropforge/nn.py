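"""Small feed-forward networks for tabular droplet data.

Fully-connected networks with rectified-linear hidden layers, trained
full-batch with the Adam optimizer, inverted dropout and early stopping on
a validation carve-out. Regression heads are linear (MSE loss);
classification heads are sigmoid (binary cross-entropy).

The implementation keeps explicit per-layer weight arrays so that transfer
learning can freeze the first layers of a pre-trained network (their
gradients are masked out) and optionally append fresh layers before the
output head — operations the high-level sklearn estimators do not expose.
Everything is deterministic given the seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLP", "extend_network"]

_EPS = 1e-8


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class MLP:
    """Feed-forward network with ReLU hidden layers.

    Parameters
    ----------
    layer_sizes : sequence of int
        Sizes including input and output, e.g. ``[8, 32, 32, 16, 1]``.
    task : {"regression", "classification"}
        Output head and loss: linear/MSE or sigmoid/BCE.
    seed : int
        Seeds the He-style weight initialization.
    """

    def __init__(self, layer_sizes, task: str = "regression", seed: int = 0):
        if task not in ("regression", "classification"):
            raise ValueError("task must be 'regression' or 'classification'")
        if len(layer_sizes) < 2:
            raise ValueError("need at least input and output sizes")
        self.layer_sizes = list(int(s) for s in layer_sizes)
        self.task = task
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(self.layer_sizes[:-1], self.layer_sizes[1:]):
            scale = np.sqrt(2.0 / fan_in)
            self.weights.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))

    # ------------------------------------------------------------------ #

    @property
    def n_layers(self) -> int:
        """Number of weight layers (hidden layers + output head)."""
        return len(self.weights)

    def get_weights(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [(w.copy(), b.copy()) for w, b in zip(self.weights, self.biases)]

    def set_weights(self, params: list[tuple[np.ndarray, np.ndarray]]) -> None:
        if len(params) != self.n_layers:
            raise ValueError("layer count mismatch")
        self.weights = [w.copy() for w, _ in params]
        self.biases = [b.copy() for _, b in params]

    def _forward(self, x: np.ndarray, dropout: float = 0.0,
                 rng: np.random.Generator | None = None):
        """Forward pass; returns activations per layer (pre-output linear)."""
        acts = [x]
        h = x
        masks = []
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = h @ w + b
            if i < self.n_layers - 1:
                h = _relu(z)
                if dropout > 0.0 and rng is not None:
                    mask = (rng.random(h.shape) >= dropout) / (1.0 - dropout)
                    h = h * mask
                    masks.append(mask)
                else:
                    masks.append(None)
            else:
                h = z
            acts.append(h)
        return acts, masks

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Network output: raw values (regression) or probabilities."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        out = self._forward(x)[0][-1]
        if self.task == "classification":
            out = _sigmoid(out)
        return out

    # ------------------------------------------------------------------ #

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        epochs: int = 2000,
        learning_rate: float = 1e-3,
        dropout: float = 0.0,
        patience: int = 50,
        val_fraction: float = 0.1,
        frozen_layers: int = 0,
        seed: int | None = None,
    ) -> dict:
        """Train with full-batch Adam and early stopping.

        A ``val_fraction`` carve-out of the training data is monitored; when
        the validation loss has not improved for ``patience`` epochs the best
        weights are restored and training stops. With ``frozen_layers`` = k,
        the first k weight layers receive no updates. Returns a history dict.
        """
        if frozen_layers >= self.n_layers:
            raise ValueError(
                f"frozen_layers={frozen_layers} must be < depth {self.n_layers}"
            )
        x = np.atleast_2d(np.asarray(x, dtype=float))
        y = np.asarray(y, dtype=float).reshape(len(x), -1)
        if epochs <= 0:
            return {"train_loss": [], "val_loss": [], "epochs_run": 0}
        rng = np.random.default_rng(self.seed if seed is None else seed)

        n_val = int(round(len(x) * val_fraction)) if len(x) >= 10 else 0
        if n_val > 0:
            perm = rng.permutation(len(x))
            x_val, y_val = x[perm[:n_val]], y[perm[:n_val]]
            x_tr, y_tr = x[perm[n_val:]], y[perm[n_val:]]
        else:
            x_tr, y_tr = x, y
            x_val = y_val = None

        m_w = [np.zeros_like(w) for w in self.weights]
        v_w = [np.zeros_like(w) for w in self.weights]
        m_b = [np.zeros_like(b) for b in self.biases]
        v_b = [np.zeros_like(b) for b in self.biases]
        beta1, beta2 = 0.9, 0.999

        best_val = np.inf
        best_params = None
        stall = 0
        history = {"train_loss": [], "val_loss": []}

        for epoch in range(1, epochs + 1):
            acts, masks = self._forward(x_tr, dropout=dropout, rng=rng)
            out = acts[-1]
            n = len(x_tr)
            if self.task == "classification":
                p = _sigmoid(out)
                grad = (p - y_tr) / n  # d(BCE)/d(logit)
                loss = float(-np.mean(
                    y_tr * np.log(p + _EPS) + (1 - y_tr) * np.log(1 - p + _EPS)))
            else:
                grad = 2.0 * (out - y_tr) / n
                loss = float(np.mean((out - y_tr) ** 2))
            history["train_loss"].append(loss)

            # Backprop through the dense stack.
            grads_w = [None] * self.n_layers
            grads_b = [None] * self.n_layers
            delta = grad
            for i in range(self.n_layers - 1, -1, -1):
                grads_w[i] = acts[i].T @ delta
                grads_b[i] = delta.sum(axis=0)
                if i > 0:
                    delta = delta @ self.weights[i].T
                    if masks[i - 1] is not None:
                        delta = delta * masks[i - 1]
                    delta = delta * (acts[i] > 0)

            corr1 = 1.0 - beta1**epoch
            corr2 = 1.0 - beta2**epoch
            for i in range(frozen_layers, self.n_layers):
                m_w[i] = beta1 * m_w[i] + (1 - beta1) * grads_w[i]
                v_w[i] = beta2 * v_w[i] + (1 - beta2) * grads_w[i] ** 2
                self.weights[i] -= learning_rate * (m_w[i] / corr1) / (
                    np.sqrt(v_w[i] / corr2) + _EPS)
                m_b[i] = beta1 * m_b[i] + (1 - beta1) * grads_b[i]
                v_b[i] = beta2 * v_b[i] + (1 - beta2) * grads_b[i] ** 2
                self.biases[i] -= learning_rate * (m_b[i] / corr1) / (
                    np.sqrt(v_b[i] / corr2) + _EPS)

            if x_val is not None:
                val_out = self._forward(x_val)[0][-1]
                if self.task == "classification":
                    pv = _sigmoid(val_out)
                    val_loss = float(-np.mean(
                        y_val * np.log(pv + _EPS)
                        + (1 - y_val) * np.log(1 - pv + _EPS)))
                else:
                    val_loss = float(np.mean((val_out - y_val) ** 2))
                history["val_loss"].append(val_loss)
                if val_loss < best_val - 1e-12:
                    best_val = val_loss
                    best_params = self.get_weights()
                    stall = 0
                else:
                    stall += 1
                    if stall >= patience:
                        break

        if best_params is not None:
            self.set_weights(best_params)
        history["epochs_run"] = epoch
        return history

    # ------------------------------------------------------------------ #

    def to_dict(self) -> dict:
        return {"layer_sizes": self.layer_sizes, "task": self.task, "seed": self.seed}

    @classmethod
    def from_dict(cls, meta: dict) -> "MLP":
        return cls(meta["layer_sizes"], task=meta["task"], seed=meta["seed"])


def extend_network(net: MLP, extra_hidden: list[int], seed: int = 0) -> MLP:
    """Return a deeper copy of ``net`` with fresh hidden layers before the head.

    All of ``net``'s hidden layers keep their trained weights; the appended
    hidden layers and the new output head are freshly initialized. Used by
    the transfer-learning protocol for strongly shifted fluid properties.
    """
    old_hidden = net.layer_sizes[1:-1]
    new_sizes = [net.layer_sizes[0]] + old_hidden + list(extra_hidden) + [net.layer_sizes[-1]]
    out = MLP(new_sizes, task=net.task, seed=seed)
    for i in range(len(old_hidden)):  # copy trained hidden layers
        out.weights[i] = net.weights[i].copy()
        out.biases[i] = net.biases[i].copy()
    return out
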