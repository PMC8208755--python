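"""A compact feed-forward network engine in numpy.

This implements exactly what the latent-space models need: dense layers,
tanh/relu/sigmoid activations, a linear or softmax (simplex) output head,
Adam, mini-batch training with early stopping, and analytic gradients for
the three composition losses (MSE, crossentropy, Bray–Curtis). Rows are
samples throughout.

Gradient notes
--------------
For a simplex prediction ``y = softmax(z)`` the head backprop is
``dL/dz = y ⊙ (dL/dy − ⟨dL/dy, y⟩)`` row-wise. The Bray–Curtis loss per
sample is ``Σ|y−t| / Σ(y+t)``; with ``S = Σ(y+t)`` and ``D = Σ|y−t|`` its
(sub)gradient is ``sign(y−t)/S − D/S²`` elementwise, which is exact away
from ties and a valid subgradient at them.
"""

from __future__ import annotations

import numpy as np

from .metrics import CROSSENTROPY_EPS

_ACT = {
    "tanh": (np.tanh, lambda a: 1.0 - a ** 2),
    "relu": (lambda x: np.maximum(x, 0.0), lambda a: (a > 0).astype(float)),
    "sigmoid": (lambda x: 1.0 / (1.0 + np.exp(-x)), lambda a: a * (1.0 - a)),
    "identity": (lambda x: x, lambda a: np.ones_like(a)),
}


class Dense:
    """Fully-connected layer with an elementwise activation or softmax head."""

    def __init__(self, n_in: int, n_out: int, activation: str, rng: np.random.Generator):
        if activation not in _ACT and activation != "softmax":
            raise ValueError(f"unknown activation {activation!r}")
        # Glorot-uniform init keeps tanh/sigmoid in their active range
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.activation = activation
        self._x: np.ndarray | None = None
        self._a: np.ndarray | None = None
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        z = x @ self.W + self.b
        if self.activation == "softmax":
            z = z - z.max(axis=1, keepdims=True)
            e = np.exp(z)
            a = e / e.sum(axis=1, keepdims=True)
        else:
            a = _ACT[self.activation][0](z)
        if cache:
            self._x, self._a = x, a
        return a

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        x, a = self._x, self._a
        if self.activation == "softmax":
            dz = a * (grad_out - (grad_out * a).sum(axis=1, keepdims=True))
        else:
            dz = grad_out * _ACT[self.activation][1](a)
        self.dW += x.T @ dz
        self.db += dz.sum(axis=0)
        return dz @ self.W.T


class Network:
    """A stack of dense layers; ``sizes`` includes input and output widths.

    ``hidden_activation`` applies to all but the last layer; the last layer
    uses ``output_activation`` (``identity``, ``softmax``, ``tanh``,
    ``sigmoid``).
    """

    def __init__(self, sizes: list[int], hidden_activation: str,
                 output_activation: str, rng: np.random.Generator):
        if len(sizes) < 2:
            raise ValueError("need at least input and output sizes")
        self.layers = []
        for i in range(len(sizes) - 1):
            act = output_activation if i == len(sizes) - 2 else hidden_activation
            self.layers.append(Dense(sizes[i], sizes[i + 1], act, rng))
        self.sizes = list(sizes)
        self.hidden_activation = hidden_activation
        self.output_activation = output_activation

    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, cache=cache)
        return x

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad_out = layer.backward(grad_out)
        return grad_out

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.dW[:] = 0.0
            layer.db[:] = 0.0

    def parameters(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers:
            out.extend([layer.W, layer.b])
        return out

    def gradients(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers:
            out.extend([layer.dW, layer.db])
        return out

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.parameters(), state):
            p[:] = s

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.forward(np.asarray(x, dtype=float), cache=False)


def loss_value_and_grad(kind: str, pred: np.ndarray, target: np.ndarray
                        ) -> tuple[float, np.ndarray]:
    """Batch-mean loss and its gradient with respect to ``pred`` (rows are
    samples). Matches :func:`ecolatent.metrics.loss` in value."""
    n = pred.shape[0]
    if kind == "mse":
        diff = pred - target
        return float((diff ** 2).mean()), 2.0 * diff / diff.size
    if kind == "crossentropy":
        p = pred + CROSSENTROPY_EPS
        value = float(-(target * np.log(p)).sum(axis=1).mean())
        return value, -target / p / n
    if kind == "braycurtis":
        diff = pred - target
        d = np.abs(diff).sum(axis=1, keepdims=True)
        s = (pred + target).sum(axis=1, keepdims=True)
        value = float((d / s).mean())
        grad = (np.sign(diff) / s - d / s ** 2) / n
        return value, grad
    raise ValueError(f"unknown loss kind {kind!r}")


class Adam:
    """Adam optimizer over a flat list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[:] = b1 * m + (1 - b1) * g
            v[:] = b2 * v + (1 - b2) * g ** 2
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def minibatches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def fit_network(net: Network, x: np.ndarray, y: np.ndarray, *, loss_kind: str,
                learning_rate: float, batch_size: int, epochs: int, patience: int,
                rng: np.random.Generator,
                x_val: np.ndarray | None = None,
                y_val: np.ndarray | None = None) -> dict:
    """Mini-batch training with early stopping on validation loss.

    Returns a history dict with per-epoch ``train_loss`` and ``val_loss``
    (validation defaults to the training data when none is given). The best
    validation-loss parameters are restored at the end. Raises on non-finite
    loss, reporting the epoch.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x_val is None:
        x_val, y_val = x, y
    opt = Adam(net.parameters(), lr=learning_rate)
    history = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_state = net.get_state()
    bad_epochs = 0
    for epoch in range(epochs):
        epoch_loss = 0.0
        n_seen = 0
        for idx in minibatches(x.shape[0], batch_size, rng):
            net.zero_grad()
            pred = net.forward(x[idx])
            value, grad = loss_value_and_grad(loss_kind, pred, y[idx])
            if not np.isfinite(value):
                raise FloatingPointError(f"training diverged at epoch {epoch}: loss={value}")
            net.backward(grad)
            opt.step(net.gradients())
            epoch_loss += value * len(idx)
            n_seen += len(idx)
        val_pred = net.forward(x_val, cache=False)
        val_value, _ = loss_value_and_grad(loss_kind, val_pred, y_val)
        if not np.isfinite(val_value):
            raise FloatingPointError(f"training diverged at epoch {epoch}: val loss={val_value}")
        history["train_loss"].append(epoch_loss / max(n_seen, 1))
        history["val_loss"].append(val_value)
        if val_value < best_val - 1e-12:
            best_val = val_value
            best_state = net.get_state()
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs > patience:
                break
    net.set_state(best_state)
    history["best_val_loss"] = float(best_val) if np.isfinite(best_val) else None
    return history


def network_state_flat(nets: list[Network]) -> list[np.ndarray]:
    state = []
    for net in nets:
        state.extend(net.get_state())
    return state


def set_network_state_flat(nets: list[Network], state: list[np.ndarray]) -> None:
    i = 0
    for net in nets:
        n = len(net.parameters())
        net.set_state(state[i:i + n])
        i += n
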