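"""Sequential network, Adam optimizer, and the training loop.

Training minimises categorical cross-entropy (plus any L2 kernel penalties)
with mini-batch Adam, a held-out validation split, and optional
early-stopping / learning-rate-reduction callbacks keyed on validation loss
— the usual deep-learning defaults for small tabular/sequence classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layers import Layer


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Adam:
    def __init__(self, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7) -> None:
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m: list[np.ndarray] | None = None
        self._v: list[np.ndarray] | None = None

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        if self._m is None:
            self._m = [np.zeros_like(p) for p in params]
            self._v = [np.zeros_like(p) for p in params]
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, g, m, v in zip(params, grads, self._m, self._v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


@dataclass
class History:
    """Per-epoch training curves."""

    loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    acc: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    stopped_epoch: int | None = None


class Sequential:
    """A feed-forward stack of layers with a softmax/cross-entropy head."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params))

    def forward(self, X: np.ndarray, training: bool = False) -> np.ndarray:
        out = X
        for layer in self.layers:
            out = layer.forward(out, training)
        return softmax(out)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X, training=False)

    def predict_classes(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)

    def loss(self, proba: np.ndarray, Y: np.ndarray) -> float:
        ce = -np.mean(np.sum(Y * np.log(proba + 1e-12), axis=1))
        return float(ce + sum(layer.l2_penalty() for layer in self.layers))

    def _backward(self, proba: np.ndarray, Y: np.ndarray) -> None:
        # combined softmax + cross-entropy gradient
        g = (proba - Y) / Y.shape[0]
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def evaluate(self, X: np.ndarray, Y: np.ndarray,
                 batch_size: int = 256) -> tuple[float, float]:
        losses, correct, n = [], 0, X.shape[0]
        for s in range(0, n, batch_size):
            xb, yb = X[s:s + batch_size], Y[s:s + batch_size]
            p = self.forward(xb, training=False)
            losses.append(self.loss(p, yb) * xb.shape[0])
            correct += int((np.argmax(p, 1) == np.argmax(yb, 1)).sum())
        return float(np.sum(losses) / n), correct / n

    def fit(self, X: np.ndarray, Y: np.ndarray, *, epochs: int,
            batch_size: int = 32, validation_split: float = 0.1,
            optimizer: Adam | None = None, seed: int = 0,
            early_stopping_patience: int | None = None,
            reduce_lr_patience: int | None = None,
            reduce_lr_factor: float = 0.5, min_lr: float = 1e-5,
            ) -> History:
        """Mini-batch training with validation-loss-driven callbacks.

        The trailing ``validation_split`` fraction of a seeded shuffle of the
        data is held out; batches are reshuffled every epoch from the same
        seeded generator, so training is reproducible run to run.
        """
        rng = np.random.default_rng(seed)
        opt = optimizer or Adam()
        n = X.shape[0]
        order = rng.permutation(n)
        n_val = int(round(n * validation_split))
        if n_val > 0:
            val_idx, tr_idx = order[n - n_val:], order[:n - n_val]
        else:
            val_idx, tr_idx = order[:0], order
        Xtr, Ytr = X[tr_idx], Y[tr_idx]
        Xval, Yval = X[val_idx], Y[val_idx]

        hist = History()
        best_val = np.inf          # early stopping: any improvement counts
        best_val_lr = np.inf       # LR plateau: needs a 1e-4 improvement
        best_weights = None
        since_improve = 0
        since_reduce = 0
        for epoch in range(epochs):
            perm = rng.permutation(Xtr.shape[0])
            epoch_loss, epoch_correct = 0.0, 0
            for s in range(0, len(perm), batch_size):
                idx = perm[s:s + batch_size]
                xb, yb = Xtr[idx], Ytr[idx]
                proba = self.forward(xb, training=True)
                epoch_loss += self.loss(proba, yb) * len(idx)
                epoch_correct += int(
                    (np.argmax(proba, 1) == np.argmax(yb, 1)).sum())
                self._backward(proba, yb)
                opt.step(self.params, self.grads)
            hist.loss.append(epoch_loss / len(perm))
            hist.acc.append(epoch_correct / len(perm))
            hist.lr.append(opt.lr)
            if n_val > 0:
                vl, va = self.evaluate(Xval, Yval)
            else:
                vl, va = hist.loss[-1], hist.acc[-1]
            hist.val_loss.append(vl)
            hist.val_acc.append(va)

            if vl < best_val:
                best_val = vl
                since_improve = 0
                if early_stopping_patience is not None:
                    best_weights = [p.copy() for p in self.params]
            else:
                since_improve += 1
            if vl < best_val_lr - 1e-4:
                best_val_lr = vl
                since_reduce = 0
            else:
                since_reduce += 1
            if (reduce_lr_patience is not None
                    and since_reduce >= reduce_lr_patience
                    and opt.lr > min_lr):
                opt.lr = max(opt.lr * reduce_lr_factor, min_lr)
                since_reduce = 0
            if (early_stopping_patience is not None
                    and since_improve >= early_stopping_patience):
                hist.stopped_epoch = epoch
                break
        if best_weights is not None:
            for p, w in zip(self.params, best_weights):
                p[...] = w
        return hist
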