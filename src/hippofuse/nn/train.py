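"""SGD-with-momentum training loop shared by the CNN and the fusion heads."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layers import BatchNorm, Layer, softmax_xent


def _take(x, idx):
    if isinstance(x, (tuple, list)):
        return tuple(a[idx] for a in x)
    return x[idx]


def _nrows(x) -> int:
    return x[0].shape[0] if isinstance(x, (tuple, list)) else x.shape[0]


class SGD:
    """Stochastic gradient descent with classical momentum and L2 penalty.

    The penalty ``l2 * sum(w^2)`` is applied to parameters flagged for
    weight decay (conv/dense kernels, not biases or batch-norm scales).
    """

    def __init__(self, param_items: list[tuple[Layer, str]], lr: float,
                 momentum: float, l2: float):
        self.items = param_items
        self.lr, self.momentum, self.l2 = lr, momentum, l2
        self.vel = [np.zeros_like(lay.params[name]) for lay, name in param_items]

    def step(self):
        for v, (lay, name) in zip(self.vel, self.items):
            g = lay.grads[name]
            if name in lay.decay:
                g = g + 2.0 * self.l2 * lay.params[name]
            v *= self.momentum
            v -= self.lr * g
            lay.params[name] += v

    def penalty(self) -> float:
        return self.l2 * sum(float((lay.params[name] ** 2).sum())
                             for lay, name in self.items if name in lay.decay)


def get_state(model) -> list[np.ndarray]:
    state = []
    for lay, name in model.param_items():
        state.append(lay.params[name].copy())
    for lay in model.all_layers():
        if isinstance(lay, BatchNorm):
            state.append(lay.running_mean.copy())
            state.append(lay.running_var.copy())
    return state


def set_state(model, state: list[np.ndarray]) -> None:
    it = iter(state)
    for lay, name in model.param_items():
        lay.params[name] = next(it).copy()
    for lay in model.all_layers():
        if isinstance(lay, BatchNorm):
            lay.running_mean = next(it).copy()
            lay.running_var = next(it).copy()


@dataclass
class History:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    best_epoch: int = -1


def evaluate_loss(model, x, y, batch_size: int = 32) -> tuple[float, float]:
    """Mean cross-entropy and accuracy in inference mode."""
    n = _nrows(x)
    losses, correct = 0.0, 0
    for s in range(0, n, batch_size):
        idx = slice(s, min(s + batch_size, n))
        logits = model.forward(_take(x, idx), training=False)
        loss, _ = softmax_xent(logits, y[idx])
        losses += loss * (logits.shape[0])
        correct += int((logits.argmax(axis=1) == y[idx]).sum())
    return losses / n, correct / n


def fit_classifier(model, x, y, *, epochs: int, batch_size: int, lr: float,
                   momentum: float, l2: float, seed: int,
                   val: tuple | None = None,
                   select_best: bool = True) -> History:
    """Train ``model`` in place; returns the training history.

    With a validation set and ``select_best``, the parameters from the epoch
    with the lowest validation loss are restored at the end.
    """
    hist = History()
    if epochs == 0:
        return hist
    rng = np.random.default_rng(seed)
    opt = SGD(model.param_items(), lr=lr, momentum=momentum, l2=l2)
    n = _nrows(x)
    best_loss, best_state = np.inf, None
    for epoch in range(epochs):
        order = rng.permutation(n)
        ep_loss = 0.0
        for s in range(0, n, batch_size):
            idx = order[s:s + batch_size]
            logits = model.forward(_take(x, idx), training=True)
            loss, dlogits = softmax_xent(logits, y[idx])
            model.backward(dlogits)
            opt.step()
            ep_loss += loss * len(idx)
        hist.train_loss.append(ep_loss / n + opt.penalty())
        if val is not None:
            vloss, vacc = evaluate_loss(model, val[0], val[1], batch_size)
            hist.val_loss.append(vloss)
            hist.val_acc.append(vacc)
            if select_best and vloss < best_loss:
                best_loss, best_state = vloss, get_state(model)
                hist.best_epoch = epoch
    if best_state is not None:
        set_state(model, best_state)
    return hist
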