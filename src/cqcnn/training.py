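"""Loss, optimizers, training loop, metrics and multi-run diagnostics.

The loss is two-class cross-entropy over the (o1, 1-o1) output head; the
parameter update is plain first-order descent ``theta <- theta - lr * grad``
or one of the adaptive variants (Adam by default — in the reference
experiments it was the only optimizer that reliably converged on
near-identical classes; SGD, RMSprop, Adagrad and L-BFGS are available for
ablation).  Quantum circuit angles receive parameter-shift gradients chained
through the output head; classical weights plain backpropagation.

Repeated-run diagnostics summarise convergence variability with a one-way
ANOVA over each run's final-window training accuracies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Sequence

import numpy as np
from scipy import stats

from .network import CQCNNNetwork

OPTIMIZERS = ("sgd", "adam", "rmsprop", "adagrad", "lbfgs")

_EPS_LOG = 1e-12


class TrainingError(ValueError):
    """Invalid training request (empty batch, single class, bad config)."""


@dataclass
class TrainConfig:
    """Defaults mirror the reference classification protocol:
    batch 32, learning rate 1e-3, Adam, cross-entropy."""

    batch_size: int = 32
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    epochs: int = 10
    seed: int = 0
    runs: int = 5

    def __post_init__(self) -> None:
        if self.optimizer not in OPTIMIZERS:
            raise TrainingError(
                f"unknown optimizer {self.optimizer!r}; choose from {OPTIMIZERS}")


def cross_entropy(gamma: np.ndarray, labels: np.ndarray) -> float:
    """Mean negative log-probability of the true class.

    *gamma* is (B, C) rows on the simplex; *labels* either class indices
    (B,) or one-hot (B, C).  Log arguments are clamped at 1e-12.
    """
    gamma = np.asarray(gamma, dtype=np.float64)
    if gamma.ndim != 2 or gamma.shape[0] == 0:
        raise TrainingError(f"need a non-empty (B, C) probability batch, got {gamma.shape}")
    labels = np.asarray(labels)
    if labels.ndim == 2:
        labels = labels.argmax(axis=1)
    p_true = gamma[np.arange(gamma.shape[0]), labels.astype(int)]
    return float(-np.mean(np.log(np.clip(p_true, _EPS_LOG, None))))


# ---------------------------------------------------------------------------
# optimizers

class Optimizer:
    """In-place parameter update from a gradient dict."""

    def __init__(self, lr: float):
        self.lr = lr

    def step(self, params: Dict[str, np.ndarray], grads: Dict[str, np.ndarray]) -> None:
        raise NotImplementedError


class SGD(Optimizer):
    def step(self, params, grads):
        for k, g in grads.items():
            params[k] -= self.lr * np.asarray(g).reshape(params[k].shape)


class Adam(Optimizer):
    def __init__(self, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        super().__init__(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m: Dict[str, np.ndarray] = {}
        self.v: Dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for k, g in grads.items():
            g = np.asarray(g).reshape(params[k].shape)
            m = self.m.setdefault(k, np.zeros_like(params[k]))
            v = self.v.setdefault(k, np.zeros_like(params[k]))
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            mhat = m / (1 - self.beta1 ** self.t)
            vhat = v / (1 - self.beta2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class RMSprop(Optimizer):
    def __init__(self, lr, alpha=0.99, eps=1e-8):
        super().__init__(lr)
        self.alpha, self.eps = alpha, eps
        self.sq: Dict[str, np.ndarray] = {}

    def step(self, params, grads):
        for k, g in grads.items():
            g = np.asarray(g).reshape(params[k].shape)
            sq = self.sq.setdefault(k, np.zeros_like(params[k]))
            sq *= self.alpha
            sq += (1 - self.alpha) * g * g
            params[k] -= self.lr * g / (np.sqrt(sq) + self.eps)


class Adagrad(Optimizer):
    def __init__(self, lr, eps=1e-10):
        super().__init__(lr)
        self.eps = eps
        self.acc: Dict[str, np.ndarray] = {}

    def step(self, params, grads):
        for k, g in grads.items():
            g = np.asarray(g).reshape(params[k].shape)
            acc = self.acc.setdefault(k, np.zeros_like(params[k]))
            acc += g * g
            params[k] -= self.lr * g / (np.sqrt(acc) + self.eps)


class LBFGS(Optimizer):
    """Limited-memory BFGS direction on minibatch gradients.

    A stochastic simplification: curvature pairs are collected across
    successive minibatch steps with a fixed step length (no line search).
    Kept for the optimizer ablation; not expected to converge well on this
    loss surface.
    """

    def __init__(self, lr, history: int = 10):
        super().__init__(lr)
        self.history = history
        self.s: List[np.ndarray] = []
        self.y: List[np.ndarray] = []
        self.prev_x: np.ndarray | None = None
        self.prev_g: np.ndarray | None = None

    @staticmethod
    def _flatten(d, keys):
        return np.concatenate([np.asarray(d[k]).ravel() for k in keys])

    def step(self, params, grads):
        keys = sorted(grads)
        g = self._flatten(grads, keys)
        x = self._flatten(params, keys)
        if self.prev_x is not None:
            s, y = x - self.prev_x, g - self.prev_g
            if s @ y > 1e-10:
                self.s.append(s)
                self.y.append(y)
                if len(self.s) > self.history:
                    self.s.pop(0)
                    self.y.pop(0)
        q = g.copy()
        alphas = []
        for s, y in zip(reversed(self.s), reversed(self.y)):
            rho = 1.0 / (y @ s)
            a = rho * (s @ q)
            alphas.append((a, rho, s, y))
            q -= a * y
        if self.s:
            q *= (self.s[-1] @ self.y[-1]) / (self.y[-1] @ self.y[-1])
        for a, rho, s, y in reversed(alphas):
            q += s * (a - rho * (y @ q))
        self.prev_x, self.prev_g = x.copy(), g.copy()
        x_new = x - self.lr * q
        ofs = 0
        for k in keys:
            n = params[k].size
            params[k] = x_new[ofs:ofs + n].reshape(params[k].shape)
            ofs += n


def make_optimizer(name: str, lr: float) -> Optimizer:
    return {"sgd": SGD, "adam": Adam, "rmsprop": RMSprop,
            "adagrad": Adagrad, "lbfgs": LBFGS}[name](lr)


# ---------------------------------------------------------------------------
# training loop

def _accuracy(gamma: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean(gamma.argmax(axis=1) == y))


def train(model: CQCNNNetwork, X: np.ndarray, y: np.ndarray,
          cfg: TrainConfig, X_val: np.ndarray | None = None,
          y_val: np.ndarray | None = None) -> dict:
    """Optimize *model* in place; returns the per-epoch history.

    Fully reproducible given ``cfg.seed`` (it drives minibatch shuffling and
    the dropout masks; the circuit expectation is exact, no shot noise).
    """
    y = np.asarray(y).astype(int).ravel()
    if X.shape[0] != y.shape[0] or X.shape[0] == 0:
        raise TrainingError(f"inconsistent dataset: {X.shape[0]} images, {y.shape[0]} labels")
    if np.unique(y).size < 2:
        raise TrainingError("training requires samples from two classes")
    rng = np.random.default_rng(cfg.seed)
    opt = make_optimizer(cfg.optimizer, cfg.learning_rate)
    history = {"epoch": [], "train_loss": [], "train_acc": [], "val_acc": []}
    n = X.shape[0]
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, yb = X[idx], y[idx]
            gamma, cache = model.forward(xb, training=True, rng=rng)
            # dL/d o1 for gamma = (o1, 1-o1): -1/(B*o1) for class 0,
            # +1/(B*(1-o1)) for class 1, with the same clamp as the loss
            o1 = np.clip(cache["o1"], _EPS_LOG, 1.0 - _EPS_LOG)
            b = len(idx)
            d_o1 = np.where(yb == 0, -1.0 / o1, 1.0 / (1.0 - o1)) / b
            grads = model.backward(cache, d_o1)
            opt.step(model.params, grads)
        gamma_tr = model.predict_proba(X)
        history["epoch"].append(epoch)
        history["train_loss"].append(cross_entropy(gamma_tr, y))
        history["train_acc"].append(_accuracy(gamma_tr, y))
        if X_val is not None and len(X_val):
            history["val_acc"].append(_accuracy(model.predict_proba(X_val),
                                                np.asarray(y_val).astype(int).ravel()))
        else:
            history["val_acc"].append(float("nan"))
    return history


# ---------------------------------------------------------------------------
# evaluation metrics

@dataclass
class MetricsReport:
    """Binary-classification metrics from a 2x2 confusion table.

    confusion is ``[[TN, FP], [FN, TP]]`` with respect to *positive_class*.
    Ratios with a zero denominator are reported as 0.0 and listed in
    ``undefined``.
    """

    precision: float
    recall: float
    f1: float
    specificity: float
    accuracy: float
    confusion: np.ndarray
    positive_class: int
    undefined: tuple = ()


def metrics_from_confusion(tn: int, fp: int, fn: int, tp: int,
                           positive_class: int = 1) -> MetricsReport:
    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    precision = ratio(tp, tp + fp, "precision")
    recall = ratio(tp, tp + fn, "recall")
    f1 = ratio(2 * precision * recall, precision + recall, "f1")
    specificity = ratio(tn, tn + fp, "specificity")
    accuracy = ratio(tp + tn, tn + fp + fn + tp, "accuracy")
    return MetricsReport(precision=precision, recall=recall, f1=f1,
                         specificity=specificity, accuracy=accuracy,
                         confusion=np.array([[tn, fp], [fn, tp]]),
                         positive_class=positive_class,
                         undefined=tuple(undefined))


def evaluate(model: CQCNNNetwork, X: np.ndarray, y: np.ndarray,
             positive_class: int = 1) -> MetricsReport:
    """Metrics at the argmax(gamma) decision rule.

    The positive class defaults to label 1 (by the package's data
    conventions, the minority clinical class).
    """
    y = np.asarray(y).astype(int).ravel()
    pred = model.predict_proba(X).argmax(axis=1)
    return metrics_from_predictions(y, pred, positive_class)


def metrics_from_predictions(y_true: np.ndarray, y_pred: np.ndarray,
                             positive_class: int = 1) -> MetricsReport:
    y_true = np.asarray(y_true).astype(int).ravel()
    y_pred = np.asarray(y_pred).astype(int).ravel()
    pos = positive_class
    tp = int(np.sum((y_pred == pos) & (y_true == pos)))
    tn = int(np.sum((y_pred != pos) & (y_true != pos)))
    fp = int(np.sum((y_pred == pos) & (y_true != pos)))
    fn = int(np.sum((y_pred != pos) & (y_true == pos)))
    return metrics_from_confusion(tn, fp, fn, tp, positive_class)


def aggregate_metrics(reports: Sequence[MetricsReport]) -> dict:
    """Mean and standard deviation per metric over repeated runs."""
    out = {}
    for name in ("precision", "recall", "f1", "specificity", "accuracy"):
        vals = np.array([getattr(r, name) for r in reports], dtype=float)
        out[name] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1))
                     if len(vals) > 1 else 0.0}
    return out


# ---------------------------------------------------------------------------
# repeated runs / convergence diagnostics

@dataclass
class ConvergenceReport:
    curves: list                 # per-run epoch train-accuracy lists
    val_curves: list
    anova_f: float
    anova_p: float
    window: int


def one_way_anova(groups: Sequence[Sequence[float]]):
    """One-way ANOVA F and p; degenerate zero-variance input yields (0, 1)."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise TrainingError("ANOVA needs at least two groups")
    flat = np.concatenate(arrays)
    if np.allclose(flat, flat[0]):
        return 0.0, 1.0
    f, p = stats.f_oneway(*arrays)
    if not np.isfinite(f):
        return 0.0, 1.0
    return float(f), float(p)


def run_repeated(model_factory: Callable[[int], CQCNNNetwork],
                 X: np.ndarray, y: np.ndarray, cfg: TrainConfig,
                 runs: int | None = None, window: int = 3,
                 X_val: np.ndarray | None = None,
                 y_val: np.ndarray | None = None) -> ConvergenceReport:
    """Train ``runs`` independent replicates and quantify run-to-run spread.

    ``model_factory(seed)`` must build a freshly initialised model; per-run
    seeds derive from ``cfg.seed`` by a fixed counter.  The ANOVA groups are
    each run's last-*window* per-epoch training accuracies.
    """
    runs = cfg.runs if runs is None else runs
    if runs < 2:
        raise TrainingError(f"repeated-run analysis needs runs >= 2, got {runs}")
    curves, val_curves = [], []
    for r in range(runs):
        seed_r = int(cfg.seed) + 1 + r
        model = model_factory(seed_r)
        run_cfg = TrainConfig(batch_size=cfg.batch_size,
                              learning_rate=cfg.learning_rate,
                              optimizer=cfg.optimizer, epochs=cfg.epochs,
                              seed=seed_r, runs=cfg.runs)
        hist = train(model, X, y, run_cfg, X_val, y_val)
        curves.append(list(hist["train_acc"]))
        val_curves.append(list(hist["val_acc"]))
    groups = [c[-window:] for c in curves]
    f, p = one_way_anova(groups)
    return ConvergenceReport(curves=curves, val_curves=val_curves,
                             anova_f=f, anova_p=p, window=window)
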