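"""Shallow feed-forward classifier variants and the staging metric suite.

The testing phase scores deep features with five small fully connected
networks distinguished only by hidden layout — narrow (NNN), medium
(MNN), shallow-wide (SWNN), bi-layered (BNN) and tri-layered (TNN) —
evaluated with stratified k-fold cross-validation and reported as
confusion-matrix metrics: accuracy, macro sensitivity (recall), macro
precision, macro F1 and the false negative rate FNR = 100 - sensitivity.

Hidden layouts (fixed here; the convention follows the usual
narrow/medium/wide presets of point-and-click classifier toolboxes):
NNN=[10], MNN=[25], SWNN=[100], BNN=[10,10], TNN=[10,10,10].

The networks are trained by plain SGD with momentum on the softmax
cross-entropy loss; weights, shuffling and fold assignment are all
seeded, so every fit is bit-reproducible.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "VARIANT_LAYOUTS",
    "ClassifierSpec",
    "ClassificationReport",
    "MLP",
    "build_classifier",
    "fit",
    "compute_metrics",
    "kfold_evaluate",
    "stratified_split",
]

VARIANT_LAYOUTS = {
    "NNN": [10],
    "MNN": [25],
    "SWNN": [100],
    "BNN": [10, 10],
    "TNN": [10, 10, 10],
}


@dataclass
class ClassifierSpec:
    variant: str
    input_dim: int
    n_classes: int
    seed: int = 0
    hidden_layout: list[int] | None = None

    def __post_init__(self):
        if self.variant not in VARIANT_LAYOUTS:
            raise ValueError(f"unknown classifier variant {self.variant!r}")
        if self.hidden_layout is None:
            self.hidden_layout = list(VARIANT_LAYOUTS[self.variant])
        if self.input_dim < 1:
            raise ValueError("input_dim must be >= 1")


@dataclass
class ClassificationReport:
    confusion: np.ndarray
    accuracy: float
    sensitivity: float
    precision: float
    f1: float
    fnr: float
    per_class: dict = field(default_factory=dict)
    elapsed_s: float = 0.0


class MLP:
    """Fully connected ReLU network with softmax output, manual backprop."""

    def __init__(self, layout: list[int], seed: int = 0):
        self.layout = list(layout)
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        self.W, self.b = [], []
        for din, dout in zip(layout[:-1], layout[1:]):
            limit = np.sqrt(6.0 / din)
            self.W.append(rng.uniform(-limit, limit, size=(din, dout)))
            self.b.append(np.zeros(dout))
        self.mu = np.zeros(layout[0])
        self.sd = np.ones(layout[0])
        self.final_loss = None

    def n_parameters(self) -> int:
        return sum(w.size + b.size for w, b in zip(self.W, self.b))

    def _forward(self, X):
        acts = [X]
        for i, (w, b) in enumerate(zip(self.W, self.b)):
            z = acts[-1] @ w + b
            acts.append(np.maximum(z, 0.0) if i < len(self.W) - 1 else z)
        return acts

    def fit(self, X, y, epochs: int = 200, lr: float = 1e-3,
            momentum: float = 0.9, batch_size: int = 32, seed: int = 0):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if np.isnan(X).any():
            raise ValueError("features contain NaN")
        self.mu = X.mean(axis=0)
        self.sd = X.std(axis=0)
        self.sd[self.sd == 0] = 1.0
        Xs = (X - self.mu) / self.sd
        rng = np.random.default_rng(seed)
        vel = [np.zeros_like(w) for w in self.W] + [np.zeros_like(b) for b in self.b]
        n = len(Xs)
        for _ in range(epochs):
            order = rng.permutation(n)
            losses = []
            for s in range(0, n, batch_size):
                idx = order[s:s + batch_size]
                acts = self._forward(Xs[idx])
                z = acts[-1]
                zs = z - z.max(axis=1, keepdims=True)
                p = np.exp(zs)
                p /= p.sum(axis=1, keepdims=True)
                m = len(idx)
                losses.append(float(np.mean(
                    -zs[np.arange(m), y[idx]] + np.log(np.exp(zs).sum(axis=1)))))
                g = p
                g[np.arange(m), y[idx]] -= 1.0
                g /= m
                grads_w, grads_b = [], []
                for i in range(len(self.W) - 1, -1, -1):
                    grads_w.append(acts[i].T @ g)
                    grads_b.append(g.sum(axis=0))
                    if i > 0:
                        g = (g @ self.W[i].T) * (acts[i] > 0)
                grads_w.reverse()
                grads_b.reverse()
                for i in range(len(self.W)):
                    vel[i] = momentum * vel[i] - lr * grads_w[i]
                    self.W[i] += vel[i]
                    j = len(self.W) + i
                    vel[j] = momentum * vel[j] - lr * grads_b[i]
                    self.b[i] += vel[j]
            self.final_loss = float(np.mean(losses)) if losses else None
        return self

    def decision_function(self, X):
        Xs = (np.asarray(X, dtype=float) - self.mu) / self.sd
        return self._forward(Xs)[-1]

    def predict_proba(self, X):
        z = self.decision_function(X)
        z -= z.max(axis=1, keepdims=True)
        p = np.exp(z)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X):
        return np.argmax(self.decision_function(X), axis=1)


def build_classifier(spec: ClassifierSpec) -> MLP:
    """Instantiate the variant's network with seeded initial weights."""
    layout = [spec.input_dim] + list(spec.hidden_layout) + [spec.n_classes]
    return MLP(layout, seed=spec.seed)


def fit(clf: MLP, X, y, epochs: int = 200, seed: int = 0, **kw) -> MLP:
    return clf.fit(X, y, epochs=epochs, seed=seed, **kw)


def compute_metrics(confusion) -> ClassificationReport:
    """Macro-averaged metrics from a C x C confusion matrix (rows = true).

    Classes with zero support are excluded from the macro averages;
    FNR is 100 - macro sensitivity by construction.
    """
    cm = np.asarray(confusion, dtype=float)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1] or cm.size == 0:
        raise ValueError("confusion matrix must be square and non-empty")
    total = cm.sum()
    if total == 0:
        raise ValueError("confusion matrix is all zero")
    support = cm.sum(axis=1)
    predicted = cm.sum(axis=0)
    diag = np.diag(cm)
    live = support > 0
    recall = np.divide(diag, support, out=np.zeros_like(diag), where=support > 0)
    prec = np.divide(diag, predicted, out=np.zeros_like(diag), where=predicted > 0)
    denom = recall + prec
    f1 = np.divide(2 * recall * prec, denom, out=np.zeros_like(diag),
                   where=denom > 0)
    sens = 100.0 * recall[live].mean()
    report = ClassificationReport(
        confusion=cm.astype(int),
        accuracy=100.0 * diag.sum() / total,
        sensitivity=sens,
        precision=100.0 * prec[live].mean(),
        f1=100.0 * f1[live].mean(),
        fnr=100.0 - sens,
        per_class={int(c): {"recall": 100.0 * recall[c],
                            "precision": 100.0 * prec[c]}
                   for c in np.flatnonzero(live)},
    )
    return report


def kfold_evaluate(X, y, spec: ClassifierSpec, k: int = 10, seed: int = 0,
                   epochs: int = 200):
    """Stratified k-fold CV; pooled confusion across folds.

    Returns (report from the pooled confusion, list of per-fold reports).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = np.bincount(y)
    if counts[counts > 0].min() < k:
        raise ValueError(f"every class needs >= {k} members for {k}-fold CV")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    n_classes = spec.n_classes
    pooled = np.zeros((n_classes, n_classes), dtype=int)
    fold_reports = []
    t0 = time.perf_counter()
    for tr, te in skf.split(X, y):
        clf = build_classifier(spec)
        clf.fit(X[tr], y[tr], epochs=epochs, seed=spec.seed)
        pred = clf.predict(X[te])
        cm = np.zeros((n_classes, n_classes), dtype=int)
        np.add.at(cm, (y[te], pred), 1)
        pooled += cm
        fold_reports.append(compute_metrics(cm))
    report = compute_metrics(pooled)
    report.elapsed_s = time.perf_counter() - t0
    return report, fold_reports


def stratified_split(y, test_fraction: float = 0.2, seed: int = 0):
    """Seeded stratified index split; returns (train_idx, test_idx)."""
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    train, test = [], []
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        n_test = max(1, int(round(test_fraction * len(idx))))
        test.extend(idx[:n_test])
        train.extend(idx[n_test:])
    return np.sort(np.array(train)), np.sort(np.array(test))
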