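"""Executable instantiation of a :class:`~denseinceps.netspec.NetworkGraph`.

Builds seeded weight tensors for every learnable node, runs forward
passes (optionally tapping any intermediate layer — in particular the
fusion concatenation, which yields the deep feature matrix), and trains
with SGD-with-momentum on the combined softmax/cross-entropy loss.

Weight initialization: He-uniform for convolutions, Xavier-uniform for
fully connected layers and attention projections (the smaller
classifier-head scale keeps initial logits moderate, which markedly
stabilizes short training runs), ones/zeros for batch norm; all drawn
from one seeded generator so a graph + seed pair is fully reproducible.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .netspec import NetworkGraph, infer_shapes, attention_geometry

__all__ = ["NetworkModel", "softmax_cross_entropy"]


def softmax_cross_entropy(logits, true_class: int) -> float:
    """-t_y + log(sum_j exp(t_j)), log-sum-exp stabilized (scalar form)."""
    t = np.asarray(logits, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("logits must be finite")
    if not 0 <= true_class < t.size:
        raise ValueError("true_class out of range")
    m = t.max()
    return float(-t[true_class] + m + np.log(np.exp(t - m).sum()))


def _he_uniform(rng, shape, fan_in):
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


def _xavier_uniform(rng, shape):
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class NetworkModel:
    """Weights + forward/backward execution for one network graph."""

    def __init__(self, graph: NetworkGraph, seed: int = 0):
        self.graph = graph
        self.shapes = infer_shapes(graph)
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        self.params: dict[str, dict[str, ag.Tensor]] = {}
        self.bn_stats: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for l in graph.layers:
            if l.kind in ("convolution", "grouped-convolution"):
                cin = self.shapes[l.inputs[0]][0]
                g = l.groups or 1
                w = _he_uniform(rng,
                                (l.out_channels, cin // g, l.filter_h, l.filter_w),
                                fan_in=l.filter_h * l.filter_w * cin // g)
                self.params[l.id] = {
                    "w": ag.Tensor(w, requires_grad=True),
                    "b": ag.Tensor(np.zeros(l.out_channels, np.float32),
                                   requires_grad=True),
                }
            elif l.kind == "batch-norm":
                c = self.shapes[l.inputs[0]][0]
                self.params[l.id] = {
                    "gamma": ag.Tensor(np.ones(c, np.float32), requires_grad=True),
                    "beta": ag.Tensor(np.zeros(c, np.float32), requires_grad=True),
                }
                self.bn_stats[l.id] = (np.zeros(c, np.float32),
                                       np.ones(c, np.float32))
            elif l.kind == "fully-connected":
                din = self.shapes[l.inputs[0]][0]
                self.params[l.id] = {
                    "w": ag.Tensor(_xavier_uniform(rng, (din, l.out_channels)),
                                   requires_grad=True),
                    "b": ag.Tensor(np.zeros(l.out_channels, np.float32),
                                   requires_grad=True),
                }
            elif l.kind == "self-attention":
                _, n = attention_geometry(graph, l, self.shapes)
                p = {k: ag.Tensor(_xavier_uniform(rng, (n, n)),
                                  requires_grad=True)
                     for k in ("wq", "wk", "wv")}
                if (l.heads or 1) > 1:
                    p["wo"] = ag.Tensor(_xavier_uniform(rng, (n, n)),
                                        requires_grad=True)
                self.params[l.id] = p

    # -- persistence --------------------------------------------------------
    def save(self, path):
        arrays = {}
        for lid, p in self.params.items():
            for k, t in p.items():
                arrays[f"{lid}/{k}"] = t.data
        for lid, (rm, rv) in self.bn_stats.items():
            arrays[f"{lid}/running_mean"] = rm
            arrays[f"{lid}/running_var"] = rv
        np.savez(path, **arrays)

    def load(self, path):
        with np.load(path) as z:
            for lid, p in self.params.items():
                for k, t in p.items():
                    t.data = z[f"{lid}/{k}"]
            for lid in self.bn_stats:
                self.bn_stats[lid] = (z[f"{lid}/running_mean"],
                                      z[f"{lid}/running_var"])
        return self

    def parameters(self):
        for p in self.params.values():
            yield from p.values()

    # -- execution ----------------------------------------------------------
    def _attention(self, l, acts):
        # tokens = spatial positions of the pre-flatten map, embedding = channels
        src = self.graph[l.inputs[0]]
        if src.kind == "flatten":
            x_img = acts[src.inputs[0]]
        else:
            x_img = acts[l.inputs[0]]
        data = x_img.data
        if data.ndim == 4:
            n_b, c, h, w = data.shape
            flat = ag.reshape(x_img, (n_b, c, h * w))
            tok = ag.Tensor(np.transpose(flat.data, (0, 2, 1)),
                            requires_grad=flat.requires_grad, _prev=[flat])

            def backward(g):
                flat._accumulate(np.transpose(g, (0, 2, 1)))
            tok._backward = backward
        else:
            tok = ag.reshape(x_img, (data.shape[0], 1, data.shape[1]))
        p = self.params[l.id]
        heads = l.heads or 1
        n = tok.data.shape[2]
        dk = n // heads
        outs = []
        for hd in range(heads):
            sl = np.s_[:, hd * dk:(hd + 1) * dk]
            wq, wk, wv = (self._slice_cols(p[k], hd * dk, (hd + 1) * dk)
                          for k in ("wq", "wk", "wv"))
            q, k_, v = ag.matmul(tok, wq), ag.matmul(tok, wk), ag.matmul(tok, wv)
            scores = ag.matmul(q, self._transpose_last(k_))
            scores = self._scale(scores, 1.0 / np.sqrt(dk))
            w_att = ag.softmax(scores, axis=-1)
            outs.append(ag.matmul(w_att, v))
        out = outs[0] if len(outs) == 1 else ag.concat(outs, axis=2)
        if "wo" in p:
            out = ag.matmul(out, p["wo"])
        return ag.mean(out, axis=1)  # pool tokens -> (n, C)

    @staticmethod
    def _slice_cols(t, lo, hi):
        view = ag.Tensor(t.data[:, lo:hi], requires_grad=t.requires_grad,
                         _prev=[t])

        def backward(g):
            full = np.zeros_like(t.data)
            full[:, lo:hi] = g
            t._accumulate(full)
        view._backward = backward
        return view

    @staticmethod
    def _transpose_last(t):
        out = ag.Tensor(np.swapaxes(t.data, -1, -2),
                        requires_grad=t.requires_grad, _prev=[t])

        def backward(g):
            t._accumulate(np.swapaxes(g, -1, -2))
        out._backward = backward
        return out

    @staticmethod
    def _scale(t, s):
        out = ag.Tensor(t.data * s, requires_grad=t.requires_grad, _prev=[t])

        def backward(g):
            t._accumulate(g * s)
        out._backward = backward
        return out

    def _run(self, batch: np.ndarray, training: bool, upto: str | None = None):
        """batch: n x H x W x 3 in [0,1]; returns activations dict.

        Inputs are centered at zero internally (x - 0.5): removing the
        DC component conditions the early convolutions and noticeably
        stabilizes short training runs.
        """
        x = np.transpose(np.asarray(batch, dtype=np.float32) - 0.5, (0, 3, 1, 2))
        acts: dict[str, ag.Tensor] = {}
        for l in self.graph.layers:
            if l.kind == "input":
                acts[l.id] = ag.Tensor(x, requires_grad=training)
                acts[l.id].requires_grad = False
                continue
            xin = acts[l.inputs[0]]
            if l.kind in ("convolution", "grouped-convolution"):
                p = self.params[l.id]
                pad = "same" if l.stride == 1 else "valid"
                acts[l.id] = ag.conv2d(xin, p["w"], p["b"], stride=l.stride,
                                       padding=pad, groups=l.groups or 1)
            elif l.kind == "batch-norm":
                p = self.params[l.id]
                rm, rv = self.bn_stats[l.id]
                acts[l.id] = ag.batch_norm(xin, p["gamma"], p["beta"], rm, rv,
                                           training=training)
            elif l.kind == "relu":
                acts[l.id] = ag.relu(xin)
            elif l.kind == "max-pool":
                pad = "same" if l.stride == 1 else "valid"
                acts[l.id] = ag.max_pool2d(xin, f=l.filter_h, stride=l.stride,
                                           padding=pad)
            elif l.kind == "global-average-pool":
                acts[l.id] = ag.global_avg_pool(xin)
            elif l.kind == "depth-concatenation":
                acts[l.id] = ag.concat([acts[i] for i in l.inputs], axis=1)
            elif l.kind == "flatten":
                n_b = xin.data.shape[0]
                acts[l.id] = ag.reshape(xin, (n_b, -1))
            elif l.kind == "self-attention":
                acts[l.id] = self._attention(l, acts)
            elif l.kind == "fully-connected":
                p = self.params[l.id]
                acts[l.id] = ag.linear(xin, p["w"], p["b"])
            elif l.kind == "softmax":
                acts[l.id] = ag.softmax(xin, axis=-1)
            elif l.kind == "classification":
                acts[l.id] = xin
            if l.id == upto:
                break
        return acts

    def forward(self, batch: np.ndarray, tap: str | None = None) -> np.ndarray:
        """Class probabilities, or the activation at ``tap`` if given."""
        known = {l.id for l in self.graph.layers}
        if tap is not None and tap not in known:
            raise KeyError(f"unknown tap layer id {tap!r}")
        acts = self._run(batch, training=False, upto=tap)
        if tap is not None:
            return acts[tap].data.copy()
        return acts[self.graph.layers[-1].id].data.copy()

    def logits_layer(self) -> str:
        for l in reversed(self.graph.layers):
            if l.kind == "fully-connected":
                return l.id
        raise ValueError("graph has no fully-connected layer")

    def train_epochs(self, X: np.ndarray, y: np.ndarray, epochs: int,
                     lr: float = 1.4e-4, momentum: float = 0.7002,
                     batch_size: int = 64, seed: int = 0,
                     callback=None) -> list[float]:
        """SGD-with-momentum training; returns the per-epoch mean loss.

        The loss at epoch index 0 in the returned history is evaluated
        before any update (the epoch-0 reference).
        """
        y = np.asarray(y)
        rng = np.random.default_rng(seed)
        fc = self.logits_layer()
        velocity = {id(t): np.zeros_like(t.data) for t in self.parameters()}
        history = [self.evaluate_loss(X, y, batch_size)]
        n = len(X)
        for _ in range(epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                acts = self._run(X[idx], training=True, upto=fc)
                loss = ag.softmax_cross_entropy(acts[fc], y[idx])
                for t in self.parameters():
                    t.zero_grad()
                loss.backward()
                for t in self.parameters():
                    if t.grad is not None:
                        v = velocity[id(t)]
                        v *= momentum
                        v -= lr * t.grad
                        t.data += v
                losses.append(float(loss.data))
            history.append(float(np.mean(losses)))
            if callback is not None:
                callback(len(history) - 1, history[-1])
        return history

    def evaluate_loss(self, X, y, batch_size=64) -> float:
        fc = self.logits_layer()
        tot, n = 0.0, len(X)
        for start in range(0, n, batch_size):
            acts = self._run(X[start:start + batch_size], training=False, upto=fc)
            loss = ag.softmax_cross_entropy(acts[fc], np.asarray(y)[start:start + batch_size])
            tot += float(loss.data) * len(range(start, min(start + batch_size, n)))
        return tot / n
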