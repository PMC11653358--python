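"""Scaled dot-product self-attention.

The attention nodes of the fused network operate on the flattened final
feature map: the spatial positions are the tokens (m of them) and the
channels form the embedding (n wide).  Queries, keys and values are
linear projections of the token matrix M:

    Aq = M Wq,   Ak = M Wk,   Av = M Wv
    AtS = Aq Ak^T / sqrt(dk)
    AtW = row-softmax(AtS)          (each row sums to 1)
    Attn = AtW Av

``multi_head_attention`` runs the same pipeline per head on dk/heads-wide
projections, concatenates the head outputs and applies one output
projection.

These functions are pure NumPy (float64) and are also used as the
reference semantics for the attention layers instantiated by the network
runtime.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AttentionInput",
    "AttentionWeights",
    "project_qkv",
    "attention_scores",
    "attention_weights",
    "attend",
    "self_attention",
    "multi_head_attention",
]


@dataclass
class AttentionInput:
    """Token matrix M (m×n) plus the three projection matrices (n×dk)."""

    M: np.ndarray
    Wq: np.ndarray
    Wk: np.ndarray
    Wv: np.ndarray

    def __post_init__(self):
        self.M = np.asarray(self.M, dtype=float)
        self.Wq = np.asarray(self.Wq, dtype=float)
        self.Wk = np.asarray(self.Wk, dtype=float)
        self.Wv = np.asarray(self.Wv, dtype=float)
        n = self.M.shape[1]
        for name, w in (("Wq", self.Wq), ("Wk", self.Wk), ("Wv", self.Wv)):
            if w.shape[0] != n:
                raise ValueError(
                    f"{name} has {w.shape[0]} rows, expected {n} (embedding dim)")
        if self.Wq.shape[1] < 1:
            raise ValueError("dk must be >= 1")


@dataclass
class AttentionWeights:
    """Row-stochastic m×m attention weight matrix."""

    AtW: np.ndarray

    def __post_init__(self):
        self.AtW = np.asarray(self.AtW, dtype=float)
        if self.AtW.ndim != 2 or self.AtW.shape[0] != self.AtW.shape[1]:
            raise ValueError("attention weights must be a square matrix")


def project_qkv(inp: AttentionInput):
    """Linear query/key/value projections of the token matrix."""
    return inp.M @ inp.Wq, inp.M @ inp.Wk, inp.M @ inp.Wv


def attention_scores(Aq: np.ndarray, Ak: np.ndarray, dk: int) -> np.ndarray:
    """Scaled dot products Aq·Ak^T / sqrt(dk)."""
    Aq, Ak = np.asarray(Aq, dtype=float), np.asarray(Ak, dtype=float)
    if dk <= 0:
        raise ValueError("dk must be positive")
    if Aq.shape != Ak.shape:
        raise ValueError("queries and keys must have identical shape")
    return Aq @ Ak.T / np.sqrt(dk)


def attention_weights(AtS: np.ndarray) -> AttentionWeights:
    """Row-wise softmax of the score matrix (log-sum-exp stabilized)."""
    AtS = np.asarray(AtS, dtype=float)
    z = AtS - AtS.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return AttentionWeights(e / e.sum(axis=-1, keepdims=True))


def attend(w: AttentionWeights, Av: np.ndarray) -> np.ndarray:
    """Weighted sum of values: each output row is a convex combination of Av rows."""
    Av = np.asarray(Av, dtype=float)
    if w.AtW.shape[1] != Av.shape[0]:
        raise ValueError("weight columns must match value rows")
    return w.AtW @ Av


def self_attention(inp: AttentionInput) -> np.ndarray:
    """The full single-head pipeline: project, score, softmax, weighted sum."""
    Aq, Ak, Av = project_qkv(inp)
    AtS = attention_scores(Aq, Ak, inp.Wq.shape[1])
    return attend(attention_weights(AtS), Av)


def multi_head_attention(M: np.ndarray, heads: int, Wq: np.ndarray,
                         Wk: np.ndarray, Wv: np.ndarray,
                         Wo: np.ndarray) -> np.ndarray:
    """Multi-head self-attention with concatenated head outputs.

    The n×n projection matrices are split column-wise into ``heads``
    blocks of width n/heads; head h attends with its own dk = n/heads
    slice, the outputs are concatenated back to width n, and one output
    projection Wo (n×n) mixes the heads.
    """
    M = np.asarray(M, dtype=float)
    n = M.shape[1]
    if n % heads:
        raise ValueError(f"embedding dim {n} not divisible by {heads} heads")
    dk = n // heads
    outs = []
    for h in range(heads):
        sl = slice(h * dk, (h + 1) * dk)
        outs.append(self_attention(
            AttentionInput(M, Wq[:, sl], Wk[:, sl], Wv[:, sl])))
    return np.concatenate(outs, axis=1) @ Wo
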