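"""Minimal dense-network machinery (forward, backward, Adam) in NumPy.

Everything here is deterministic given a Generator: initialization, batch
order and dropout masks all draw from the caller's stream, so training is
bit-reproducible in single-threaded mode.
"""

from __future__ import annotations

import numpy as np

NEG_INF = -1e30  # finite stand-in for -inf in masked attention scores


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)  # dtype-preserving
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softmax(s: np.ndarray, axis: int = -1) -> np.ndarray:
    # dtype-preserving (training runs in float32, inference in float64)
    m = s.max(axis=axis, keepdims=True)
    e = np.exp(s - m)
    return e / e.sum(axis=axis, keepdims=True)


def fast_auc(y: np.ndarray, scores: np.ndarray) -> float:
    """Rank-based AUC without input validation (inner-loop use)."""
    order = np.argsort(scores, kind="mergesort")
    y = np.asarray(y)[order]
    s = np.asarray(scores)[order]
    ranks = np.empty(len(s))
    i = 0
    while i < len(s):
        j = i
        while j + 1 < len(s) and s[j + 1] == s[i]:
            j += 1
        ranks[i:j + 1] = 0.5 * (i + j) + 1.0
        i = j + 1
    n1 = y.sum()
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes")
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def bce_loss(p: np.ndarray, y: np.ndarray, eps: float = 1e-12) -> float:
    p = np.clip(p, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def init_dense(rng: np.random.Generator, dims: list[int]) -> list[dict]:
    """He-scaled layers [{'W','b'}, ...] for a ReLU stack ending linear."""
    layers = []
    for d_in, d_out in zip(dims[:-1], dims[1:]):
        W = rng.standard_normal((d_in, d_out)) * np.sqrt(2.0 / d_in)
        layers.append({"W": W, "b": np.zeros(d_out)})
    return layers


def stack_forward(layers: list[dict], x: np.ndarray, dropout: float = 0.0,
                  rng: np.random.Generator | None = None, train: bool = False):
    """ReLU stack with linear last layer; inverted dropout on hidden units.

    ``x`` may have any leading shape; the last axis is the feature axis.
    Returns (output, cache) where cache holds what backward needs.
    """
    cache = {"inputs": [], "masks": [], "pre": []}
    a = x
    last = len(layers) - 1
    for i, layer in enumerate(layers):
        cache["inputs"].append(a)
        z = a @ layer["W"] + layer["b"]
        if i == last:
            cache["pre"].append(z)
            cache["masks"].append(None)
            a = z
        else:
            h = np.maximum(z, 0.0)
            cache["pre"].append(z)
            if train and dropout > 0.0:
                mask = ((rng.random(h.shape) >= dropout)
                        / (1.0 - dropout)).astype(h.dtype)
                h = h * mask
            else:
                mask = None
            cache["masks"].append(mask)
            a = h
    return a, cache


def stack_backward(layers: list[dict], cache: dict, dout: np.ndarray):
    """Gradient of the stack; returns (grads, d_input).

    Leading axes are treated as batch axes (summed into parameter grads).
    """
    grads = [None] * len(layers)
    da = dout
    last = len(layers) - 1
    for i in range(last, -1, -1):
        if i != last:
            mask = cache["masks"][i]
            if mask is not None:
                da = da * mask
            da = da * (cache["pre"][i] > 0)
        a_in = cache["inputs"][i]
        a2 = a_in.reshape(-1, a_in.shape[-1])
        d2 = da.reshape(-1, da.shape[-1])
        grads[i] = {"W": a2.T @ d2, "b": d2.sum(axis=0)}
        da = da @ layers[i]["W"].T
    return grads, da


def flatten_params(tree) -> list[np.ndarray]:
    """Depth-first list of arrays in a nested dict/list parameter tree."""
    if isinstance(tree, np.ndarray):
        return [tree]
    if isinstance(tree, dict):
        return [a for k in sorted(tree) for a in flatten_params(tree[k])]
    if isinstance(tree, (list, tuple)):
        return [a for t in tree for a in flatten_params(t)]
    raise TypeError(f"unsupported tree node {type(tree)}")


class Adam:
    """Adam with decoupled weight decay (AdamW) over a flat list of
    parameter arrays, updated in place."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1 ** self.t
        c2 = 1.0 - b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            if self.weight_decay and p.ndim > 1:  # decay weights, not biases
                p *= 1.0 - self.lr * self.weight_decay
            p -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)


def copy_tree(tree):
    if isinstance(tree, np.ndarray):
        return tree.copy()
    if isinstance(tree, dict):
        return {k: copy_tree(v) for k, v in tree.items()}
    if isinstance(tree, (list, tuple)):
        return [copy_tree(t) for t in tree]
    raise TypeError(f"unsupported tree node {type(tree)}")


def tree_astype(tree, dtype):
    if isinstance(tree, np.ndarray):
        return tree.astype(dtype)
    if isinstance(tree, dict):
        return {k: tree_astype(v, dtype) for k, v in tree.items()}
    if isinstance(tree, (list, tuple)):
        return [tree_astype(t, dtype) for t in tree]
    raise TypeError(f"unsupported tree node {type(tree)}")
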