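"""Minimal feed-forward network: input -> hidden -> 1, logistic units.

Trained by online stochastic gradient descent on squared error.  The
network is deliberately tiny and self-contained: reproducibility (same
seed, same data order => bit-identical weights) matters more here than
raw throughput, and the whole parameter set fits comfortably in a JSON
file for serialization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

DEFAULT_N_HIDDEN = 40
DEFAULT_WEIGHT_RANGE = 0.1


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


@dataclass
class Network:
    """Weights and metadata of one feed-forward net."""

    w1: np.ndarray  # (input_len, n_hidden)
    b1: np.ndarray  # (n_hidden,)
    w2: np.ndarray  # (n_hidden,)
    b2: float
    scheme: str = "sparse"
    seed: int = 0

    @property
    def input_len(self) -> int:
        return self.w1.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.w1.shape[1]


def init_network(
    input_len: int,
    n_hidden: int = DEFAULT_N_HIDDEN,
    seed: int = 0,
    weight_range: float = DEFAULT_WEIGHT_RANGE,
    scheme: str = "sparse",
    rng: np.random.Generator | None = None,
) -> Network:
    """Uniform random weights in [-weight_range, weight_range], seeded.

    If ``rng`` is given it is used directly (and ``seed`` is recorded as
    metadata only); otherwise a fresh generator is seeded from ``seed``.
    Same seed, same dims -> identical network.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    w0 = weight_range
    return Network(
        w1=rng.uniform(-w0, w0, size=(input_len, n_hidden)),
        b1=rng.uniform(-w0, w0, size=n_hidden),
        w2=rng.uniform(-w0, w0, size=n_hidden),
        b2=float(rng.uniform(-w0, w0)),
        scheme=scheme,
        seed=seed,
    )


def forward(net: Network, x: np.ndarray) -> float:
    """o = sigma(w2 . sigma(w1^T x + b1) + b2), strictly inside (0, 1)."""
    h = _sigmoid(x @ net.w1 + net.b1)
    return float(_sigmoid(h @ net.w2 + net.b2))


def forward_batch(net: Network, X: np.ndarray) -> np.ndarray:
    """forward() over the rows of X in one shot."""
    H = _sigmoid(X @ net.w1 + net.b1)
    return _sigmoid(H @ net.w2 + net.b2)


def gradients(net: Network, x: np.ndarray, target: float):
    """Backprop gradients of e = 0.5*(forward(net, x) - target)^2.

    Returns (gw1, gb1, gw2, gb2) matching the parameter shapes.
    """
    h = _sigmoid(x @ net.w1 + net.b1)
    o = float(_sigmoid(h @ net.w2 + net.b2))
    do = (o - target) * o * (1.0 - o)
    gb2 = do
    gw2 = do * h
    dh = do * net.w2 * h * (1.0 - h)
    gw1 = np.outer(x, dh)
    gb1 = dh
    return gw1, gb1, gw2, gb2


def sgd_update(net: Network, x: np.ndarray, target: float, learning_rate: float) -> Network:
    """One online gradient step, in place; returns the same Network.

    Raises if the gradient is non-finite (exploding step size).
    """
    if not 0.0 <= target <= 1.0:
        raise ValueError(f"target must be in [0, 1], got {target}")
    gw1, gb1, gw2, gb2 = gradients(net, x, target)
    if not np.isfinite(gb2) or not np.all(np.isfinite(gw1)):
        raise FloatingPointError("non-finite gradient; reduce the learning rate")
    net.w1 -= learning_rate * gw1
    net.b1 -= learning_rate * gb1
    net.w2 -= learning_rate * gw2
    net.b2 -= learning_rate * gb2
    return net


def save_network(net: Network, path) -> None:
    """Serialize to a self-describing JSON file at full precision."""
    payload = {
        "format": "panbind-network-v1",
        "input_len": net.input_len,
        "n_hidden": net.n_hidden,
        "scheme": net.scheme,
        "seed": net.seed,
        "w1": net.w1.tolist(),
        "b1": net.b1.tolist(),
        "w2": net.w2.tolist(),
        "b2": net.b2,
    }
    Path(path).write_text(json.dumps(payload))


def load_network(path) -> Network:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "panbind-network-v1":
        raise ValueError(f"{path}: not a panbind network file")
    net = Network(
        w1=np.asarray(payload["w1"], dtype=float),
        b1=np.asarray(payload["b1"], dtype=float),
        w2=np.asarray(payload["w2"], dtype=float),
        b2=float(payload["b2"]),
        scheme=payload["scheme"],
        seed=int(payload["seed"]),
    )
    if net.w1.shape != (payload["input_len"], payload["n_hidden"]):
        raise ValueError(f"{path}: inconsistent dimensions")
    return net
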