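"""Attention-based deep MIL model and its backbones.

A bag of K patch instances is pushed through a CNN backbone one batch at a
time, yielding instance feature vectors ``h_k`` (length L).  The attention
layer scores each instance with a two-layer network,

    a_k = softmax_k( w^T tanh(V h_k) ),        z = sum_k a_k h_k,

and the weighted bag representation ``z`` goes to a single sigmoid neuron for
the benign/malignant decision.  The attention weights ``a_k`` double as the
interpretability signal rendered by :mod:`admil_cyto.viz`.

The conventional-MIL baseline replaces attention with an unweighted mean of
the ``h_k``; the supervised baseline classifies instances individually with a
two-way softmax head.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .nn import (AdaptiveAvgPool, AvgPool2, Conv2d, Dense, DenseBlock,
                 Flatten, InceptionBlock, MaxPool2, Param, ReLU,
                 ResidualBlock, Sequential)

F32 = np.float32

BACKBONE_NAMES = ("lenet_like", "alexnet_like", "inception_like",
                  "resnet_like", "densenet_like")

#: feature-vector length L and attention hidden width D
DEFAULT_L = 500
DEFAULT_D = 128


# ---------------------------------------------------------------------------
# pure pooling / head math (also used directly by tests)

def attention_pool(H: np.ndarray, V: np.ndarray, w: np.ndarray):
    """Attention-weighted pooling of instance features.

    Parameters
    ----------
    H : (K, L) instance feature vectors.
    V : (D, L) first attention layer.
    w : (D,) scoring vector.

    Returns
    -------
    z : (L,) weighted bag feature, ``sum_k a_k h_k``.
    a : (K,) attention weights, softmax-normalised to sum to 1.
    """
    H = np.asarray(H, dtype=np.float64)
    if H.ndim != 2 or H.shape[0] < 1:
        raise ValueError("attention_pool requires a non-empty (K, L) feature matrix")
    t = np.tanh(H @ np.asarray(V, dtype=np.float64).T)      # (K, D)
    logits = t @ np.asarray(w, dtype=np.float64)            # (K,)
    e = np.exp(logits - logits.max())
    a = e / e.sum()
    z = a @ H
    return z, a


def mean_pool(H: np.ndarray) -> np.ndarray:
    """Unweighted average of instance features (conventional MIL pooling)."""
    H = np.asarray(H, dtype=np.float64)
    if H.ndim != 2 or H.shape[0] < 1:
        raise ValueError("mean_pool requires a non-empty (K, L) feature matrix")
    return H.mean(axis=0)


def classify_bag(z: np.ndarray, u: np.ndarray, b: float) -> float:
    """Sigmoid of the single-neuron bag head: P(malignant) = sigma(u.z + b)."""
    s = float(np.asarray(u, dtype=np.float64) @ np.asarray(z, dtype=np.float64) + b)
    return 1.0 / (1.0 + np.exp(-s))


# ---------------------------------------------------------------------------
# prediction record

@dataclass
class BagPrediction:
    """Outcome of classifying one bag (one case)."""

    case_id: str
    probability: float
    attention_weights: np.ndarray | None  # (K,), sums to 1; None for mean pooling

    @property
    def predicted_label(self) -> str:
        return "malignant" if self.probability >= 0.5 else "benign"


# ---------------------------------------------------------------------------
# backbones

@dataclass(frozen=True)
class BackboneSpec:
    name: str
    input_size: int = 64
    feature_dim: int = DEFAULT_L

    def __post_init__(self):
        if self.name not in BACKBONE_NAMES:
            raise ValueError(f"unknown backbone {self.name!r}; choose from {BACKBONE_NAMES}")


def build_backbone(spec: BackboneSpec, rng: np.random.Generator) -> Sequential:
    """Construct one of the five desk-scale CNN families.

    Every variant accepts 64/96/128-px RGB patches (adaptive 4x4 average
    pooling before the FC absorbs the spatial size) and emits an L-dim
    ReLU feature vector.
    """
    L = spec.feature_dim
    n = spec.name
    if n == "lenet_like":
        body = [Conv2d(3, 20, 5, rng=rng), ReLU(), MaxPool2(),
                Conv2d(20, 50, 5, rng=rng), ReLU(), MaxPool2()]
        ch = 50
    elif n == "alexnet_like":
        body = [Conv2d(3, 32, 3, pad=1, rng=rng), ReLU(), MaxPool2(),
                Conv2d(32, 64, 3, pad=1, rng=rng), ReLU(), MaxPool2(),
                Conv2d(64, 96, 3, pad=1, rng=rng), ReLU(),
                Conv2d(96, 96, 3, pad=1, rng=rng), ReLU(),
                Conv2d(96, 64, 3, pad=1, rng=rng), ReLU(), MaxPool2()]
        ch = 64
    elif n == "inception_like":
        b1 = InceptionBlock(32, 8, 8, 16, 4, 8, 8, rng=rng)
        b2 = InceptionBlock(b1.cout, 12, 12, 24, 6, 12, 12, rng=rng)
        body = [Conv2d(3, 16, 3, pad=1, rng=rng), ReLU(), MaxPool2(),
                Conv2d(16, 32, 3, pad=1, rng=rng), ReLU(), MaxPool2(),
                b1, MaxPool2(), b2]
        ch = b2.cout
    elif n == "resnet_like":
        body = [Conv2d(3, 16, 3, pad=1, rng=rng), ReLU(), MaxPool2(),
                ResidualBlock(16, 16, rng=rng), MaxPool2(),
                ResidualBlock(16, 32, rng=rng), MaxPool2(),
                ResidualBlock(32, 32, rng=rng)]
        ch = 32
    elif n == "densenet_like":
        d1 = DenseBlock(16, 12, 2, rng=rng)
        d2 = DenseBlock(d1.cout // 2, 12, 2, rng=rng)
        body = [Conv2d(3, 16, 3, pad=1, rng=rng), ReLU(), MaxPool2(),
                d1,
                Conv2d(d1.cout, d1.cout // 2, 1, rng=rng), ReLU(), AvgPool2(),
                d2]
        ch = d2.cout
    else:  # pragma: no cover - guarded by BackboneSpec
        raise ValueError(n)
    return Sequential(*body, AdaptiveAvgPool(4), Flatten(),
                      Dense(ch * 16, L, rng=rng), ReLU())


# ---------------------------------------------------------------------------
# attention layer (trainable)

class AttentionLayer:
    """Trainable attention pooling; forward math shared with attention_pool."""

    def __init__(self, L: int, D: int, rng: np.random.Generator):
        self.V = Param(rng.normal(0.0, np.sqrt(1.0 / L), size=(D, L)))
        self.w = Param(rng.normal(0.0, np.sqrt(1.0 / D), size=(D,)))

    def params(self):
        return [self.V, self.w]

    def forward(self, H: np.ndarray):
        t = np.tanh(H @ self.V.v.T)
        logits = t @ self.w.v
        e = np.exp(logits - logits.max())
        a = (e / e.sum()).astype(F32)
        z = a @ H
        self._H, self._t, self._a = H, t, a
        return z, a

    def backward(self, gz: np.ndarray) -> np.ndarray:
        H, t, a = self._H, self._t, self._a
        ga = H @ gz                                  # (K,)
        gH = np.outer(a, gz).astype(F32)
        dlog = (a * (ga - a @ ga)).astype(F32)       # softmax Jacobian
        self.w.g += t.T @ dlog
        gpre = np.outer(dlog, self.w.v) * (1.0 - t * t)
        self.V.g += gpre.T.astype(F32) @ H
        gH += (gpre @ self.V.v).astype(F32)
        self._H = self._t = self._a = None
        return gH


# ---------------------------------------------------------------------------
# full models

def _check_bag_input(x: np.ndarray, input_size: int) -> np.ndarray:
    x = np.asarray(x, dtype=F32)
    if x.ndim != 4 or x.shape[1] != 3:
        raise ValueError("expected instances as a (K, 3, S, S) array")
    if x.shape[2] != input_size or x.shape[3] != input_size:
        raise ValueError(f"instance size {x.shape[2]}x{x.shape[3]} does not match "
                         f"backbone input size {input_size}")
    return x


class ADMILModel:
    """Backbone + attention pooling + single sigmoid neuron."""

    regime = "admil"

    def __init__(self, spec: BackboneSpec, D: int = DEFAULT_D, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.spec = spec
        self.D = D
        self.backbone = build_backbone(spec, rng)
        self.attention = AttentionLayer(spec.feature_dim, D, rng)
        self.head = Dense(spec.feature_dim, 1, rng=rng)

    def params(self):
        return self.backbone.params() + self.attention.params() + self.head.params()

    def forward_bag(self, x: np.ndarray, train: bool = False):
        """Return (probability, attention weights, logit) for one bag."""
        x = _check_bag_input(x, self.spec.input_size)
        H = self.backbone.forward(x, train=train)
        z, a = self.attention.forward(H)
        logit = float(self.head.forward(z[None, :], train=train)[0, 0])
        p = 1.0 / (1.0 + np.exp(-logit))
        return p, a, logit

    def backward_bag(self, p: float, y: float) -> None:
        dlogit = np.array([[p - y]], dtype=F32)
        gz = self.head.backward(dlogit)[0]
        gH = self.attention.backward(gz)
        self.backbone.backward(gH)


class MeanMILModel:
    """Backbone + unweighted mean pooling + single sigmoid neuron."""

    regime = "mean_mil"

    def __init__(self, spec: BackboneSpec, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.spec = spec
        self.backbone = build_backbone(spec, rng)
        self.head = Dense(spec.feature_dim, 1, rng=rng)

    def params(self):
        return self.backbone.params() + self.head.params()

    def forward_bag(self, x: np.ndarray, train: bool = False):
        x = _check_bag_input(x, self.spec.input_size)
        H = self.backbone.forward(x, train=train)
        self._K = H.shape[0]
        z = H.mean(axis=0)
        logit = float(self.head.forward(z[None, :], train=train)[0, 0])
        p = 1.0 / (1.0 + np.exp(-logit))
        return p, None, logit

    def backward_bag(self, p: float, y: float) -> None:
        dlogit = np.array([[p - y]], dtype=F32)
        gz = self.head.backward(dlogit)[0]
        gH = np.broadcast_to(gz / self._K, (self._K, gz.shape[0])).astype(F32)
        self.backbone.backward(gH)


class SupervisedModel:
    """Backbone + extra FC layer + two-way softmax over instances."""

    regime = "supervised"

    def __init__(self, spec: BackboneSpec, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.spec = spec
        self.backbone = build_backbone(spec, rng)
        self.head = Dense(spec.feature_dim, 2, rng=rng)

    def params(self):
        return self.backbone.params() + self.head.params()

    def forward_batch(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Softmax class probabilities, shape (N, 2); column 1 = malignant."""
        x = _check_bag_input(x, self.spec.input_size)
        H = self.backbone.forward(x, train=train)
        logits = self.head.forward(H, train=train)
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)

    def backward_batch(self, probs: np.ndarray, y: np.ndarray) -> None:
        n = probs.shape[0]
        g = probs.astype(F32).copy()
        g[np.arange(n), y.astype(int)] -= 1.0
        g /= F32(n)
        gH = self.head.backward(g)
        self.backbone.backward(gH)


def build_model(regime: str, spec: BackboneSpec, seed: int = 0, D: int = DEFAULT_D):
    if regime == "admil":
        return ADMILModel(spec, D=D, seed=seed)
    if regime == "mean_mil":
        return MeanMILModel(spec, seed=seed)
    if regime == "supervised":
        return SupervisedModel(spec, seed=seed)
    raise ValueError(f"unknown regime {regime!r}")


# ---------------------------------------------------------------------------
# checkpoints

def get_state(model) -> list[np.ndarray]:
    return [p.v.copy() for p in model.params()]


def set_state(model, state: Sequence[np.ndarray]) -> None:
    ps = model.params()
    if len(ps) != len(state):
        raise ValueError("state does not match model parameter count")
    for p, s in zip(ps, state):
        p.v[...] = s


@dataclass
class Checkpoint:
    """A trained model's weights plus everything needed to re-run it."""

    regime: str
    backbone: str
    input_size: int
    feature_dim: int
    attention_dim: int | None
    patch_size: int
    state: list[np.ndarray]
    history: list[dict] = field(default_factory=list)

    def build(self):
        spec = BackboneSpec(self.backbone, input_size=self.input_size,
                            feature_dim=self.feature_dim)
        model = build_model(self.regime, spec, seed=0,
                            D=self.attention_dim or DEFAULT_D)
        set_state(model, self.state)
        return model

    def save(self, path) -> None:
        meta = dict(regime=self.regime, backbone=self.backbone,
                    input_size=self.input_size, feature_dim=self.feature_dim,
                    attention_dim=self.attention_dim, patch_size=self.patch_size,
                    history=self.history)
        arrays = {f"p{i}": a for i, a in enumerate(self.state)}
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "Checkpoint":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            state = [z[f"p{i}"] for i in range(len(z.files) - 1)]
        return cls(regime=meta["regime"], backbone=meta["backbone"],
                   input_size=meta["input_size"], feature_dim=meta["feature_dim"],
                   attention_dim=meta["attention_dim"], patch_size=meta["patch_size"],
                   state=state, history=meta.get("history", []))
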