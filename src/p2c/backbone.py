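"""Densely connected convolutional feature extractor with RMSProp training.

The extractor follows the DenseNet design: four dense blocks in which every
sub-block (a 1x1 bottleneck conv producing ``4k`` channels followed by a 3x3
conv producing ``k`` channels, each preceded by batch-norm + ReLU) receives
the concatenation of all earlier feature maps in its block, separated by
transition layers that compress ``m`` channels to ``floor(theta * m)`` and
halve the spatial resolution.  The reference profile uses block sizes
(6, 12, 36, 24) with growth rate k=48 — 2*(6+12+36+24) = 156 convolutions
inside sub-blocks — while the default desk-scale profile is (2, 2, 2, 2) with
k=12 on 64x64 inputs.  Global average pooling of the last block's maps yields
the feature vector consumed by the downstream classifier.

Training attaches a temporary dropout + linear classification head and
minimizes cross-entropy with a from-scratch RMSProp optimizer:

    G_t      = beta * G_{t-1} + (1 - beta) * g_t (.) g_t
    dtheta_t = -alpha * g_t / sqrt(G_t + eps)

with decay ``beta = 0.9``, learning rate ``alpha = 0.01`` and stabilizer
``eps = 1e-8`` by default.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, replace

import numpy as np

from .nn import (
    AvgPool2d, BatchNorm2d, Conv2d, Dropout, GlobalAvgPool, Linear, ReLU,
    softmax_cross_entropy,
)

__all__ = [
    "DenseNetConfig", "RMSPropState", "transition_channels", "rmsprop_step",
    "build_backbone", "train_backbone", "extract_features", "DenseNetModel",
    "SMALL_PROFILE", "DENSENET161_PROFILE",
]


@dataclass(frozen=True)
class DenseNetConfig:
    """Architecture hyperparameters.

    ``block_layers`` gives the number of sub-blocks per dense block;
    ``growth_rate`` (k) is the channel increment each sub-block contributes;
    ``compression`` (theta in (0, 1]) scales channel counts at transitions.
    Input height/width must be multiples of the total downsampling factor, 32.
    """

    block_layers: tuple[int, int, int, int] = (2, 2, 2, 2)
    growth_rate: int = 12
    compression: float = 0.5
    input_size: tuple[int, int] = (64, 64)
    n_classes: int = 2
    bottleneck_mult: int = 4

    def __post_init__(self):
        if len(self.block_layers) != 4 or any(l < 1 for l in self.block_layers):
            raise ValueError("block_layers must be 4 positive integers")
        if not 0.0 < self.compression <= 1.0:
            raise ValueError(f"compression must be in (0, 1], got {self.compression}")
        if self.growth_rate < 1:
            raise ValueError("growth_rate must be positive")


SMALL_PROFILE = DenseNetConfig()
DENSENET161_PROFILE = DenseNetConfig(
    block_layers=(6, 12, 36, 24), growth_rate=48, input_size=(224, 224)
)

_DOWNSAMPLE = 32  # stem conv (2) * stem pool (2) * three transition pools (8)


def transition_channels(m: int, theta: float) -> int:
    """Channel count after a transition layer: ``floor(theta * m)``, >= 1."""
    if m < 1:
        raise ValueError(f"channel count must be >= 1, got {m}")
    if not 0.0 < theta <= 1.0:
        raise ValueError(f"compression factor must be in (0, 1], got {theta}")
    return max(1, int(np.floor(theta * m)))


# ---------------------------------------------------------------------------
# RMSProp
# ---------------------------------------------------------------------------

@dataclass
class RMSPropState:
    """Squared-gradient moving average ``G`` plus the step hyperparameters.

    ``G`` mirrors the structure of the parameters (scalar/array, or a dict of
    arrays) and is created lazily on the first step.
    """

    alpha: float = 0.01
    beta: float = 0.9
    eps: float = 1e-8
    G: object = None

    def __post_init__(self):
        if not 0.0 <= self.beta < 1.0:
            raise ValueError(f"decay beta must be in [0, 1), got {self.beta}")
        if self.alpha <= 0:
            raise ValueError("learning rate alpha must be positive")
        if self.eps < 0:
            raise ValueError("eps must be non-negative")


def _rms_single(state: RMSPropState, G, p, g, name: str):
    g = np.asarray(g, dtype=np.float64) if np.ndim(g) else float(g)
    if not np.all(np.isfinite(g)):
        raise ValueError(f"non-finite gradient in parameter block '{name}'")
    if G is None:
        G = np.zeros_like(g) if np.ndim(g) else 0.0
    G_new = state.beta * G + (1.0 - state.beta) * g * g
    delta = -state.alpha * g / np.sqrt(G_new + state.eps)
    return G_new, p + delta


def rmsprop_step(state: RMSPropState, params, grads):
    """One RMSProp update; returns ``(new_state, new_params)``.

    ``params``/``grads`` may be scalars, arrays, or dicts of arrays keyed the
    same way.  A non-finite gradient raises, naming the offending block.
    """
    if isinstance(params, dict):
        if set(params) != set(grads):
            raise ValueError("params and grads must share keys")
        G = state.G if isinstance(state.G, dict) else {}
        G_new, p_new = {}, {}
        for k in params:
            G_new[k], p_new[k] = _rms_single(state, G.get(k), params[k], grads[k], k)
        return replace(state, G=G_new), p_new
    G_new, p_new = _rms_single(state, state.G, params, grads, "params")
    return replace(state, G=G_new), p_new


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class _DenseLayer:
    """BN-ReLU-conv1x1(4k) -> BN-ReLU-conv3x3(k), pre-activation ordering."""

    def __init__(self, in_c: int, k: int, bottleneck_mult: int, rng):
        bc = bottleneck_mult * k
        self.mods = OrderedDict(
            bn1=BatchNorm2d(in_c), relu1=ReLU(),
            conv1=Conv2d(in_c, bc, 1, rng=rng),
            bn2=BatchNorm2d(bc), relu2=ReLU(),
            conv2=Conv2d(bc, k, 3, pad=1, rng=rng),
        )

    def forward(self, x, training):
        for m in self.mods.values():
            x = m.forward(x, training)
        return x

    def backward(self, dout):
        for m in reversed(self.mods.values()):
            dout = m.backward(dout)
        return dout


class _DenseBlock:
    def __init__(self, in_c: int, n_layers: int, k: int, bottleneck_mult: int, rng):
        self.k = k
        self.layers = [
            _DenseLayer(in_c + i * k, k, bottleneck_mult, rng) for i in range(n_layers)
        ]
        self.in_c = in_c
        self.out_c = in_c + n_layers * k

    def forward(self, x, training):
        feats = [x]
        for layer in self.layers:
            feats.append(layer.forward(np.concatenate(feats, axis=1), training))
        self._sizes = [f.shape[1] for f in feats]
        return np.concatenate(feats, axis=1)

    def backward(self, dout):
        bounds = np.cumsum(self._sizes)[:-1]
        dfeats = list(np.split(dout, bounds, axis=1))
        for j in range(len(self.layers) - 1, -1, -1):
            dinp = self.layers[j].backward(dfeats[j + 1])
            for i, piece in enumerate(np.split(dinp, np.cumsum(self._sizes[: j + 1])[:-1], axis=1)):
                dfeats[i] = dfeats[i] + piece
        return dfeats[0]


class _Transition:
    def __init__(self, in_c: int, theta: float, rng):
        self.out_c = transition_channels(in_c, theta)
        self.mods = OrderedDict(
            bn=BatchNorm2d(in_c), relu=ReLU(),
            conv=Conv2d(in_c, self.out_c, 1, rng=rng), pool=AvgPool2d(),
        )

    def forward(self, x, training):
        for m in self.mods.values():
            x = m.forward(x, training)
        return x

    def backward(self, dout):
        for m in reversed(self.mods.values()):
            dout = m.backward(dout)
        return dout


class DenseNetModel:
    """Built network: stem, dense blocks, transitions, pooled feature head."""

    def __init__(self, cfg: DenseNetConfig, seed: int = 0):
        h, w = cfg.input_size
        if h < _DOWNSAMPLE or w < _DOWNSAMPLE or h % _DOWNSAMPLE or w % _DOWNSAMPLE:
            raise ValueError(
                f"input size {h}x{w} must be a multiple of the total "
                f"downsampling factor {_DOWNSAMPLE}"
            )
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        k = cfg.growth_rate
        c = 2 * k
        self.stem = OrderedDict(
            conv=Conv2d(1, c, 3, stride=2, pad=1, rng=rng),
            bn=BatchNorm2d(c), relu=ReLU(), pool=AvgPool2d(),
        )
        trace = [{"stage": "stem", "in": 1, "out": c}]
        self.blocks: list[_DenseBlock] = []
        self.transitions: list[_Transition] = []
        for bi, n_layers in enumerate(cfg.block_layers):
            block = _DenseBlock(c, n_layers, k, cfg.bottleneck_mult, rng)
            self.blocks.append(block)
            trace.append({"stage": f"block{bi + 1}", "in": c, "out": block.out_c})
            c = block.out_c
            if bi < 3:
                tr = _Transition(c, cfg.compression, rng)
                self.transitions.append(tr)
                trace.append({"stage": f"transition{bi + 1}", "in": c, "out": tr.out_c})
                c = tr.out_c
        self.final_bn = BatchNorm2d(c)
        self.final_relu = ReLU()
        self.gap = GlobalAvgPool()
        self.feature_dim = c
        self.dropout = Dropout(0.0)
        self.head = Linear(c, cfg.n_classes, rng=rng)
        self.description = {
            "block_layers": list(cfg.block_layers),
            "growth_rate": k,
            "compression": cfg.compression,
            "n_subblock_convs": 2 * sum(cfg.block_layers),
            "channel_trace": trace,
            "feature_dim": c,
            "total_downsample": _DOWNSAMPLE,
        }

    # -- module bookkeeping -------------------------------------------------
    def _named_modules(self):
        for name, m in self.stem.items():
            yield f"stem.{name}", m
        for bi, block in enumerate(self.blocks):
            for li, layer in enumerate(block.layers):
                for name, m in layer.mods.items():
                    yield f"block{bi + 1}.layer{li + 1}.{name}", m
            if bi < 3:
                for name, m in self.transitions[bi].mods.items():
                    yield f"transition{bi + 1}.{name}", m
        yield "final_bn", self.final_bn
        yield "head", self.head

    def parameters(self) -> OrderedDict:
        out = OrderedDict()
        for mname, m in self._named_modules():
            for pname, p in m.params.items():
                out[f"{mname}.{pname}"] = p
        return out

    def gradients(self) -> OrderedDict:
        out = OrderedDict()
        for mname, m in self._named_modules():
            for pname in m.params:
                out[f"{mname}.{pname}"] = m.grads[pname]
        return out

    def set_parameters(self, new: dict) -> None:
        for mname, m in self._named_modules():
            for pname in m.params:
                m.params[pname][...] = new[f"{mname}.{pname}"]

    # -- forward / backward -------------------------------------------------
    def features(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for m in self.stem.values():
            x = m.forward(x, training)
        for bi, block in enumerate(self.blocks):
            x = block.forward(x, training)
            if bi < 3:
                x = self.transitions[bi].forward(x, training)
        x = self.final_bn.forward(x, training)
        x = self.final_relu.forward(x, training)
        return self.gap.forward(x, training)

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        f = self.features(x, training)
        f = self.dropout.forward(f, training, rng)
        return self.head.forward(f, training)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        d = self.dropout.backward(d)
        d = self.gap.backward(d)
        d = self.final_relu.backward(d)
        d = self.final_bn.backward(d)
        for bi in range(3, -1, -1):
            if bi < 3:
                d = self.transitions[bi].backward(d)
            d = self.blocks[bi].backward(d)
        for m in reversed(self.stem.values()):
            d = m.backward(d)


def build_backbone(cfg: DenseNetConfig = SMALL_PROFILE, seed: int = 0) -> DenseNetModel:
    """Construct (and randomly initialize) the extractor for ``cfg``."""
    return DenseNetModel(cfg, seed=seed)


# ---------------------------------------------------------------------------
# Training / extraction
# ---------------------------------------------------------------------------

def _to_batch(images: np.ndarray) -> np.ndarray:
    """n x h x w intensities (8-bit or [0,1] float) -> NCHW float32 in [-1, 1]."""
    x = np.asarray(images, dtype=np.float32)
    if x.ndim != 3:
        raise ValueError(f"expected an n x h x w image stack, got shape {x.shape}")
    if x.max() > 1.0:
        x = x / 255.0
    return (x * 2.0 - 1.0)[:, None, :, :]


def train_backbone(model: DenseNetModel, images: np.ndarray, labels: np.ndarray,
                   rmsprop: RMSPropState | None = None, epochs: int = 50,
                   batch_size: int = 5, dropout: float = 0.5,
                   seed: int = 0) -> tuple[DenseNetModel, list[float]]:
    """Train with cross-entropy on a temporary head; RMSProp is the optimizer.

    Default settings follow the reference configuration (learning rate 0.01,
    dropout 0.5, batch size 5, 50 epochs); desk-scale callers pass fewer
    epochs.  Returns the model and the per-epoch mean training loss.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("training requires at least two classes in the labels")
    y = np.searchsorted(classes, labels)
    if epochs < 0:
        raise ValueError("epochs must be >= 0")
    if epochs == 0:
        return model, []

    x_all = _to_batch(images)
    state = rmsprop if rmsprop is not None else RMSPropState()
    model.dropout.p = dropout
    rng = np.random.default_rng(seed)
    history: list[float] = []
    n = x_all.shape[0]
    for _ in range(epochs):
        perm = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = perm[start : start + batch_size]
            logits = model.forward(x_all[idx], training=True, rng=rng)
            loss, dlogits = softmax_cross_entropy(logits, y[idx])
            model.backward(dlogits)
            params = model.parameters()
            state, new_params = rmsprop_step(state, dict(params), dict(model.gradients()))
            model.set_parameters(new_params)
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return model, history


def extract_features(model: DenseNetModel, images: np.ndarray,
                     batch_size: int = 32) -> np.ndarray:
    """Global-pooled penultimate activations, one row per input image."""
    images = np.asarray(images)
    if images.ndim == 3 and images.shape[0] == 0 or images.size == 0:
        raise ValueError("extract_features requires at least one image")
    x = _to_batch(images)
    rows = [
        model.features(x[i : i + batch_size], training=False)
        for i in range(0, x.shape[0], batch_size)
    ]
    return np.concatenate(rows, axis=0).astype(np.float64)
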