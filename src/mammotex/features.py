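"""Configurable convolutional feature hierarchy.

The texture statistics at the heart of the pipeline are Gram matrices of
feature-map activations, so the package needs a deterministic, seedable
feature hierarchy whose forward *and* reverse passes it fully controls.
This module implements one directly in numpy: same-padded convolutions,
ReLU, 2x2 average/max pooling and dense layers, with hand-derived
backpropagation for both pixel gradients (used by texture synthesis) and
weight gradients (used by the miniature fine-tuning loop).

The default "desk-scale" architecture (three 3x3 conv blocks separated by
2x2 average pools) is small enough to synthesize against on one CPU core in
seconds while still exposing a hierarchy of receptive-field sizes.  A
19-weight-layer VGG-style reference configuration ships under ``configs/``
for architecture parity; its pretrained weights are out of scope and it is
never needed at test time.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .exceptions import ConfigError, DegenerateDataError, InputError, ParameterError
from .phantoms import CLASS_LABELS
from .seeds import child_rng

__all__ = [
    "LayerSpec",
    "NetworkConfig",
    "Network",
    "FeatureStack",
    "desk_config",
    "build_network",
    "forward",
    "finetune_features",
    "classify",
    "load_network_config",
    "reference_config_path",
    "count_weight_layers",
]


@dataclass(frozen=True)
class LayerSpec:
    """One layer of the hierarchy.

    kind ``conv``: same-padded 2-D convolution, ``out_channels`` filters of
    odd ``kernel`` size, optional ReLU. kind ``pool``: 2x2 stride-2 pooling
    (``avg`` or ``max``); spatial dims floor-divide by 2. kind ``dense``:
    affine map on the flattened input, optional ReLU.
    """

    kind: str
    out_channels: int | None = None
    kernel: int | None = None
    activation: str = "relu"
    pool_mode: str = "avg"

    def __post_init__(self):
        if self.kind not in ("conv", "pool", "dense"):
            raise ConfigError(f"unknown layer kind {self.kind!r}")
        if self.kind in ("conv", "dense"):
            if self.out_channels is None or self.out_channels < 1:
                raise ConfigError(f"{self.kind} layer needs out_channels >= 1")
        if self.kind == "conv":
            if self.kernel is None or self.kernel < 1 or self.kernel % 2 == 0:
                raise ConfigError("conv kernel must be odd and >= 1")
        if self.activation not in ("relu", "none"):
            raise ConfigError(f"unknown activation {self.activation!r}")
        if self.kind == "pool" and self.pool_mode not in ("avg", "max"):
            raise ConfigError(f"unknown pool_mode {self.pool_mode!r}")


@dataclass(frozen=True)
class NetworkConfig:
    """An ordered stack of :class:`LayerSpec` plus weight seed and Gram layers.

    ``gram_layers`` are indices of layers whose outputs feed the Gram
    statistics; they must be spatial (conv or pool) outputs. ``padding``
    selects zero (default) or periodic boundary handling for convolutions —
    the periodic variant makes Gram sets exactly invariant to circular
    shifts and exists for validation.
    """

    layers: tuple[LayerSpec, ...]
    input_channels: int = 1
    weight_seed: int = 0
    gram_layers: tuple[int, ...] = ()
    padding: str = "zero"

    def __post_init__(self):
        object.__setattr__(self, "layers", tuple(self.layers))
        object.__setattr__(self, "gram_layers", tuple(self.gram_layers))
        if not self.layers:
            raise ConfigError("network needs at least one layer")
        if self.padding not in ("zero", "periodic"):
            raise ConfigError(f"unknown padding {self.padding!r}")
        first_dense = next(
            (i for i, l in enumerate(self.layers) if l.kind == "dense"), len(self.layers)
        )
        for gi in self.gram_layers:
            if not (0 <= gi < len(self.layers)):
                raise ConfigError(f"gram layer index {gi} out of range")
            if gi >= first_dense:
                raise ConfigError(
                    f"gram layer {gi} is not a spatial feature map (at/after dense layers)"
                )


def desk_config(weight_seed: int = 0, padding: str = "zero") -> NetworkConfig:
    """The default desk-scale net: conv3x3(8) -> avgpool -> conv3x3(16)
    -> avgpool -> conv3x3(32); Gram layers are the three ReLU outputs."""
    return NetworkConfig(
        layers=(
            LayerSpec("conv", out_channels=8, kernel=3),
            LayerSpec("pool", pool_mode="avg"),
            LayerSpec("conv", out_channels=16, kernel=3),
            LayerSpec("pool", pool_mode="avg"),
            LayerSpec("conv", out_channels=32, kernel=3),
        ),
        input_channels=1,
        weight_seed=weight_seed,
        gram_layers=(0, 2, 4),
        padding=padding,
    )


class Network:
    """A built network: config plus materialized conv weights.

    Conv weights are drawn at construction from a seeded Gaussian with
    std 1/sqrt(fan_in); dense weights are materialized lazily on first
    forward (their fan-in depends on the input resolution) from a stream
    keyed by (weight_seed, layer index), so they are equally deterministic.
    An optional linear classification ``head`` is attached by
    :func:`finetune_features`.
    """

    def __init__(self, config: NetworkConfig):
        self.config = config
        self.weights: list[dict | None] = []
        for i, spec in enumerate(config.layers):
            if spec.kind == "conv":
                in_ch = self._in_channels_at(i)
                fan_in = in_ch * spec.kernel * spec.kernel
                rng = child_rng(config.weight_seed, i)
                W = rng.standard_normal(
                    (spec.out_channels, in_ch, spec.kernel, spec.kernel)
                ) / np.sqrt(fan_in)
                self.weights.append({"W": W, "b": np.zeros(spec.out_channels)})
            else:
                self.weights.append(None)  # pool, or dense pending lazy init
        self.head: dict | None = None
        self.head_classes: tuple[str, ...] | None = None

    def _in_channels_at(self, index: int) -> int:
        ch = self.config.input_channels
        for spec in self.config.layers[:index]:
            if spec.kind in ("conv", "dense"):
                ch = spec.out_channels
        return ch

    @property
    def n_weight_layers(self) -> int:
        return count_weight_layers(self.config)

    def copy(self) -> "Network":
        return copy.deepcopy(self)


def count_weight_layers(config: NetworkConfig) -> int:
    """Number of weight-bearing (conv or dense) layers."""
    return sum(1 for l in config.layers if l.kind in ("conv", "dense"))


def build_network(config: NetworkConfig) -> Network:
    """Materialize a :class:`Network` from its config (seeded, deterministic)."""
    return Network(config)


# ---------------------------------------------------------------------------
# forward / backward primitives

def _pad(x, p, mode):
    if p == 0:
        return x
    np_mode = "wrap" if mode == "periodic" else "constant"
    return np.pad(x, ((0, 0), (p, p), (p, p)), mode=np_mode)


def _conv_forward(x, W, b, pad_mode):
    """Same-size convolution. x: (Cin,H,W); W: (Cout,Cin,k,k)."""
    k = W.shape[-1]
    p = k // 2
    xp = _pad(x, p, pad_mode)
    patches = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
    y = np.einsum("oikl,ihwkl->ohw", W, patches, optimize=True) + b[:, None, None]
    return y, patches


def _conv_backward(dy, x_shape, patches, W, pad_mode):
    """Gradients of a same-size conv wrt input, W and b."""
    k = W.shape[-1]
    p = k // 2
    _, H, Wd = x_shape
    dW = np.einsum("ohw,ihwkl->oikl", dy, patches, optimize=True)
    db = dy.sum(axis=(1, 2))
    dxp = np.zeros((x_shape[0], H + 2 * p, Wd + 2 * p))
    for dh in range(k):
        for dw in range(k):
            dxp[:, dh:dh + H, dw:dw + Wd] += np.einsum(
                "oi,ohw->ihw", W[:, :, dh, dw], dy, optimize=True
            )
    if p == 0:
        return dxp, dW, db
    if pad_mode == "periodic":
        # fold the padded borders back onto the opposite edges
        dx = dxp[:, p:-p, p:-p].copy()
        dx[:, :p, :] += dxp[:, H + p:, p:-p]
        dx[:, -p:, :] += dxp[:, :p, p:-p]
        dx[:, :, :p] += dxp[:, p:-p, Wd + p:]
        dx[:, :, -p:] += dxp[:, p:-p, :p]
        # corners
        dx[:, :p, :p] += dxp[:, H + p:, Wd + p:]
        dx[:, :p, -p:] += dxp[:, H + p:, :p]
        dx[:, -p:, :p] += dxp[:, :p, Wd + p:]
        dx[:, -p:, -p:] += dxp[:, :p, :p]
        return dx, dW, db
    return dxp[:, p:-p, p:-p], dW, db


def _pool_forward(x, mode):
    """2x2 stride-2 pooling; odd trailing row/col dropped (floor division)."""
    C, H, W = x.shape
    H2, W2 = H // 2, W // 2
    if H2 < 1 or W2 < 1:
        raise InputError("feature map too small to pool")
    xc = x[:, : 2 * H2, : 2 * W2]
    blocks = xc.reshape(C, H2, 2, W2, 2)
    if mode == "avg":
        return blocks.mean(axis=(2, 4)), None
    flat = blocks.transpose(0, 1, 3, 2, 4).reshape(C, H2, W2, 4)
    arg = flat.argmax(axis=3)
    return flat.max(axis=3), arg


def _pool_backward(dy, x_shape, mode, arg):
    C, H, W = x_shape
    H2, W2 = H // 2, W // 2
    dx = np.zeros(x_shape)
    if mode == "avg":
        q = dy / 4.0
        dx[:, 0:2 * H2:2, 0:2 * W2:2] = q
        dx[:, 1:2 * H2:2, 0:2 * W2:2] = q
        dx[:, 0:2 * H2:2, 1:2 * W2:2] = q
        dx[:, 1:2 * H2:2, 1:2 * W2:2] = q
        return dx
    dblocks = np.zeros((C, H2, W2, 4))
    np.put_along_axis(dblocks, arg[..., None], dy[..., None], axis=3)
    dx[:, : 2 * H2, : 2 * W2] = (
        dblocks.reshape(C, H2, W2, 2, 2).transpose(0, 1, 3, 2, 4).reshape(C, 2 * H2, 2 * W2)
    )
    return dx


@dataclass
class FeatureStack:
    """Per-layer feature maps (post-activation), in config order."""

    maps: list[np.ndarray]
    config: NetworkConfig

    def gram_maps(self):
        """(layer index, (N_l, M_l), flattened (N_l x M_l) map) per gram layer."""
        out = []
        for gi in self.config.gram_layers:
            fm = self.maps[gi]
            N = fm.shape[0]
            M = int(np.prod(fm.shape[1:]))
            out.append((gi, (N, M), fm.reshape(N, M)))
        return out


def _as_channels_first(network, image):
    img = np.asarray(image, dtype=float)
    if img.ndim == 2:
        img = img[None]
    if img.ndim != 3 or img.shape[0] != network.config.input_channels:
        raise InputError(
            f"expected {network.config.input_channels}-channel image, got shape {img.shape}"
        )
    return img


def _ensure_dense_weights(network, index, in_dim):
    spec = network.config.layers[index]
    w = network.weights[index]
    if w is None:
        rng = child_rng(network.config.weight_seed, index)
        W = rng.standard_normal((spec.out_channels, in_dim)) / np.sqrt(in_dim)
        w = {"W": W, "b": np.zeros(spec.out_channels)}
        network.weights[index] = w
    elif w["W"].shape[1] != in_dim:
        raise InputError(
            f"dense layer {index} was initialized for input dim {w['W'].shape[1]}, got {in_dim}"
        )
    return w


def _forward_cache(network: Network, image) -> tuple[FeatureStack, list]:
    """Forward pass keeping everything the reverse pass needs."""
    x = _as_channels_first(network, image)
    pad_mode = network.config.padding
    maps, caches = [], []
    for i, spec in enumerate(network.config.layers):
        if spec.kind == "conv":
            w = network.weights[i]
            pre, patches = _conv_forward(x, w["W"], w["b"], pad_mode)
            y = np.maximum(pre, 0.0) if spec.activation == "relu" else pre
            caches.append({"kind": "conv", "x_shape": x.shape, "patches": patches,
                           "pre": pre, "spec": spec, "index": i})
        elif spec.kind == "pool":
            y, arg = _pool_forward(x, spec.pool_mode)
            caches.append({"kind": "pool", "x_shape": x.shape, "arg": arg, "spec": spec})
        else:  # dense
            flat = x.reshape(-1)
            w = _ensure_dense_weights(network, i, flat.size)
            pre = w["W"] @ flat + w["b"]
            y = np.maximum(pre, 0.0) if spec.activation == "relu" else pre
            y = y[:, None, None]  # keep (C,1,1) layout for uniformity
            caches.append({"kind": "dense", "x_shape": x.shape, "flat": flat,
                           "pre": pre, "spec": spec, "index": i})
        maps.append(y)
        x = y
    return FeatureStack(maps=maps, config=network.config), caches


def forward(network: Network, image) -> FeatureStack:
    """Feed-forward pass; returns post-activation maps for every layer."""
    stack, _ = _forward_cache(network, image)
    return stack


def _backward(network: Network, caches, grads_by_layer: dict[int, np.ndarray],
              want_weight_grads: bool = False):
    """Reverse pass.  ``grads_by_layer`` maps layer index -> dL/d(output of
    that layer); returns (dL/dpixels, weight grads or None)."""
    pad_mode = network.config.padding
    n = len(caches)
    wgrads = [None] * n if want_weight_grads else None
    g = None
    for i in range(n - 1, -1, -1):
        cache = caches[i]
        spec = cache["spec"]
        out_grad = grads_by_layer.get(i)
        if g is None:
            if out_grad is None:
                continue
            g = out_grad.copy()
        elif out_grad is not None:
            g = g + out_grad
        if cache["kind"] == "conv":
            if spec.activation == "relu":
                g = g * (cache["pre"] > 0)
            w = network.weights[i]
            g, dW, db = _conv_backward(g, cache["x_shape"], cache["patches"],
                                       w["W"], pad_mode)
            if want_weight_grads:
                wgrads[i] = {"W": dW, "b": db}
        elif cache["kind"] == "pool":
            g = _pool_backward(g, cache["x_shape"], spec.pool_mode, cache["arg"])
        else:  # dense
            g = g.reshape(-1)
            if spec.activation == "relu":
                g = g * (cache["pre"] > 0)
            w = network.weights[i]
            if want_weight_grads:
                wgrads[i] = {"W": np.outer(g, cache["flat"]), "b": g.copy()}
            g = (w["W"].T @ g).reshape(cache["x_shape"])
    if g is None:
        # no injected gradient at all — zero gradient wrt the input
        g = np.zeros(caches[0]["x_shape"])
    return g, wgrads


# ---------------------------------------------------------------------------
# miniature fine-tuning

def _softmax(z):
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def _head_features(network, image):
    stack, caches = _forward_cache(network, image)
    last = stack.maps[-1]
    return last.reshape(-1), last.shape, caches


def finetune_features(network: Network, cohort, epochs: int, lr: float,
                      seed: int = 0) -> Network:
    """Fine-tune the hierarchy on labeled phantoms with a 4-way linear head.

    Full-batch gradient descent on the mean multinomial cross-entropy of a
    linear softmax head over the final feature layer; gradients are
    backpropagated into every conv (and dense) weight.  Returns a new
    Network carrying the updated weights and the trained head; the input
    network is left untouched.  Deterministic given ``seed``.
    """
    if epochs < 1:
        raise ParameterError("epochs must be >= 1")
    labels = sorted({ph.class_label for ph in cohort})
    if len(labels) < 2:
        raise DegenerateDataError("fine-tuning needs a cohort with >= 2 classes")
    classes = tuple(l for l in CLASS_LABELS if l in labels) or tuple(labels)
    class_index = {l: k for k, l in enumerate(classes)}

    net = network.copy()
    feat0, _, _ = _head_features(net, cohort[0].image)
    rng = child_rng(seed, 0)
    Wh = rng.standard_normal((len(classes), feat0.size)) / np.sqrt(feat0.size)
    bh = np.zeros(len(classes))

    n = len(cohort)
    for _epoch in range(epochs):
        gWh = np.zeros_like(Wh)
        gbh = np.zeros_like(bh)
        acc_wgrads = None
        for ph in cohort:
            feat, last_shape, caches = _head_features(net, ph.image)
            p = _softmax(Wh @ feat + bh)
            delta = p.copy()
            delta[class_index[ph.class_label]] -= 1.0  # dCE/dlogits
            gWh += np.outer(delta, feat) / n
            gbh += delta / n
            dlast = (Wh.T @ delta).reshape(last_shape)
            _, wg = _backward(net, caches, {len(caches) - 1: dlast},
                              want_weight_grads=True)
            if acc_wgrads is None:
                acc_wgrads = wg
            else:
                for a, b in zip(acc_wgrads, wg):
                    if a is not None:
                        a["W"] += b["W"]
                        a["b"] += b["b"]
        Wh -= lr * gWh
        bh -= lr * gbh
        for i, wg in enumerate(acc_wgrads):
            if wg is not None and net.weights[i] is not None:
                net.weights[i]["W"] -= lr * wg["W"] / n
                net.weights[i]["b"] -= lr * wg["b"] / n

    net.head = {"W": Wh, "b": bh}
    net.head_classes = classes
    return net


def classify(network: Network, image) -> str:
    """Predict the diagnostic class of an image with the fine-tuned head."""
    if network.head is None:
        raise InputError("network has no trained classification head")
    feat, _, _ = _head_features(network, image)
    logits = network.head["W"] @ feat + network.head["b"]
    return network.head_classes[int(np.argmax(logits))]


# ---------------------------------------------------------------------------
# configuration files

def load_network_config(path) -> NetworkConfig:
    """Read a network architecture from a YAML document."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "layers" not in doc:
        raise ConfigError(f"{path}: expected a mapping with a 'layers' list")
    layers = []
    for entry in doc["layers"]:
        if not isinstance(entry, dict) or "kind" not in entry:
            raise ConfigError(f"{path}: each layer needs a 'kind'")
        layers.append(LayerSpec(
            kind=entry["kind"],
            out_channels=entry.get("out_channels"),
            kernel=entry.get("kernel"),
            activation=entry.get("activation", "relu"),
            pool_mode=entry.get("pool_mode", "avg"),
        ))
    return NetworkConfig(
        layers=tuple(layers),
        input_channels=int(doc.get("input_channels", 1)),
        weight_seed=int(doc.get("weight_seed", 0)),
        gram_layers=tuple(doc.get("gram_layers", ())),
        padding=doc.get("padding", "zero"),
    )


def reference_config_path() -> Path:
    """Path of the shipped 19-weight-layer VGG-style reference config."""
    return Path(__file__).parent / "configs" / "vgg19.yaml"
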