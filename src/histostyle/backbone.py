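"""Convolutional feature extractors with explicit forward/backward passes.

Style transfer needs gradients of a feature-space loss with respect to the
*input pixels* (the network weights stay frozen), so each layer implements
a hand-written backward pass; the whole stack is plain numpy.

Two extractors share one layer-naming scheme ("Conv4_2", "ReLU1_1", ...):

* a 19-layer VGG-style production extractor whose weights are loaded from a
  user-supplied ``.npz`` file, and
* a small seeded random extractor (5 conv blocks, ReLU after each conv,
  2x average pooling between blocks) used as the download-free test path.

Convolutions are 3x3, zero-padded "same". Note that zero padding makes Gram
statistics border-sensitive at small image sizes.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .image import Image


class LayerConfigError(KeyError):
    """A requested layer name is not registered in the backbone."""


# ---------------------------------------------------------------------------
# layers


class _Conv3x3:
    """3x3 same-padded convolution. weight: (C_out, C_in, 3, 3)."""

    def __init__(self, weight: np.ndarray, bias: np.ndarray):
        weight = np.asarray(weight, dtype=np.float64)
        bias = np.asarray(bias, dtype=np.float64)
        if weight.ndim != 4 or weight.shape[2:] != (3, 3):
            raise ValueError(f"conv weight must be (C_out, C_in, 3, 3), got {weight.shape}")
        if bias.shape != (weight.shape[0],):
            raise ValueError("conv bias shape mismatch")
        self.weight = weight
        self.bias = bias
        self.c_out, self.c_in = weight.shape[:2]
        self._wmat = weight.reshape(self.c_out, -1)  # (C_out, C_in*9)

    def forward(self, x: np.ndarray):
        c, h, w = x.shape
        if c != self.c_in:
            raise ValueError(f"conv expects {self.c_in} channels, got {c}")
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1)))
        # (C, H, W, 3, 3) -> (H*W, C*9)
        win = sliding_window_view(xp, (3, 3), axis=(1, 2))
        cols = win.transpose(1, 2, 0, 3, 4).reshape(h * w, c * 9)
        y = cols @ self._wmat.T + self.bias
        y = y.T.reshape(self.c_out, h, w)
        return y, (h, w)

    def backward(self, grad_y: np.ndarray, cache):
        h, w = cache
        dcols = grad_y.reshape(self.c_out, h * w).T @ self._wmat  # (H*W, C*9)
        dcols = dcols.reshape(h, w, self.c_in, 3, 3)
        dxp = np.zeros((self.c_in, h + 2, w + 2))
        for i in range(3):
            for j in range(3):
                dxp[:, i : i + h, j : j + w] += dcols[:, :, :, i, j].transpose(2, 0, 1)
        return dxp[:, 1 : 1 + h, 1 : 1 + w]


class _ReLU:
    def forward(self, x: np.ndarray):
        y = np.maximum(x, 0.0)
        return y, (x > 0.0)

    def backward(self, grad_y: np.ndarray, cache):
        return grad_y * cache


class _AvgPool2:
    """2x2 average pooling, stride 2; a trailing odd row/column is dropped."""

    def forward(self, x: np.ndarray):
        c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        xt = x[:, : 2 * h2, : 2 * w2].reshape(c, h2, 2, w2, 2)
        y = xt.mean(axis=(2, 4))
        return y, (c, h, w)

    def backward(self, grad_y: np.ndarray, cache):
        c, h, w = cache
        h2, w2 = h // 2, w // 2
        dx = np.zeros((c, h, w))
        up = np.repeat(np.repeat(grad_y, 2, axis=1), 2, axis=2) * 0.25
        dx[:, : 2 * h2, : 2 * w2] = up
        return dx


# ---------------------------------------------------------------------------
# spec and feature containers


@dataclass(frozen=True)
class Preprocessing:
    """Per-channel shift/scale applied before extraction: (x - mean) / std."""

    mean: tuple[float, float, float] = (0.0, 0.0, 0.0)
    std: tuple[float, float, float] = (1.0, 1.0, 1.0)


#: torchvision-style ImageNet normalization used by the pretrained extractor.
IMAGENET_PREPROCESSING = Preprocessing(
    mean=(0.485, 0.456, 0.406), std=(0.229, 0.224, 0.225)
)

DEFAULT_CONTENT_LAYER = "Conv4_2"
DEFAULT_STYLE_LAYERS = ("ReLU1_1", "ReLU2_1", "ReLU3_1", "ReLU4_1", "ReLU5_1")


@dataclass(frozen=True)
class BackboneSpec:
    """Which layers carry content/style and how pixels are normalized."""

    content_layer: str = DEFAULT_CONTENT_LAYER
    style_layers: tuple[str, ...] = DEFAULT_STYLE_LAYERS
    preprocessing: Preprocessing = field(default_factory=Preprocessing)

    def __post_init__(self) -> None:
        if len(set(self.style_layers)) != len(self.style_layers):
            raise ValueError("style_layers must be distinct")

    @property
    def all_layers(self) -> tuple[str, ...]:
        layers = list(self.style_layers)
        if self.content_layer not in layers:
            layers.append(self.content_layer)
        return tuple(layers)


@dataclass
class FeatureMapSet:
    """Named-layer activations (C×H'×W' arrays) extracted from one image."""

    maps: dict[str, np.ndarray]
    image_id: str = ""


# ---------------------------------------------------------------------------
# backbone


class Backbone:
    """An ordered stack of named layers with input-gradient support."""

    def __init__(self, layers: list[tuple[str, object]], name: str = "backbone"):
        self._layers = layers
        self._index = {lname: i for i, (lname, _) in enumerate(layers)}
        self.name = name

    @property
    def layer_names(self) -> tuple[str, ...]:
        return tuple(lname for lname, _ in self._layers)

    def _check_layers(self, names) -> None:
        missing = [n for n in names if n not in self._index]
        if missing:
            raise LayerConfigError(
                f"unknown layer(s) {missing} for backbone {self.name!r}; "
                f"registered layers: {list(self.layer_names)}"
            )

    def conv_weights(self) -> dict[str, np.ndarray]:
        """Snapshot of all convolution weights (for immutability checks)."""
        return {
            lname: layer.weight.copy()
            for lname, layer in self._layers
            if isinstance(layer, _Conv3x3)
        }

    def forward(
        self,
        pixels: np.ndarray,
        layer_names,
        preprocessing: Preprocessing = Preprocessing(),
    ):
        """Run pixels (3×H×W, [0,1]) through the stack.

        Returns (activations at the requested layers, cache for backward).
        """
        self._check_layers(layer_names)
        needed = set(layer_names)
        deepest = max(self._index[n] for n in needed)
        mean = np.asarray(preprocessing.mean, dtype=np.float64).reshape(3, 1, 1)
        std = np.asarray(preprocessing.std, dtype=np.float64).reshape(3, 1, 1)
        x = (np.asarray(pixels, dtype=np.float64) - mean) / std
        acts: dict[str, np.ndarray] = {}
        caches = []
        for lname, layer in self._layers[: deepest + 1]:
            x, cache = layer.forward(x)
            caches.append(cache)
            if lname in needed:
                acts[lname] = x
        return acts, (caches, deepest, std)

    def backward(self, cache, grads_by_layer: dict[str, np.ndarray]) -> np.ndarray:
        """Backpropagate per-layer output gradients to the input pixels."""
        caches, deepest, std = cache
        self._check_layers(grads_by_layer)
        g = None
        for i in range(deepest, -1, -1):
            lname, layer = self._layers[i]
            if lname in grads_by_layer:
                inj = grads_by_layer[lname]
                g = inj.copy() if g is None else g + inj
            if g is None:
                continue
            g = layer.backward(g, caches[i])
        if g is None:
            raise ValueError("no gradients supplied")
        return g / std  # undo preprocessing scale

    def extract_features(self, img: Image, spec: BackboneSpec) -> FeatureMapSet:
        """Activations for exactly content_layer ∪ style_layers (no gradient)."""
        pixels = img.pixels.transpose(2, 0, 1)
        acts, _ = self.forward(pixels, spec.all_layers, spec.preprocessing)
        return FeatureMapSet(maps=acts, image_id=img.source_id)


def extract_features(img: Image, spec: BackboneSpec, backbone: Backbone) -> FeatureMapSet:
    """Functional form of :meth:`Backbone.extract_features`."""
    return backbone.extract_features(img, spec)


# ---------------------------------------------------------------------------
# constructors

#: VGG-19 convolution counts per block.
_VGG19_BLOCKS = (2, 2, 4, 4, 4)
#: test backbone: one conv per block except block 4 (so Conv4_2 exists).
_TEST_BLOCKS = (1, 1, 1, 2, 1)
_TEST_CHANNELS = (8, 12, 16, 16, 16)


def _stack_names(blocks) -> list[tuple[int, int]]:
    return [(b + 1, c + 1) for b, n in enumerate(blocks) for c in range(n)]


def build_test_backbone(seed: int) -> Backbone:
    """Small fixed-architecture extractor with weights drawn from ``seed``.

    Five conv blocks with ReLU after each conv and 2x average pooling
    between blocks; He-scaled Gaussian weights, zero biases; layer names
    match the production scheme so a TransferConfig is interchangeable.

    After drawing the weights, each convolution is rescaled so that the mean
    rectified activation of its filters is one on seeded reference noise —
    the activation-normalization convention classically used for
    style-transfer networks. It keeps feature (and hence Gram) magnitudes
    comparable across depth, which conditions the pixel optimization.
    """
    rng = np.random.default_rng(seed)
    layers: list[tuple[str, object]] = []
    c_in = 3
    for block, n_convs in enumerate(_TEST_BLOCKS, start=1):
        c_out = _TEST_CHANNELS[block - 1]
        for conv in range(1, n_convs + 1):
            fan_in = c_in * 9
            w = rng.standard_normal((c_out, c_in, 3, 3)) * np.sqrt(2.0 / fan_in)
            b = np.zeros(c_out)
            layers.append((f"Conv{block}_{conv}", _Conv3x3(w, b)))
            layers.append((f"ReLU{block}_{conv}", _ReLU()))
            c_in = c_out
        if block < len(_TEST_BLOCKS):
            layers.append((f"Pool{block}", _AvgPool2()))

    # activation normalization on seeded reference noise (64x64, 4 draws)
    calib = [rng.uniform(0.0, 1.0, size=(3, 64, 64)) for _ in range(4)]
    for lname, layer in layers:
        if isinstance(layer, _Conv3x3):
            outs = [layer.forward(x)[0] for x in calib]
            mean_act = float(np.mean([np.maximum(y, 0.0).mean() for y in outs]))
            if mean_act > 0:
                layer.weight /= mean_act
                layer._wmat = layer.weight.reshape(layer.c_out, -1)
                outs = [y / mean_act for y in outs]
        else:
            outs = [layer.forward(x)[0] for x in calib]
        calib = outs
    return Backbone(layers, name=f"test(seed={seed})")


def load_pretrained_backbone(weights_path: str | os.PathLike) -> Backbone:
    """Build the 19-layer extractor from a local ``.npz`` weights file.

    The archive must hold arrays named ``conv{b}_{c}.weight`` of shape
    (C_out, C_in, 3, 3) and ``conv{b}_{c}.bias`` for every convolution of
    the 2-2-4-4-4 block layout. Weights can be exported once, offline, from
    any published VGG-19 checkpoint, e.g.::

        import numpy as np, torchvision
        sd = torchvision.models.vgg19(weights="IMAGENET1K_V1").features.state_dict()
        # map sequential indices to conv{b}_{c} names, then np.savez(...)

    There is no fallback to random weights: a missing or corrupt file is an
    explicit error (use :func:`build_test_backbone` for the test path).
    """
    weights_path = os.fspath(weights_path)
    if not os.path.exists(weights_path):
        raise FileNotFoundError(
            f"pretrained weights not found at {weights_path!r}. Export VGG-19 "
            "convolution weights to an .npz archive with keys "
            "'conv{block}_{conv}.weight' / 'conv{block}_{conv}.bias' "
            "(blocks 1-5 with 2,2,4,4,4 convolutions) and pass its path."
        )
    try:
        with np.load(weights_path) as npz:
            arrays = {k: npz[k] for k in npz.files}
    except Exception as exc:
        raise IOError(f"could not load weights from {weights_path!r}: {exc}") from exc

    layers: list[tuple[str, object]] = []
    for block, n_convs in enumerate(_VGG19_BLOCKS, start=1):
        for conv in range(1, n_convs + 1):
            wkey, bkey = f"conv{block}_{conv}.weight", f"conv{block}_{conv}.bias"
            if wkey not in arrays or bkey not in arrays:
                raise IOError(
                    f"weights archive {weights_path!r} is missing {wkey!r}/"
                    f"{bkey!r}; no partial backbone is built"
                )
            layers.append((f"Conv{block}_{conv}", _Conv3x3(arrays[wkey], arrays[bkey])))
            layers.append((f"ReLU{block}_{conv}", _ReLU()))
        if block < len(_VGG19_BLOCKS):
            layers.append((f"Pool{block}", _AvgPool2()))
    return Backbone(layers, name="vgg19-pretrained")


def pretrained_spec() -> BackboneSpec:
    """Default layer/preprocessing choices for the pretrained extractor."""
    return BackboneSpec(preprocessing=IMAGENET_PREPROCESSING)
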