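"""Content/style representations, the composite loss, and pixel optimization.

The transformation blends a grayscale CLE micrograph (content) with an H&E
micrograph (style). Content is the activation tensor at one deep layer;
style is the list of Gram matrices — channel-by-channel inner products of
the feature maps, a spatial-position-invariant texture statistic — at five
layers. The target image starts from the content image and its *pixels* are
optimized by L-BFGS to minimize

    L = D_c(C_source, C_target) + alpha * sum_i w_i * D_s(S_source_i, S_target_i)

with alpha = 100 and w_i = 0.2 by default. Distance functionals (selectable
via TransferConfig.distance_form):

* ``normalized`` (default) — content D_c = mean(ΔF²), per-layer style
  D_s = ‖ΔG‖² / (4 C² M²). Both terms are per-element ("intensive")
  quantities, so the alpha = 100 balance carries across image resolutions
  and feature widths.
* ``classic`` — content ½‖ΔF‖² (summed), style as above.
* ``mse`` — plain mean squared error for both terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage
import scipy.optimize

from .image import Image
from .backbone import Backbone, BackboneSpec, FeatureMapSet, LayerConfigError


class NumericError(ValueError):
    """Non-finite values in a numeric input."""


class DimensionError(ValueError):
    """Representation shapes do not match pairwise."""


class DivergenceError(RuntimeError):
    """The optimization produced a non-finite loss."""


# ---------------------------------------------------------------------------
# representations


@dataclass(frozen=True)
class GramMatrix:
    """C×C symmetric PSD matrix of channel inner products at one layer."""

    values: np.ndarray
    layer: str
    n_channels: int
    n_positions: int


@dataclass(frozen=True)
class ContentRepresentation:
    activations: np.ndarray  # C×H'×W'
    layer: str


@dataclass(frozen=True)
class StyleRepresentation:
    grams: tuple[GramMatrix, ...]  # ordered as BackboneSpec.style_layers


@dataclass(frozen=True)
class LossWeights:
    """Style-vs-content trade-off alpha and per-layer style weights w_i."""

    alpha: float = 100.0
    layer_weights: tuple[float, ...] = (0.2, 0.2, 0.2, 0.2, 0.2)

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if any(w < 0 for w in self.layer_weights):
            raise ValueError("layer weights must be non-negative")


@dataclass(frozen=True)
class TransferConfig:
    """Everything stylize needs besides the two images and the backbone."""

    backbone_spec: BackboneSpec = field(default_factory=BackboneSpec)
    weights: LossWeights = field(default_factory=LossWeights)
    n_iterations: int = 1600
    init_mode: str = "content_copy"  # or "noise"
    init_seed: int = 0
    clamp_range: bool = True
    distance_form: str = "normalized"  # or "classic" / "mse"
    history_size: int = 100
    max_linesearch: int = 20

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.init_mode not in ("content_copy", "noise"):
            raise ValueError(f"unknown init_mode {self.init_mode!r}")
        if self.distance_form not in ("normalized", "classic", "mse"):
            raise ValueError(f"unknown distance_form {self.distance_form!r}")
        if len(self.weights.layer_weights) != len(self.backbone_spec.style_layers):
            raise ValueError(
                "one style layer weight per style layer is required: "
                f"{len(self.weights.layer_weights)} weights for "
                f"{len(self.backbone_spec.style_layers)} layers"
            )


@dataclass
class LossTrace:
    """Per-iteration (total, content term, style term) records."""

    total: list[float] = field(default_factory=list)
    content: list[float] = field(default_factory=list)
    style: list[float] = field(default_factory=list)

    def append(self, total: float, content: float, style: float) -> None:
        self.total.append(float(total))
        self.content.append(float(content))
        self.style.append(float(style))

    def __len__(self) -> int:
        return len(self.total)

    def as_array(self) -> np.ndarray:
        """(n, 3) array of [total, content, style] rows."""
        return np.column_stack([self.total, self.content, self.style])


# ---------------------------------------------------------------------------
# operations


def gram_matrix(features: np.ndarray, layer: str = "") -> GramMatrix:
    """Channel co-activation matrix G[i, j] = Σ_positions F_i · F_j.

    The Gram is kept unnormalized; the style distance carries the
    1/(4 C² M²) normalization.
    """
    f = np.asarray(features, dtype=np.float64)
    if f.ndim != 3:
        raise ValueError(f"feature map must be C×H'×W', got shape {f.shape}")
    if not np.all(np.isfinite(f)):
        raise NumericError(f"non-finite activations at layer {layer!r}")
    c = f.shape[0]
    m = f.shape[1] * f.shape[2]
    flat = f.reshape(c, m)
    values = flat @ flat.T
    values = 0.5 * (values + values.T)  # enforce exact symmetry
    return GramMatrix(values=values, layer=layer, n_channels=c, n_positions=m)


def content_representation(fm: FeatureMapSet, spec: BackboneSpec) -> ContentRepresentation:
    """Project the content-layer activations out of a feature map set."""
    if spec.content_layer not in fm.maps:
        raise LayerConfigError(
            f"content layer {spec.content_layer!r} absent from feature maps "
            f"(have {sorted(fm.maps)})"
        )
    return ContentRepresentation(
        activations=fm.maps[spec.content_layer], layer=spec.content_layer
    )


def style_representation(fm: FeatureMapSet, spec: BackboneSpec) -> StyleRepresentation:
    """Ordered Gram matrices at the style layers."""
    missing = [n for n in spec.style_layers if n not in fm.maps]
    if missing:
        raise LayerConfigError(
            f"style layer(s) {missing} absent from feature maps (have {sorted(fm.maps)})"
        )
    return StyleRepresentation(
        grams=tuple(gram_matrix(fm.maps[n], layer=n) for n in spec.style_layers)
    )


def _content_distance(f_target, f_source, form):
    diff = f_target - f_source
    if form == "classic":
        return 0.5 * float(np.sum(diff * diff)), diff
    grad = 2.0 * diff / diff.size
    return float(np.mean(diff * diff)), grad


def _style_distance(g_target: GramMatrix, g_source: GramMatrix, form):
    dg = g_target.values - g_source.values
    c, m = g_target.n_channels, g_target.n_positions
    if form == "mse":
        norm = float(dg.size)
    else:  # normalized and classic share the 1/(4 C² M²) style normalization
        norm = 4.0 * (c * m) ** 2
    return float(np.sum(dg * dg)) / norm, dg / norm


def total_loss(
    c_target: ContentRepresentation,
    c_source: ContentRepresentation,
    s_target: StyleRepresentation,
    s_source: StyleRepresentation,
    w: LossWeights,
    form: str = "normalized",
) -> tuple[float, float, float]:
    """Composite loss (L, content_term, style_term); L = content + style.

    The returned style term already carries alpha and the layer weights,
    so alpha = 0 makes L equal the content term alone.
    """
    if c_target.activations.shape != c_source.activations.shape:
        raise DimensionError(
            f"content shapes differ at layer {c_source.layer!r}: "
            f"{c_target.activations.shape} vs {c_source.activations.shape}"
        )
    if len(s_target.grams) != len(s_source.grams):
        raise DimensionError("style representations have different layer counts")
    if len(w.layer_weights) != len(s_source.grams):
        raise DimensionError("one layer weight per style layer is required")

    content_term, _ = _content_distance(
        c_target.activations, c_source.activations, form
    )
    style_term = 0.0
    for wi, gt, gs in zip(w.layer_weights, s_target.grams, s_source.grams):
        if gt.values.shape != gs.values.shape:
            raise DimensionError(
                f"style Gram shapes differ at layer {gs.layer!r}: "
                f"{gt.values.shape} vs {gs.values.shape}"
            )
        d, _ = _style_distance(gt, gs, form)
        style_term += wi * d
    style_term *= w.alpha
    return content_term + style_term, content_term, style_term


def _resize_to(img: Image, height: int, width: int) -> Image:
    """Bilinear resize; style statistics are resolution-sensitive, so the
    style image is brought to the content working resolution."""
    if (img.height, img.width) == (height, width):
        return img
    zoom = (height / img.height, width / img.width, 1.0)
    px = scipy.ndimage.zoom(img.pixels, zoom, order=1, mode="nearest")
    px = np.clip(px[:height, :width, :], 0.0, 1.0)
    return Image(pixels=px, source_id=img.source_id)


def _loss_and_pixel_grad(x, backbone, spec, w, form, c_source, s_source):
    """Loss terms and dL/dpixels at pixel tensor x (3×H×W)."""
    acts, cache = backbone.forward(x, spec.all_layers, spec.preprocessing)

    f_t = acts[spec.content_layer]
    content_term, c_grad = _content_distance(f_t, c_source.activations, form)
    grads: dict[str, np.ndarray] = {spec.content_layer: c_grad}

    style_term = 0.0
    for wi, lname, gs in zip(w.layer_weights, spec.style_layers, s_source.grams):
        f = acts[lname]
        gt = gram_matrix(f, layer=lname)
        d, dgrad = _style_distance(gt, gs, form)
        style_term += wi * d
        c, h, ww = f.shape
        # D = ‖ΔG‖²/norm with G = F Fᵀ ⇒ dD/dF = 4 (ΔG/norm) F
        f_flat = f.reshape(c, h * ww)
        g = (4.0 * w.alpha * wi) * (dgrad @ f_flat)
        g = g.reshape(c, h, ww)
        grads[lname] = grads.get(lname, 0.0) + g
    style_term *= w.alpha

    pixel_grad = backbone.backward(cache, grads)
    return content_term + style_term, content_term, style_term, pixel_grad


def stylize(
    content_img: Image,
    style_img: Image,
    backbone: Backbone,
    cfg: TransferConfig,
) -> tuple[Image, LossTrace]:
    """Optimize target pixels to carry CLE content and H&E style.

    Network weights stay frozen; only the target image changes. Pixels are
    box-constrained to [0, 1] when cfg.clamp_range is set. Returns the
    optimized target (content image's dimensions) and the per-iteration
    loss trace; the first trace record is the loss at initialization.
    """
    spec = cfg.backbone_spec
    w = cfg.weights
    form = cfg.distance_form

    c_source = content_representation(backbone.extract_features(content_img, spec), spec)
    style_scaled = _resize_to(style_img, content_img.height, content_img.width)
    s_source = style_representation(backbone.extract_features(style_scaled, spec), spec)

    shape = (3, content_img.height, content_img.width)
    if cfg.init_mode == "content_copy":
        x0 = content_img.pixels.transpose(2, 0, 1).copy()
    else:
        x0 = np.random.default_rng(cfg.init_seed).uniform(0.0, 1.0, size=shape)

    trace = LossTrace()
    last_eval = {"content": np.nan, "style": np.nan, "total": np.nan}
    eval_count = [0]

    def objective(xflat: np.ndarray):
        eval_count[0] += 1
        x = xflat.reshape(shape)
        total, content, style, grad = _loss_and_pixel_grad(
            x, backbone, spec, w, form, c_source, s_source
        )
        if not np.isfinite(total):
            raise DivergenceError(
                f"non-finite loss at iteration {len(trace)} "
                f"(evaluation {eval_count[0]}): content={content!r}, style={style!r}"
            )
        last_eval.update(total=total, content=content, style=style)
        return total, grad.ravel()

    # record the loss at the initial point
    f0, _ = objective(x0.ravel())
    trace.append(last_eval["total"], last_eval["content"], last_eval["style"])

    def callback(xk: np.ndarray) -> None:
        # L-BFGS-B's accepted iterate is the last line-search evaluation.
        # The trace is capped at n_iterations records (the init record
        # occupies the first slot).
        if len(trace) < cfg.n_iterations:
            trace.append(last_eval["total"], last_eval["content"], last_eval["style"])

    bounds = [(0.0, 1.0)] * x0.size if cfg.clamp_range else None
    res = scipy.optimize.minimize(
        objective,
        x0.ravel(),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        callback=callback,
        options={
            "maxiter": cfg.n_iterations,
            "maxcor": cfg.history_size,
            "maxls": cfg.max_linesearch,
            "ftol": 1e-15,
            "gtol": 1e-12,
        },
    )

    x_final = np.clip(res.x.reshape(shape), 0.0, 1.0)
    target = Image(
        pixels=x_final.transpose(1, 2, 0),
        source_id=f"{content_img.source_id}+style",
    )
    return target, trace
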