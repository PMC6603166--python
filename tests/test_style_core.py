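"""Gram matrices, the composite loss, pixel gradients, and L-BFGS stylization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from histostyle import (
    BackboneSpec,
    Image,
    LossWeights,
    TransferConfig,
    content_representation,
    gram_matrix,
    style_representation,
    stylize,
    total_loss,
)
from histostyle.backbone import FeatureMapSet, LayerConfigError
from histostyle.style_core import (
    DimensionError,
    NumericError,
    _loss_and_pixel_grad,
)


def gram_oracle(features: np.ndarray) -> np.ndarray:
    """Explicit double loop over channels and positions."""
    c = features.shape[0]
    flat = features.reshape(c, -1)
    out = np.zeros((c, c))
    for i in range(c):
        for j in range(c):
            for pos in range(flat.shape[1]):
                out[i, j] += flat[i, pos] * flat[j, pos]
    return out


class TestGramMatrix:
    def test_matches_double_loop_oracle_on_random_maps(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            c = rng.integers(1, 7)
            h = rng.integers(1, 5)
            w = rng.integers(1, 5)  # up to 16 positions
            f = rng.normal(0, 2, size=(c, h, w))
            g = gram_matrix(f)
            expected = gram_oracle(f)
            np.testing.assert_allclose(g.values, expected, rtol=1e-10, atol=1e-12)
            assert g.n_channels == c and g.n_positions == h * w

    def test_zero_map(self):
        g = gram_matrix(np.zeros((3, 2, 2)))
        np.testing.assert_array_equal(g.values, np.zeros((3, 3)))

    def test_orthogonal_channels_give_identity(self):
        # channel 1 = (1, 0), channel 2 = (0, 1) over two positions
        f = np.array([[[1.0, 0.0]], [[0.0, 1.0]]])
        g = gram_matrix(f)
        np.testing.assert_array_equal(g.values, np.eye(2))

    def test_spatial_permutation_invariance(self, rng):
        f = rng.normal(size=(4, 3, 5))
        flat = f.reshape(4, -1)
        perm = rng.permutation(15)
        f2 = flat[:, perm].reshape(4, 3, 5)
        np.testing.assert_allclose(
            gram_matrix(f).values, gram_matrix(f2).values, rtol=1e-12
        )

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_symmetry_and_psd(self, seed):
        rng = np.random.default_rng(seed)
        f = rng.normal(0, 3, size=(rng.integers(1, 6), rng.integers(1, 5), rng.integers(1, 5)))
        g = gram_matrix(f).values
        np.testing.assert_array_equal(g, g.T)
        eigs = np.linalg.eigvalsh(g)
        assert eigs.min() >= -1e-9 * max(1.0, eigs.max())
        assert np.all(np.diag(g) >= 0)

    def test_non_finite_input_rejected(self):
        f = np.zeros((2, 2, 2))
        f[0, 0, 0] = np.inf
        with pytest.raises(NumericError):
            gram_matrix(f)


class TestRepresentations:
    def _fm(self, spec, rng):
        maps = {n: rng.normal(size=(3, 4, 4)) for n in spec.all_layers}
        return FeatureMapSet(maps=maps)

    def test_content_projection_is_bit_identical(self, spec, rng):
        fm = self._fm(spec, rng)
        rep = content_representation(fm, spec)
        assert rep.layer == spec.content_layer
        assert rep.activations is fm.maps[spec.content_layer]

    def test_missing_content_layer_errors(self, spec, rng):
        fm = self._fm(spec, rng)
        del fm.maps[spec.content_layer]
        with pytest.raises(LayerConfigError):
            content_representation(fm, spec)

    def test_style_list_order_matches_spec(self, spec, rng):
        fm = self._fm(spec, rng)
        rep = style_representation(fm, spec)
        assert tuple(g.layer for g in rep.grams) == spec.style_layers

    def test_missing_style_layer_errors(self, spec, rng):
        fm = self._fm(spec, rng)
        del fm.maps[spec.style_layers[2]]
        with pytest.raises(LayerConfigError):
            style_representation(fm, spec)

    def test_all_zero_maps_give_zero_grams(self, spec):
        fm = FeatureMapSet(maps={n: np.zeros((2, 3, 3)) for n in spec.all_layers})
        rep = style_representation(fm, spec)
        for g in rep.grams:
            assert np.all(g.values == 0.0)

    def test_mirror_symmetric_kernel_gives_equal_grams(self):
        """A horizontally weight-tied 1-layer stack cannot distinguish an
        image from its mirror at the Gram level."""
        from histostyle.backbone import Backbone, _Conv3x3, _ReLU

        rng = np.random.default_rng(5)
        w = rng.normal(0, 0.5, size=(4, 3, 3, 3))
        w = 0.5 * (w + w[:, :, :, ::-1])  # tie left-right kernel halves
        bb = Backbone([("Conv1_1", _Conv3x3(w, np.zeros(4))), ("ReLU1_1", _ReLU())])
        sp = BackboneSpec(content_layer="ReLU1_1", style_layers=("ReLU1_1",))
        img = Image(pixels=rng.uniform(size=(12, 12, 3)))
        mirrored = Image(pixels=img.pixels[:, ::-1, :].copy())
        g1 = style_representation(bb.extract_features(img, sp), sp).grams[0]
        g2 = style_representation(bb.extract_features(mirrored, sp), sp).grams[0]
        np.testing.assert_allclose(g1.values, g2.values, rtol=1e-10)


def _reps(spec, rng, c=3, hw=4):
    maps = {n: rng.normal(size=(c, hw, hw)) for n in spec.all_layers}
    fm = FeatureMapSet(maps=maps)
    return content_representation(fm, spec), style_representation(fm, spec)


class TestTotalLoss:
    def test_zero_at_identity(self, spec, rng):
        c, s = _reps(spec, rng)
        L, ct, st_ = total_loss(c, c, s, s, LossWeights())
        assert L == ct == st_ == 0.0

    def test_alpha_zero_reduces_to_content(self, spec, rng):
        ct_rep, s_t = _reps(spec, rng)
        cs_rep, s_s = _reps(spec, rng)
        L, ct, st_ = total_loss(ct_rep, cs_rep, s_t, s_s, LossWeights(alpha=0.0))
        assert st_ == 0.0
        assert L == pytest.approx(ct)
        assert ct > 0

    def test_matches_hand_scalar_oracle(self, spec):
        """Tiny fixed representations vs. independent scalar arithmetic."""
        rng = np.random.default_rng(11)
        c_t, s_t = _reps(spec, rng, c=2, hw=2)
        c_s, s_s = _reps(spec, rng, c=2, hw=2)
        w = LossWeights(alpha=3.0, layer_weights=(0.1, 0.2, 0.3, 0.2, 0.2))

        # oracle: per-element mean content distance + 1/(4C²M²) style
        diff = c_t.activations - c_s.activations
        content = float(np.mean(diff * diff))
        style = 0.0
        for wi, gt, gs in zip(w.layer_weights, s_t.grams, s_s.grams):
            dg = gt.values - gs.values
            style += wi * float(np.sum(dg * dg)) / (4.0 * (gt.n_channels * gt.n_positions) ** 2)
        style *= w.alpha

        L, ct, st_ = total_loss(c_t, c_s, s_t, s_s, w)
        assert ct == pytest.approx(content, rel=1e-10)
        assert st_ == pytest.approx(style, rel=1e-10)
        assert L == pytest.approx(content + style, rel=1e-10)

    def test_classic_form_is_half_sse(self, spec, rng):
        c_t, s_t = _reps(spec, rng)
        c_s, s_s = _reps(spec, rng)
        _, ct, _ = total_loss(c_t, c_s, s_t, s_s, LossWeights(), form="classic")
        expected = 0.5 * np.sum((c_t.activations - c_s.activations) ** 2)
        assert ct == pytest.approx(expected, rel=1e-12)

    def test_non_negative_on_random_representations(self, spec, rng):
        for _ in range(20):
            c_t, s_t = _reps(spec, rng)
            c_s, s_s = _reps(spec, rng)
            L, ct, st_ = total_loss(c_t, c_s, s_t, s_s, LossWeights())
            assert L >= 0 and ct >= 0 and st_ >= 0

    def test_shape_mismatch_names_layer(self, spec, rng):
        c_t, s_t = _reps(spec, rng, hw=4)
        c_s, s_s = _reps(spec, rng, hw=3)
        with pytest.raises(DimensionError, match=spec.content_layer):
            total_loss(c_t, c_s, s_t, s_s, LossWeights())


class TestPixelGradient:
    @pytest.mark.parametrize("form", ["normalized", "classic", "mse"])
    def test_analytic_gradient_matches_finite_differences(self, test_backbone, spec, form):
        rng = np.random.default_rng(2)
        content = Image(pixels=rng.uniform(size=(18, 18, 3)))
        style = Image(pixels=rng.uniform(size=(18, 18, 3)))
        c_src = content_representation(test_backbone.extract_features(content, spec), spec)
        s_src = style_representation(test_backbone.extract_features(style, spec), spec)
        w = LossWeights()
        x = rng.uniform(0.2, 0.8, size=(3, 18, 18))
        _, _, _, g = _loss_and_pixel_grad(x, test_backbone, spec, w, form, c_src, s_src)
        eps = 1e-6
        for idx in [(0, 3, 4), (1, 9, 9), (2, 17, 0), (0, 0, 17)]:
            xp, xm = x.copy(), x.copy()
            xp[idx] += eps
            xm[idx] -= eps
            lp = _loss_and_pixel_grad(xp, test_backbone, spec, w, form, c_src, s_src)[0]
            lm = _loss_and_pixel_grad(xm, test_backbone, spec, w, form, c_src, s_src)[0]
            num = (lp - lm) / (2 * eps)
            assert g[idx] == pytest.approx(num, rel=5e-4, abs=1e-9)


class TestStylize:
    def test_self_style_fixed_point(self, test_backbone, cle_image):
        cfg = TransferConfig(n_iterations=20)
        target, trace = stylize(cle_image, cle_image, test_backbone, cfg)
        assert trace.total[0] == 0.0
        assert np.abs(target.pixels - cle_image.pixels).max() <= 1.0 / 255

    def test_optimization_decreases_loss_monotonically(
        self, test_backbone, cle_image, he_image
    ):
        cfg = TransferConfig(n_iterations=50)
        target, trace = stylize(cle_image, he_image, test_backbone, cfg)
        tot = np.array(trace.total)
        assert len(trace) <= cfg.n_iterations
        assert trace.content[0] == 0.0  # content-copy init
        assert np.all(np.diff(tot) <= 1e-12)
        assert trace.style[-1] < trace.style[0]
        assert tot[-1] <= tot[0]
        assert (target.height, target.width) == (cle_image.height, cle_image.width)
        assert target.pixels.min() >= 0.0 and target.pixels.max() <= 1.0

    def test_sources_and_weights_immutable(self, test_backbone, cle_image, he_image):
        before_c = cle_image.pixels.copy()
        before_s = he_image.pixels.copy()
        before_w = test_backbone.conv_weights()
        stylize(cle_image, he_image, test_backbone, TransferConfig(n_iterations=5))
        np.testing.assert_array_equal(cle_image.pixels, before_c)
        np.testing.assert_array_equal(he_image.pixels, before_s)
        after_w = test_backbone.conv_weights()
        for name in before_w:
            np.testing.assert_array_equal(before_w[name], after_w[name])

    def test_noise_init_is_seeded(self, test_backbone, cle_image, he_image):
        cfg = TransferConfig(n_iterations=3, init_mode="noise", init_seed=9)
        t1, tr1 = stylize(cle_image, he_image, test_backbone, cfg)
        t2, tr2 = stylize(cle_image, he_image, test_backbone, cfg)
        assert tr1.total[0] == tr2.total[0]
        np.testing.assert_allclose(t1.pixels, t2.pixels, atol=1e-8)

    def test_style_image_resized_to_content_resolution(
        self, test_backbone, cle_image
    ):
        from histostyle import make_he_style_image

        big_style, _ = make_he_style_image(size=96, seed=1)
        cfg = TransferConfig(n_iterations=3)
        target, _ = stylize(cle_image, big_style, test_backbone, cfg)
        assert (target.height, target.width) == (cle_image.height, cle_image.width)

    def test_layer_weight_count_must_match(self, spec):
        with pytest.raises(ValueError):
            TransferConfig(weights=LossWeights(layer_weights=(0.5, 0.5)))
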