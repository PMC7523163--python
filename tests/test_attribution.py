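"""Path-attribution oracles: closed forms, completeness, and rank maps."""

import numpy as np
import pytest

import cxraudit as cx
from cxraudit.attribution import (BackgroundSet, FunctionModel,
                                  background_sensitivity, expected_gradients,
                                  integrated_gradients, percentile_saliency)
from cxraudit.errors import ParameterError


def linear_model(w, b=0.0):
    w = np.asarray(w, dtype=np.float64)
    return FunctionModel(
        f=lambda x: (x * w).sum(axis=(1, 2)) + b,
        grad=lambda x: np.broadcast_to(w, x.shape).copy())


def smooth_model(seed=0, shape=(6, 6)):
    """Two-layer tanh network on flattened input: smooth and nonlinear."""
    rng = np.random.default_rng(seed)
    W1 = rng.normal(0, 0.8, size=(12, shape[0] * shape[1]))
    w2 = rng.normal(0, 0.8, size=12)

    def f(x):
        h = np.tanh(x.reshape(x.shape[0], -1) @ W1.T)
        return h @ w2

    def grad(x):
        flat = x.reshape(x.shape[0], -1)
        h = np.tanh(flat @ W1.T)
        return (((1 - h ** 2) * w2) @ W1).reshape(x.shape)

    return FunctionModel(f, grad)


class TestExpectedGradients:
    def test_constant_model_attributes_nothing(self):
        model = FunctionModel(f=lambda x: np.full(x.shape[0], 3.0),
                              grad=lambda x: np.zeros_like(x))
        bg = BackgroundSet(np.random.default_rng(0).random((5, 4, 4)))
        attr = expected_gradients(model, np.ones((4, 4)), bg, n_samples=50, seed=0)
        assert np.all(attr.phi == 0.0)
        assert attr.completeness_gap < 1e-12

    def test_linear_model_matches_closed_form(self):
        rng = np.random.default_rng(1)
        w = rng.normal(size=(5, 5))
        model = linear_model(w, b=0.3)
        bg = BackgroundSet(rng.random((30, 5, 5)))
        x = rng.random((5, 5))
        attr = expected_gradients(model, x, bg, n_samples=4000, seed=2)
        expected = w * (x - bg.images.mean(axis=0))
        # Monte-Carlo error of the reference mean at n=4000
        assert np.abs(attr.phi - expected).max() < 4 * np.abs(w).max() * \
            bg.images.std() / np.sqrt(4000) * 10

    def test_quadratic_single_pixel_matches_path_integral(self):
        # f(x) = x^2, reference 0: phi -> f(x) - f(0) = x^2
        def grad(x):
            g = np.zeros_like(x)
            g[:, 0, 0] = 2 * x[:, 0, 0]
            return g

        model = FunctionModel(f=lambda x: x[:, 0, 0] ** 2, grad=grad)
        x = np.array([[0.8]])
        bg = BackgroundSet(np.zeros((1, 1, 1)))
        attr = expected_gradients(model, x, bg, n_samples=10_000, seed=3)
        assert attr.phi[0, 0] == pytest.approx(0.64, abs=0.01)

    def test_empty_background_rejected(self):
        with pytest.raises(ParameterError):
            BackgroundSet(np.zeros((0, 3, 3)))


class TestIntegratedGradients:
    def test_reference_equal_to_image_gives_zero(self):
        model = smooth_model()
        x = np.random.default_rng(4).random((6, 6))
        attr = integrated_gradients(model, x, x, n_alpha=16, node=0)
        assert np.all(attr.phi == 0.0)

    def test_linear_model_exact(self):
        rng = np.random.default_rng(5)
        w = rng.normal(size=(4, 4))
        model = linear_model(w)
        x, ref = rng.random((4, 4)), rng.random((4, 4))
        attr = integrated_gradients(model, x, ref, n_alpha=8)
        assert np.allclose(attr.phi, w * (x - ref), atol=1e-12)

    def test_completeness_on_smooth_model_to_quadrature_tolerance(self):
        model = smooth_model(seed=6)
        rng = np.random.default_rng(7)
        x, ref = rng.random((6, 6)), rng.random((6, 6))
        attr = integrated_gradients(model, x, ref, n_alpha=512)
        assert attr.completeness_gap < 1e-4

    def test_equals_expected_gradients_with_singleton_background(self):
        model = smooth_model(seed=8)
        rng = np.random.default_rng(9)
        x, ref = rng.random((6, 6)), rng.random((6, 6))
        n_alpha = 64
        ig = integrated_gradients(model, x, ref, n_alpha=n_alpha)
        grid = (np.arange(n_alpha) + 0.5) / n_alpha
        eg = expected_gradients(model, x, BackgroundSet(ref[None]),
                                seed=0, alphas=grid)
        assert np.allclose(eg.phi, ig.phi, atol=1e-12)


class TestCompletenessConvergence:
    def test_gap_shrinks_with_sample_count(self):
        model = smooth_model(seed=10)
        rng = np.random.default_rng(11)
        x = rng.random((6, 6))
        bg = BackgroundSet(rng.random((40, 6, 6)))
        gaps = [np.mean([expected_gradients(model, x, bg, n_samples=n,
                                            seed=s).completeness_gap
                         for s in range(10)])
                for n in (20, 2000)]
        assert gaps[1] < gaps[0] / 3   # ~1/sqrt(n) scaling at 100x samples


class TestPercentileSaliency:
    def test_strictly_increasing_values_give_increasing_percentiles(self):
        attr = cx.AttributionMap(phi=np.array([[1, 2, 3, 4, 5.0]]),
                                 image=np.zeros((1, 5)), node=0, n_references=1,
                                 n_alpha=1, seed=0, background_id="t",
                                 completeness_gap=0.0)
        pct = percentile_saliency(attr)
        assert np.all(np.diff(pct[0]) > 0)
        assert pct[0, -1] == 100.0

    def test_single_dominant_pixel_at_top_percentile(self):
        phi = np.zeros((3, 3))
        phi[1, 1] = 99.0
        attr = cx.AttributionMap(phi=phi, image=np.zeros((3, 3)), node=0,
                                 n_references=1, n_alpha=1, seed=0,
                                 background_id="t", completeness_gap=0.0)
        assert percentile_saliency(attr)[1, 1] == 100.0

    def test_random_map_matches_sort_oracle(self):
        rng = np.random.default_rng(12)
        phi = rng.normal(size=(8, 8))
        attr = cx.AttributionMap(phi=phi, image=np.zeros((8, 8)), node=0,
                                 n_references=1, n_alpha=1, seed=0,
                                 background_id="t", completeness_gap=0.0)
        pct = percentile_saliency(attr)
        order = np.argsort(np.abs(phi).ravel())
        expected = np.empty(64)
        expected[order] = (np.arange(64) + 1) / 64 * 100
        assert np.allclose(pct.ravel(), expected)

    def test_all_equal_map_displays_flat_midscale(self):
        attr = cx.AttributionMap(phi=np.ones((4, 4)), image=np.zeros((4, 4)),
                                 node=0, n_references=1, n_alpha=1, seed=0,
                                 background_id="t", completeness_gap=0.0)
        pct = percentile_saliency(attr)
        assert np.ptp(pct) == 0.0
        assert pct[0, 0] == pytest.approx(50.0, abs=4.0)


class TestBackgroundSensitivity:
    def test_identical_backgrounds_same_seed_correlate_perfectly(self):
        model = smooth_model(seed=13)
        rng = np.random.default_rng(14)
        x = rng.random((6, 6))
        bg = BackgroundSet(rng.random((10, 6, 6)))
        rho, _, _ = background_sensitivity(model, x, bg, bg, n_samples=100, seed=5)
        assert rho == pytest.approx(1.0)

    def test_linear_model_depends_only_on_background_mean(self):
        rng = np.random.default_rng(15)
        w = rng.normal(size=(5, 5))
        model = linear_model(w)
        x = rng.random((5, 5))
        base = rng.random((200, 5, 5))
        bg_a = BackgroundSet(base)
        bg_b = BackgroundSet(base[::-1].copy())           # same mean, reordered
        rho, _, _ = background_sensitivity(model, x, bg_a, bg_b,
                                           n_samples=5000, seed=6)
        assert rho > 0.99

    def test_degenerate_map_warns_and_returns_nan(self):
        model = FunctionModel(f=lambda x: np.zeros(x.shape[0]),
                              grad=lambda x: np.zeros_like(x))
        bg = BackgroundSet(np.random.default_rng(16).random((4, 3, 3)))
        with pytest.warns(UserWarning):
            rho, _, _ = background_sensitivity(model, np.ones((3, 3)), bg, bg,
                                               n_samples=20, seed=7)
        assert np.isnan(rho)


class TestSymmetry:
    def test_consistent_pixel_permutation_permutes_attributions(self):
        rng = np.random.default_rng(17)
        w = rng.normal(size=(4, 4))
        x = rng.random((4, 4))
        bg_imgs = rng.random((12, 4, 4))
        perm = rng.permutation(16)

        attr = expected_gradients(linear_model(w), x,
                                  BackgroundSet(bg_imgs), n_samples=300, seed=8)

        def p(arr):
            return arr.ravel()[perm].reshape(4, 4)

        attr_p = expected_gradients(
            linear_model(p(w)), p(x),
            BackgroundSet(np.stack([p(im) for im in bg_imgs])),
            n_samples=300, seed=8)
        assert np.allclose(attr_p.phi, p(attr.phi), atol=1e-12)
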