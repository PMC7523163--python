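"""Expected Gradients path attributions and diagnostics.

The attribution of pixel i for input x is

    phi_i(x) = E_{x' ~ D, alpha ~ U(0,1)} [ (x_i - x'_i) *
               df(x' + alpha (x - x')) / dx_i ],

estimated by Monte-Carlo with one gradient evaluation per jointly drawn
(x', alpha) pair. D is a *background distribution* of reference images
(typically the training negatives). Integrated Gradients is the special
case of a single reference with a deterministic alpha grid.

f is the model's pre-sigmoid (log-odds) output at the requested node, so
attributions are additive in the same space used by the behavioral tests.
The *completeness* identity, sum_i phi_i = f(x) - E_D f(x'), holds in
expectation; the realized gap is recorded on every map as a convergence
diagnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata, spearmanr

from .errors import NumericError, ParameterError

__all__ = ["BackgroundSet", "AttributionMap", "FunctionModel",
           "expected_gradients", "integrated_gradients",
           "percentile_saliency", "background_sensitivity"]


@dataclass
class BackgroundSet:
    """A nonempty, shape-homogeneous collection of reference images."""

    images: np.ndarray                 # (M, H, W)
    description: str = ""
    background_id: str = "background"

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=np.float64)
        if self.images.ndim == 2:
            self.images = self.images[None]
        if self.images.ndim != 3 or self.images.shape[0] == 0:
            raise ParameterError("background must be a nonempty (M, H, W) stack")

    def __len__(self) -> int:
        return self.images.shape[0]


@dataclass
class AttributionMap:
    phi: np.ndarray
    image: np.ndarray
    node: object
    n_references: int
    n_alpha: int
    seed: int | None
    background_id: str
    completeness_gap: float

    @property
    def total(self) -> float:
        return float(self.phi.sum())


class FunctionModel:
    """Adapter exposing a plain ``f(x)`` / ``grad f(x)`` pair as a model.

    ``f`` maps a batch (N, H, W) -> (N,); ``grad`` maps the same batch to
    per-sample input gradients (N, H, W). Used for closed-form oracles
    (linear and low-dimensional smooth models).
    """

    def __init__(self, f, grad):
        self._f, self._grad = f, grad

    def logits(self, images: np.ndarray) -> np.ndarray:
        images = np.asarray(images, dtype=np.float64)
        if images.ndim == 2:
            images = images[None]
        return np.asarray(self._f(images), dtype=np.float64).reshape(-1, 1)

    def input_gradients(self, images: np.ndarray, node=0) -> np.ndarray:
        images = np.asarray(images, dtype=np.float64)
        if images.ndim == 2:
            images = images[None]
        return np.asarray(self._grad(images), dtype=np.float64)


def _node_scores(model, images: np.ndarray, node) -> np.ndarray:
    out = model.logits(images)
    if hasattr(model, "_node_index"):
        j = model._node_index(node)
    else:
        j = 0 if node in (0, "covid", None) else int(node)
    return out[:, j]


def _accumulate(model, image, refs, alphas, node) -> np.ndarray:
    diffs = image[None] - refs                       # (S, H, W)
    points = refs + alphas[:, None, None] * diffs
    grads = model.input_gradients(points, node)
    if not np.all(np.isfinite(grads)):
        raise NumericError("non-finite gradients during path attribution")
    return (diffs * grads).mean(axis=0)


def expected_gradients(model, image: np.ndarray, background: BackgroundSet,
                       n_samples: int = 200, seed: int = 0, node="covid",
                       alphas: np.ndarray | None = None) -> AttributionMap:
    """Monte-Carlo Expected Gradients estimate for one image and node.

    Each of the ``n_samples`` draws pairs a uniformly chosen background
    reference with an independent alpha ~ U(0,1). Passing an explicit
    ``alphas`` grid overrides the uniform draw (each grid point is paired
    with an independently drawn reference), which with a singleton
    background reduces the estimator to Integrated Gradients.
    """
    if n_samples < 1:
        raise ParameterError("n_samples must be >= 1")
    image = np.asarray(image, dtype=np.float64)
    rng = np.random.default_rng(seed)
    if alphas is None:
        alphas = rng.random(n_samples)
    else:
        alphas = np.asarray(alphas, dtype=np.float64)
        n_samples = alphas.size
    idx = rng.integers(0, len(background), n_samples)
    refs = background.images[idx]
    phi = _accumulate(model, image, refs, alphas, node)

    f_x = float(_node_scores(model, image[None], node)[0])
    f_bg = float(_node_scores(model, background.images, node).mean())
    gap = abs(phi.sum() - (f_x - f_bg))
    return AttributionMap(phi=phi, image=image, node=node,
                          n_references=len(background), n_alpha=n_samples,
                          seed=seed, background_id=background.background_id,
                          completeness_gap=gap)


def integrated_gradients(model, image: np.ndarray, reference: np.ndarray,
                         n_alpha: int = 64, node="covid") -> AttributionMap:
    """Single-reference path integral on a midpoint alpha grid."""
    if n_alpha < 1:
        raise ParameterError("n_alpha must be >= 1")
    image = np.asarray(image, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if reference.shape != image.shape:
        raise ParameterError("reference shape must match image shape")
    alphas = (np.arange(n_alpha) + 0.5) / n_alpha
    refs = np.broadcast_to(reference, (n_alpha, *reference.shape))
    phi = _accumulate(model, image, refs, alphas, node)

    f_x = float(_node_scores(model, image[None], node)[0])
    f_ref = float(_node_scores(model, reference[None], node)[0])
    gap = abs(phi.sum() - (f_x - f_ref))
    return AttributionMap(phi=phi, image=image, node=node, n_references=1,
                          n_alpha=n_alpha, seed=None,
                          background_id="single-reference",
                          completeness_gap=gap)


def percentile_saliency(attr: AttributionMap, signed: bool = False) -> np.ndarray:
    """Rank-transform of |phi| (or signed phi) to [0, 100] percentiles.

    Monotone in phi; ties share their average rank, so an all-equal map
    displays as a flat ~50th percentile.
    """
    values = attr.phi if signed else np.abs(attr.phi)
    if not np.all(np.isfinite(values)):
        raise NumericError("attribution map contains non-finite values")
    flat = values.ravel()
    pct = rankdata(flat) / flat.size * 100.0
    return pct.reshape(values.shape)


def background_sensitivity(model, image: np.ndarray, background_a: BackgroundSet,
                           background_b: BackgroundSet, n_samples: int = 200,
                           seed: int = 0, node="covid"):
    """Spearman rank correlation between attributions under two backgrounds.

    Returns ``(correlation, map_a, map_b)``; a constant map makes the
    correlation undefined (warned, returned as nan).
    """
    map_a = expected_gradients(model, image, background_a, n_samples, seed, node)
    map_b = expected_gradients(model, image, background_b, n_samples, seed, node)
    fa, fb = map_a.phi.ravel(), map_b.phi.ravel()
    if np.ptp(fa) == 0 or np.ptp(fb) == 0:
        warnings.warn("degenerate (constant) attribution map: correlation undefined",
                      stacklevel=2)
        return float("nan"), map_a, map_b
    rho = spearmanr(fa, fb).statistic
    return float(rho), map_a, map_b
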