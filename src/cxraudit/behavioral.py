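"""Behavioral perturbation tests with Monte-Carlo empirical p-values.

Two experiments probe whether a classifier actually uses a suspected
shortcut region:

* **marker swap** — exchange the laterality-marker patches of a positive
  and a negative image and measure each image's change in COVID log-odds;
* **shoulder relocation** — copy the shoulder/clavicle band of an image to
  the top corners (where the positive source places it).

Significance comes from an empirical null of n random same-size patch
modifications: p = (r + 1) / (n + 1), where r counts null modifications
whose effect strictly exceeds the observed one in the direction of
interest. All output changes are measured in pre-sigmoid log-odds of the
COVID node.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError, NumericError, ParameterError

__all__ = ["PatchRegion", "SwapTestResult", "swap_patches",
           "empirical_p_value", "run_swap_test", "run_reposition_test"]


@dataclass(frozen=True)
class PatchRegion:
    """Half-open pixel rectangle [top, top+height) x [left, left+width)."""

    top: int
    left: int
    height: int
    width: int

    def __post_init__(self):
        if self.height < 1 or self.width < 1:
            raise GeometryError("region height and width must be >= 1")
        if self.top < 0 or self.left < 0:
            raise GeometryError("region origin must be nonnegative")

    @property
    def slices(self) -> tuple[slice, slice]:
        return (slice(self.top, self.top + self.height),
                slice(self.left, self.left + self.width))

    def check_within(self, shape: tuple[int, int]) -> None:
        if self.top + self.height > shape[0] or self.left + self.width > shape[1]:
            raise GeometryError(f"region {self} exceeds image bounds {shape}")

    @property
    def dims(self) -> tuple[int, int]:
        return (self.height, self.width)


@dataclass
class SwapTestResult:
    delta_observed: float
    null_deltas: np.ndarray
    r: int
    p: float
    n: int
    seed: int
    region: PatchRegion
    direction: str

    def __post_init__(self):
        assert len(self.null_deltas) == self.n
        assert abs(self.p - (self.r + 1) / (self.n + 1)) < 1e-12


def swap_patches(image_a: np.ndarray, image_b: np.ndarray,
                 region_a: PatchRegion, region_b: PatchRegion):
    """Exchange patch contents between two images; everything else untouched."""
    if region_a.dims != region_b.dims:
        raise GeometryError(f"patch dimensions differ: {region_a.dims} vs {region_b.dims}")
    region_a.check_within(image_a.shape)
    region_b.check_within(image_b.shape)
    out_a = np.array(image_a, copy=True)
    out_b = np.array(image_b, copy=True)
    out_a[region_a.slices] = image_b[region_b.slices]
    out_b[region_b.slices] = image_a[region_a.slices]
    return out_a, out_b


def empirical_p_value(delta_observed: float, null_deltas, direction: str = "increase") -> float:
    """p = (r + 1) / (n + 1), r = # null deltas strictly beyond the observed.

    ``direction="increase"`` counts null deltas greater than the observed
    change; ``"decrease"`` counts those with a greater-magnitude decrease
    (more negative). Ties are not counted.
    """
    null_deltas = np.asarray(null_deltas, dtype=float)
    if null_deltas.size == 0:
        raise ParameterError("null_deltas must be nonempty")
    if not np.isfinite(delta_observed) or not np.all(np.isfinite(null_deltas)):
        raise NumericError("non-finite deltas in p-value computation")
    if direction == "increase":
        r = int(np.sum(null_deltas > delta_observed))
    elif direction == "decrease":
        r = int(np.sum(null_deltas < delta_observed))
    else:
        raise ParameterError(f"direction must be 'increase' or 'decrease', got {direction!r}")
    return (r + 1) / (null_deltas.size + 1)


def _random_region(rng: np.random.Generator, shape, dims: tuple[int, int]) -> PatchRegion:
    h, w = dims
    top = int(rng.integers(0, shape[0] - h + 1))
    left = int(rng.integers(0, shape[1] - w + 1))
    return PatchRegion(top=top, left=left, height=h, width=w)


def _log_odds_batch(model, images: list[np.ndarray], node) -> np.ndarray:
    return model.logits(np.stack(images))[:, model._node_index(node)] \
        if hasattr(model, "_node_index") else model.logits(np.stack(images))[:, 0]


def run_swap_test(model, image_pos: np.ndarray, image_neg: np.ndarray,
                  region_pos: PatchRegion, region_neg: PatchRegion,
                  n: int = 1000, seed: int = 0, node="covid"):
    """Marker-swap test; returns (result_for_positive, result_for_negative).

    The observed modification swaps the two marker regions. Null draws swap
    n uniformly placed random patch pairs of identical dimensions (fresh
    positions per draw; they may overlap the true marker regions). The
    positive image is tested for a decrease in log-odds, the negative for
    an increase.
    """
    if n < 1:
        raise ParameterError("null size n must be >= 1")
    if region_pos.dims != region_neg.dims:
        raise GeometryError("marker regions must have equal dimensions")
    region_pos.check_within(image_pos.shape)
    region_neg.check_within(image_neg.shape)

    base = _log_odds_batch(model, [image_pos, image_neg], node)
    mod_pos, mod_neg = swap_patches(image_pos, image_neg, region_pos, region_neg)
    obs = _log_odds_batch(model, [mod_pos, mod_neg], node)
    delta_pos = float(obs[0] - base[0])
    delta_neg = float(obs[1] - base[1])

    rng = np.random.default_rng(seed)
    null_pos_imgs, null_neg_imgs = [], []
    for _ in range(n):
        ra = _random_region(rng, image_pos.shape, region_pos.dims)
        rb = _random_region(rng, image_neg.shape, region_neg.dims)
        na, nb = swap_patches(image_pos, image_neg, ra, rb)
        null_pos_imgs.append(na)
        null_neg_imgs.append(nb)
    null_pos = _log_odds_batch(model, null_pos_imgs, node) - base[0]
    null_neg = _log_odds_batch(model, null_neg_imgs, node) - base[1]

    p_pos = empirical_p_value(delta_pos, null_pos, "decrease")
    p_neg = empirical_p_value(delta_neg, null_neg, "increase")
    r_pos = int(np.sum(null_pos < delta_pos))
    r_neg = int(np.sum(null_neg > delta_neg))
    res_pos = SwapTestResult(delta_pos, np.asarray(null_pos), r_pos, p_pos, n,
                             seed, region_pos, "decrease")
    res_neg = SwapTestResult(delta_neg, np.asarray(null_neg), r_neg, p_neg, n,
                             seed, region_neg, "increase")
    return res_pos, res_neg


def run_reposition_test(model, image: np.ndarray, source_region: PatchRegion,
                        target_positions, n: int = 1000, seed: int = 0,
                        node="covid", direction: str = "increase") -> SwapTestResult:
    """Shoulder-relocation test.

    The observed modification copies ``source_region``'s content to each
    (row, col) in ``target_positions`` (the source region keeps its
    original content — duplication, not cut-paste). Null modifications
    copy n random same-size patches of the original image to the same
    targets.
    """
    if n < 1:
        raise ParameterError("null size n must be >= 1")
    source_region.check_within(image.shape)
    h, w = source_region.dims
    targets = [PatchRegion(top=int(r), left=int(c), height=h, width=w)
               for r, c in target_positions]
    for t in targets:
        t.check_within(image.shape)

    def apply(src: PatchRegion) -> np.ndarray:
        out = np.array(image, copy=True)
        patch = image[src.slices]
        for t in targets:
            out[t.slices] = patch
        return out

    base = float(_log_odds_batch(model, [image], node)[0])
    delta_obs = float(_log_odds_batch(model, [apply(source_region)], node)[0]) - base

    rng = np.random.default_rng(seed)
    null_imgs = [apply(_random_region(rng, image.shape, (h, w))) for _ in range(n)]
    null_deltas = _log_odds_batch(model, null_imgs, node) - base

    p = empirical_p_value(delta_obs, null_deltas, direction)
    r = int(np.sum(null_deltas > delta_obs) if direction == "increase"
            else np.sum(null_deltas < delta_obs))
    return SwapTestResult(delta_obs, np.asarray(null_deltas), r, p, n, seed,
                          source_region, direction)
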