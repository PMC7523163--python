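"""Unpaired image-to-image translation between the COVID-negative domain X
and the COVID-positive domain Y, used as dataset-level interpretability.

Two generators are trained adversarially, G: X -> Y and F: Y -> X, against
discriminators D_Y and D_X, with losses

    L_GAN(G, D_Y) = E_y[log D_Y(y)] + E_x[log(1 - D_Y(G(x)))]
    L_GAN(F, D_X) = E_x[log D_X(x)] + E_y[log(1 - D_X(F(y)))]
    L_cyc(G, F)   = E_x ||F(G(x)) - x||_1 + E_y ||G(F(y)) - y||_1
    L             = L_GAN(G, D_Y) + L_GAN(F, D_X) + L_cyc(G, F)

(the plain sum, with unit weights and no identity loss). After training,
|G(x) - x| difference maps localize the features that separate the domains,
and the classifier flip rate measures how much of an audited classifier's
decision the transformation carries.

Desk-scale architecture: residual convolutional generators (output = input
+ bounded delta) and patch discriminators, both with two appended
coordinate channels so that position-specific features (corner glyphs) are
expressible at shallow depth. The generators' adversarial update uses the
non-saturating form (minimize -log D(G(x))), the standard stable
realization of the minimax objective; reported losses are always the
printed forms above. A least-squares adversarial variant is available via
``loss_type="lsgan"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data import DatasetManifest
from .errors import ParameterError
from .nn import (Adam, Conv2d, Dense, Flatten, LeakyReLU, ReLU, Sequential,
                 SigmoidSqueeze, Tanh)

logger = logging.getLogger(__name__)

__all__ = ["GanSystem", "GanLossReport", "ResidualGenerator", "PatchDiscriminator",
           "cyclegan_losses", "train_cyclegan", "classifier_flip_rate",
           "difference_map"]

_EPS = 1e-7


def _coord_channels(size: int) -> np.ndarray:
    rows = np.linspace(-1.0, 1.0, size)[:, None] * np.ones((1, size))
    cols = np.linspace(-1.0, 1.0, size)[None, :] * np.ones((size, 1))
    return np.stack([rows, cols])           # (2, H, W)


class ResidualGenerator:
    """G(x) = x + delta(x), delta bounded in (-1, 1) by a tanh output layer."""

    def __init__(self, image_size: int, channels: int = 12,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.image_size = image_size
        self.net = Sequential([
            Conv2d(3, channels, k=3, stride=1, pad=1, rng=rng), ReLU(),
            Conv2d(channels, channels, k=3, stride=1, pad=1, rng=rng), ReLU(),
            Conv2d(channels, 1, k=3, stride=1, pad=1, rng=rng,
                   weight_scale=1e-3), Tanh(),
        ])
        self._coords = _coord_channels(image_size)

    def params(self):
        return self.net.params()

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (N, 1, H, W) -> translated batch of the same shape."""
        n = x.shape[0]
        coords = np.broadcast_to(self._coords, (n, 2, *self._coords.shape[1:]))
        inp = np.concatenate([x, coords], axis=1)
        return x + self.net.forward(inp)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dinp = self.net.backward(dout)
        return dout + dinp[:, :1]            # skip connection + delta path

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


class PatchDiscriminator:
    """Conv patch features pooled by a dense positional head -> (N,) in (0, 1).

    The final dense layer weights each patch logit by location, so localized
    domain differences (a corner glyph) can drive the image-level decision.
    """

    def __init__(self, image_size: int, channels: int = 12,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.image_size = image_size
        feat = image_size // 4
        self.net = Sequential([
            Conv2d(3, channels, k=3, stride=2, pad=1, rng=rng), LeakyReLU(0.2),
            Conv2d(channels, 2 * channels, k=3, stride=2, pad=1, rng=rng), LeakyReLU(0.2),
            Conv2d(2 * channels, 1, k=3, stride=1, pad=1, rng=rng),
            Flatten(), Dense(feat * feat, 1, rng=rng), SigmoidSqueeze(),
        ])
        self._coords = _coord_channels(image_size)

    def params(self):
        return self.net.params()

    def forward(self, x: np.ndarray) -> np.ndarray:
        n = x.shape[0]
        coords = np.broadcast_to(self._coords, (n, 2, *self._coords.shape[1:]))
        return self.net.forward(np.concatenate([x, coords], axis=1))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return self.net.backward(dout)[:, :1]

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


@dataclass
class GanSystem:
    G: ResidualGenerator
    F: ResidualGenerator
    D_X: PatchDiscriminator
    D_Y: PatchDiscriminator
    image_size: int
    seed: int = 0
    loss_history: list["GanLossReport"] = field(default_factory=list)


@dataclass
class GanLossReport:
    l_gan_G: float
    l_gan_F: float
    l_cyc: float

    @property
    def total(self) -> float:
        return self.l_gan_G + self.l_gan_F + self.l_cyc


def _safe_log(p: np.ndarray) -> np.ndarray:
    clipped = np.clip(p, _EPS, 1.0 - _EPS)
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        logger.warning("discriminator output clamped to (%g, %g) before log",
                       _EPS, 1.0 - _EPS)
    return np.log(clipped)


def cyclegan_losses(system: GanSystem, batch_x: np.ndarray,
                    batch_y: np.ndarray) -> GanLossReport:
    """Evaluate the printed adversarial and cycle losses on two batches."""
    if batch_x.size == 0 or batch_y.size == 0:
        raise ParameterError("batches must be nonempty")
    gx = system.G(batch_x)
    fy = system.F(batch_y)
    l_gan_G = float(np.mean(_safe_log(system.D_Y(batch_y)))
                    + np.mean(_safe_log(1.0 - system.D_Y(gx))))
    l_gan_F = float(np.mean(_safe_log(system.D_X(batch_x)))
                    + np.mean(_safe_log(1.0 - system.D_X(fy))))
    # ||.||_1 is a sum over pixels; the expectation runs over images
    l_cyc = float(np.abs(system.F(gx) - batch_x).sum(axis=(1, 2, 3)).mean()
                  + np.abs(system.G(fy) - batch_y).sum(axis=(1, 2, 3)).mean())
    return GanLossReport(l_gan_G=l_gan_G, l_gan_F=l_gan_F, l_cyc=l_cyc)


def _gen_direction_step(gen, inv, disc, batch, opt_gen, opt_inv):
    """One generator-side update for a single translation direction.

    Minimizes -log D(gen(x)) + ||inv(gen(x)) - x||_1 w.r.t. gen and inv.
    """
    n = batch.shape[0]
    y_hat = gen.forward(batch)
    # cycle branch: L1 norm per image, mean over the batch
    x_rec = inv.forward(y_hat)
    d_rec = np.sign(x_rec - batch) / n
    d_yhat_cycle = inv.backward(d_rec)
    # adversarial branch (non-saturating): d/dp of -mean log p = -1/(n p)
    p = disc.forward(y_hat)
    dp = -1.0 / (np.clip(p, _EPS, None) * n)
    d_yhat_adv = disc.backward(dp)
    disc.net.zero_grad()                 # adversarial pass must not train D
    gen.backward(d_yhat_cycle + d_yhat_adv)
    opt_inv.step()
    opt_inv.zero_grad()
    opt_gen.step()
    opt_gen.zero_grad()


def _gen_direction_step_lsgan(gen, inv, disc, batch, opt_gen, opt_inv):
    n = batch.shape[0]
    y_hat = gen.forward(batch)
    x_rec = inv.forward(y_hat)
    d_rec = np.sign(x_rec - batch) / n
    d_yhat_cycle = inv.backward(d_rec)
    p = disc.forward(y_hat)
    dp = 2.0 * (p - 1.0) / n
    d_yhat_adv = disc.backward(dp)
    disc.net.zero_grad()
    gen.backward(d_yhat_cycle + d_yhat_adv)
    opt_inv.step()
    opt_inv.zero_grad()
    opt_gen.step()
    opt_gen.zero_grad()


def _disc_step(disc, real, fake, opt, loss_type):
    opt.zero_grad()
    n_r, n_f = real.shape[0], fake.shape[0]
    p_real = disc.forward(real)
    if loss_type == "log":
        dp = -1.0 / (np.clip(p_real, _EPS, None) * n_r)      # maximize log D(real)
    else:
        dp = 2.0 * (p_real - 1.0) / n_r
    disc.backward(dp)
    p_fake = disc.forward(fake)
    if loss_type == "log":
        dp = 1.0 / (np.clip(1.0 - p_fake, _EPS, None) * n_f)  # maximize log(1 - D(fake))
    else:
        dp = 2.0 * p_fake / n_f
    disc.backward(dp)
    opt.step()
    opt.zero_grad()


def train_cyclegan(manifest_x: DatasetManifest, manifest_y: DatasetManifest,
                   epochs: int = 50, seed: int = 0, image_size: int | None = None,
                   batch_size: int = 8, lr: float = 2e-4,
                   loss_type: str = "log") -> GanSystem:
    """Alternating minimax training of the two translation directions.

    Per-batch schedule: update D_X and D_Y on real/fake pairs, then update
    (G, F) through both the adversarial and cycle branches. The printed
    losses (Eq.-form) are logged each epoch on a fixed probe batch.
    """
    if len(manifest_x) == 0 or len(manifest_y) == 0:
        raise ParameterError("both domains must be nonempty")
    if loss_type not in ("log", "lsgan"):
        raise ParameterError(f"loss_type must be 'log' or 'lsgan', got {loss_type!r}")
    x_all = manifest_x.images()
    y_all = manifest_y.images()
    image_size = image_size or x_all.shape[-1]

    rng = np.random.default_rng(seed)
    G = ResidualGenerator(image_size, rng=np.random.default_rng(seed + 10))
    F = ResidualGenerator(image_size, rng=np.random.default_rng(seed + 11))
    D_X = PatchDiscriminator(image_size, rng=np.random.default_rng(seed + 12))
    D_Y = PatchDiscriminator(image_size, rng=np.random.default_rng(seed + 13))
    system = GanSystem(G=G, F=F, D_X=D_X, D_Y=D_Y, image_size=image_size, seed=seed)

    opt_G = Adam(G.params(), lr=lr)
    opt_F = Adam(F.params(), lr=lr)
    opt_DX = Adam(D_X.params(), lr=lr)
    opt_DY = Adam(D_Y.params(), lr=lr)

    probe_x = x_all[:min(8, len(x_all))]
    probe_y = y_all[:min(8, len(y_all))]

    gen_step = _gen_direction_step if loss_type == "log" else _gen_direction_step_lsgan
    n_batches = max(1, min(len(x_all), len(y_all)) // batch_size)
    for epoch in range(epochs):
        xi = rng.permutation(len(x_all))
        yi = rng.permutation(len(y_all))
        for b in range(n_batches):
            bx = x_all[xi[b * batch_size:(b + 1) * batch_size]]
            by = y_all[yi[b * batch_size:(b + 1) * batch_size]]
            if bx.size == 0 or by.size == 0:
                continue
            _disc_step(D_Y, by, G(bx), opt_DY, loss_type)
            _disc_step(D_X, bx, F(by), opt_DX, loss_type)
            gen_step(G, F, D_Y, bx, opt_G, opt_F)
            gen_step(F, G, D_X, by, opt_F, opt_G)
        report = cyclegan_losses(system, probe_x, probe_y)
        system.loss_history.append(report)
        gx = G(probe_x)
        if float(np.std(gx - probe_x)) < 1e-8 and epoch > epochs // 2:
            logger.warning("possible mode collapse: generator delta is constant")
    return system


def difference_map(system_or_gen, images: np.ndarray, direction: str = "neg2pos") -> np.ndarray:
    """Signed per-pixel G(x) - x (or F(y) - y) averaged over a batch."""
    gen = system_or_gen
    if isinstance(system_or_gen, GanSystem):
        gen = system_or_gen.G if direction == "neg2pos" else system_or_gen.F
    images = np.asarray(images, dtype=np.float64)
    if images.ndim == 3:
        images = images[:, None]
    out = gen(images)
    return (out - images)[:, 0].mean(axis=0)


def classifier_flip_rate(classifier, images: np.ndarray, direction: str,
                         transform) -> tuple[float, float]:
    """Fraction of transformed images predicted as the *target* class.

    ``transform`` is a GanSystem (G or F picked by ``direction``) or any
    callable mapping one 2-D image to another. Returns
    ``(flip_rate, mean_delta_log_odds)`` where the delta is signed toward
    the target class.
    """
    images = np.asarray(images, dtype=np.float64)
    if images.ndim == 2:
        images = images[None]
    if images.shape[0] == 0:
        raise ParameterError("image set must be nonempty")
    if direction not in ("neg2pos", "pos2neg"):
        raise ParameterError(f"direction must be 'neg2pos' or 'pos2neg', got {direction!r}")

    if isinstance(transform, GanSystem):
        gen = transform.G if direction == "neg2pos" else transform.F
        transformed = gen(images[:, None])[:, 0]
    else:
        transformed = np.stack([np.asarray(transform(img)) for img in images])

    node = getattr(classifier, "covid_node", 0)
    z_before = classifier.logits(images)[:, node]
    z_after = classifier.logits(transformed)[:, node]
    if direction == "neg2pos":
        flips = z_after > 0.0
        mean_delta = float(np.mean(z_after - z_before))
    else:
        flips = z_after < 0.0
        mean_delta = float(np.mean(z_before - z_after))
    return float(np.mean(flips)), mean_delta
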