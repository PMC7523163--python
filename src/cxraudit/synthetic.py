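"""Two-source confounded synthetic radiograph generator.

The generator emulates the statistical structure that makes shortcut
learning possible when a classification dataset is assembled from one
predominantly-negative and one predominantly-positive image repository:

* **source-specific spurious features** — a laterality-marker glyph whose
  shape and canonical position differ by source, a border band of altered
  radiopacity (a patient-positioning / AP-vs-PA proxy), a vertical offset of
  the shoulder band, and optional annotation stamps;
* **a genuine pathology signal** — smooth additive opacity blobs rendered
  bilaterally inside the lung fields of truly positive cases;
* **a tunable confound strength** ``rho`` coupling source identity to the
  COVID label, with ``rho = 1`` the worst case (every positive from one
  source, every negative from the other) and ``rho = 0`` independence.

Anatomy is deliberately schematic (elliptical lung fields, a bright
shoulder band, a cardiac silhouette, a diaphragm shelf): the audit only
needs region semantics, not radiographic realism.

All randomness flows from one integer seed; each record renders from its
own ``default_rng([seed, index])`` substream, so datasets are reproducible
record-by-record.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .data import DatasetManifest, ImageRecord
from .errors import GeometryError, ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "SourceProfile",
    "PathologySpec",
    "GenerationConfig",
    "RecordParams",
    "generate_dataset",
    "render_image",
    "default_profiles",
    "marker_only_profiles",
    "signal_only_profiles",
    "lung_field_mask",
    "marker_region",
    "shoulder_region",
    "oracle_marker_transform",
    "GLYPH_L", "GLYPH_R", "GLYPH_ARROW",
]


def _glyph(rows: list[str]) -> np.ndarray:
    return np.array([[c == "#" for c in row] for row in rows], dtype=bool)


GLYPH_L = _glyph([
    "#....",
    "#....",
    "#....",
    "#....",
    "#....",
    "#....",
    "#####",
])

GLYPH_R = _glyph([
    "####.",
    "#...#",
    "#...#",
    "####.",
    "#.#..",
    "#..#.",
    "#...#",
])

GLYPH_ARROW = _glyph([
    "...#...",
    "..###..",
    ".#.#.#.",
    "...#...",
    "...#...",
])


@dataclass
class SourceProfile:
    """Rendering style of one image source (hospital / repository analogue)."""

    source_id: str
    marker_glyph: np.ndarray = field(default_factory=lambda: GLYPH_L.copy())
    marker_row: int = 4
    marker_col: int = 52
    marker_jitter: int = 1
    marker_intensity: float = 0.95
    border_band_intensity: float = 0.0
    border_band_width: int = 4
    shoulder_offset: int = 0
    annotation_rate: float = 0.0
    base_noise_sd: float = 0.04

    def __post_init__(self):
        self.marker_glyph = np.asarray(self.marker_glyph, dtype=bool)
        if self.marker_glyph.size == 0 or not self.marker_glyph.any():
            raise ParameterError("marker glyph mask must be nonempty")
        if self.marker_jitter < 0 or self.border_band_width < 0:
            raise ParameterError("jitter and band width must be >= 0")
        if not 0.0 <= self.annotation_rate <= 1.0:
            raise ParameterError("annotation_rate must lie in [0, 1]")
        if self.base_noise_sd < 0:
            raise ParameterError("base_noise_sd must be nonnegative")
        if not -1.0 <= self.border_band_intensity <= 1.0:
            raise ParameterError("border_band_intensity must lie in [-1, 1]")


@dataclass
class PathologySpec:
    """Diffuse lung-field opacity carried by truly positive cases."""

    opacity_effect: float = 0.30
    blob_count: int = 3
    blob_scale: float = 3.5          # Gaussian sigma in pixels at 64 px
    bilateral: bool = True

    def __post_init__(self):
        if self.opacity_effect < 0:
            raise ParameterError("opacity_effect must be >= 0")
        if self.blob_count < 1 or self.blob_scale <= 0:
            raise ParameterError("blob_count and blob_scale must be positive")


_DEFAULT_PROJ = {
    "a": {"PA": 0.85, "AP": 0.05, "lateral": 0.04, "AP-supine": 0.03, "unknown": 0.03},
    "b": {"AP": 0.75, "PA": 0.15, "lateral": 0.04, "AP-supine": 0.03, "unknown": 0.03},
}
_DEFAULT_SEX = {"a": {"A": 0.55, "B": 0.45}, "b": {"A": 0.45, "B": 0.55}}


@dataclass
class GenerationConfig:
    image_size: int = 64
    n_per_source: int = 400
    confound_correlation: float = 1.0     # rho: 0 = independent, 1 = worst case
    pathology_penetrance: float = 1.0
    labeling_rule: str = "latent_status"  # or "radiographic_evidence"
    seed: int = 0
    projection_dist_a: dict[str, float] | None = None
    projection_dist_b: dict[str, float] | None = None
    sex_dist_a: dict[str, float] | None = None
    sex_dist_b: dict[str, float] | None = None
    projection_cue: str = "none"          # none | border_frame | band_topbottom | band_leftright
    sex_cue: str = "none"                 # none | cardiac

    def __post_init__(self):
        if not 0.0 <= self.confound_correlation <= 1.0:
            raise ParameterError("confound_correlation must lie in [0, 1]")
        if not 0.0 <= self.pathology_penetrance <= 1.0:
            raise ParameterError("pathology_penetrance must lie in [0, 1]")
        if self.image_size < 32:
            raise ParameterError("image_size must be >= 32")
        if self.labeling_rule not in ("latent_status", "radiographic_evidence"):
            raise ParameterError(f"unknown labeling_rule {self.labeling_rule!r}")
        if self.projection_cue not in ("none", "border_frame", "band_topbottom", "band_leftright"):
            raise ParameterError(f"unknown projection_cue {self.projection_cue!r}")
        if self.sex_cue not in ("none", "cardiac"):
            raise ParameterError(f"unknown sex_cue {self.sex_cue!r}")


@dataclass
class RecordParams:
    """Per-record rendering inputs derived during dataset generation."""

    image_size: int
    has_signal: int = 0
    projection: str = "PA"
    sex_analogue: str = "A"
    projection_cue: str = "none"
    sex_cue: str = "none"


# --------------------------------------------------------------- geometry

def _ellipse_mask(size: int, cy: float, cx: float, ry: float, rx: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def lung_field_mask(size: int) -> np.ndarray:
    """Boolean mask of the two elliptical lung fields."""
    left = _ellipse_mask(size, 0.52 * size, 0.30 * size, 0.24 * size, 0.14 * size)
    right = _ellipse_mask(size, 0.52 * size, 0.70 * size, 0.24 * size, 0.14 * size)
    return left | right


def _single_lung_masks(size: int) -> tuple[np.ndarray, np.ndarray]:
    return (
        _ellipse_mask(size, 0.52 * size, 0.30 * size, 0.24 * size, 0.14 * size),
        _ellipse_mask(size, 0.52 * size, 0.70 * size, 0.24 * size, 0.14 * size),
    )


def _shoulder_top_row(profile: SourceProfile, size: int) -> int:
    return max(0, int(round(0.14 * size)) - profile.shoulder_offset)


def marker_region(profile: SourceProfile, image_size: int, dilate: int = 2):
    """Bounding region of the profile's glyph (jitter + dilation margin)."""
    from .behavioral import PatchRegion

    gh, gw = profile.marker_glyph.shape
    pad = profile.marker_jitter + dilate
    top = max(0, profile.marker_row - pad)
    left = max(0, profile.marker_col - pad)
    bottom = min(image_size, profile.marker_row + gh + pad)
    right = min(image_size, profile.marker_col + gw + pad)
    return PatchRegion(top=top, left=left, height=bottom - top, width=right - left)


def shoulder_region(profile: SourceProfile, image_size: int):
    """Central portion of the shoulder band, for relocation tests."""
    from .behavioral import PatchRegion

    r0 = _shoulder_top_row(profile, image_size)
    t = max(2, int(round(0.06 * image_size)))
    w = image_size // 4
    left = (image_size - w) // 2
    return PatchRegion(top=r0, left=left, height=t, width=w)


def _stamp(canvas: np.ndarray, glyph: np.ndarray, row: int, col: int,
           intensity: float) -> None:
    size = canvas.shape[0]
    gh, gw = glyph.shape
    r = min(max(row, 0), size - gh)
    c = min(max(col, 0), size - gw)
    if (r, c) != (row, col):
        logger.debug("glyph placement clamped from (%d, %d) to (%d, %d)", row, col, r, c)
    patch = canvas[r:r + gh, c:c + gw]
    patch[glyph] = intensity


# --------------------------------------------------------------- rendering

def render_image(params: RecordParams, profile: SourceProfile,
                 pathology: PathologySpec, rng: np.random.Generator) -> np.ndarray:
    """Render one schematic radiograph. Deterministic given the rng state.

    Layer order: anatomy, shoulder band, attribute cues, pathology blobs,
    border band, marker glyph, optional annotation, Gaussian noise, clip.
    """
    size = params.image_size
    gh, gw = profile.marker_glyph.shape
    if gh + profile.marker_jitter > size or gw + profile.marker_jitter > size:
        raise GeometryError("marker glyph (plus jitter) larger than image")

    img = np.full((size, size), 0.32)
    left_lung, right_lung = _single_lung_masks(size)
    img[left_lung | right_lung] -= 0.18
    # cardiac silhouette
    heart = _ellipse_mask(size, 0.62 * size, 0.56 * size, 0.14 * size, 0.11 * size)
    img[heart] += 0.10
    if params.sex_cue == "cardiac" and params.sex_analogue == "B":
        big = _ellipse_mask(size, 0.62 * size, 0.56 * size, 0.16 * size, 0.13 * size)
        img[big] += 0.08
    # diaphragm shelf
    img[int(round(0.78 * size)):, :] += 0.12
    # shoulder band
    r0 = _shoulder_top_row(profile, size)
    t = max(2, int(round(0.06 * size)))
    img[r0:r0 + t, :] += 0.22

    # projection cue (shared across sources when both configs use the same style)
    if params.projection == "AP" and params.projection_cue != "none":
        w = max(2, size // 21)
        if params.projection_cue == "border_frame":
            frame = np.zeros((size, size), dtype=bool)
            frame[:w, :] = frame[-w:, :] = True
            frame[:, :w] = frame[:, -w:] = True
            img[frame] += 0.12
        elif params.projection_cue == "band_topbottom":
            img[:w, :] += 0.15
            img[-w:, :] += 0.15
        elif params.projection_cue == "band_leftright":
            img[:, :w] += 0.15
            img[:, -w:] += 0.15

    # genuine pathology: smooth opacity blobs constrained to the lung fields
    if params.has_signal:
        lungs = [left_lung, right_lung] if pathology.bilateral else \
            [(left_lung, right_lung)[rng.integers(0, 2)]]
        yy, xx = np.mgrid[0:size, 0:size]
        for lung in lungs:
            rows, cols = np.nonzero(lung)
            for _ in range(pathology.blob_count):
                j = rng.integers(0, rows.size)
                cy, cx = rows[j], cols[j]
                bump = np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2)
                                / (2.0 * pathology.blob_scale ** 2)))
                img += pathology.opacity_effect * bump * lung

    # border radiopacity band
    if profile.border_band_intensity != 0.0 and profile.border_band_width > 0:
        w = profile.border_band_width
        frame = np.zeros((size, size), dtype=bool)
        frame[:w, :] = frame[-w:, :] = True
        frame[:, :w] = frame[:, -w:] = True
        img[frame] += profile.border_band_intensity

    # laterality marker
    if profile.marker_jitter > 0:
        dr = int(rng.integers(-profile.marker_jitter, profile.marker_jitter + 1))
        dc = int(rng.integers(-profile.marker_jitter, profile.marker_jitter + 1))
    else:
        dr = dc = 0
    _stamp(img, profile.marker_glyph, profile.marker_row + dr,
           profile.marker_col + dc, profile.marker_intensity)

    # annotation stamp (arrows/text unique to figure-scraped repositories)
    if profile.annotation_rate > 0 and rng.random() < profile.annotation_rate:
        ah, aw = GLYPH_ARROW.shape
        ar = int(rng.integers(size // 3, size - ah))
        ac = int(rng.integers(4, size - aw - 4))
        _stamp(img, GLYPH_ARROW, ar, ac, 0.9)

    if profile.base_noise_sd > 0:
        img = img + rng.normal(0.0, profile.base_noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0)


# ------------------------------------------------------------ profile kits

def default_profiles(image_size: int = 64) -> tuple[SourceProfile, SourceProfile]:
    """Two sources in the style of a negative-only hospital archive (A) and a
    positive-heavy scraped repository (B): different glyphs/corners, brighter
    borders, raised shoulders, and occasional annotations in B."""
    s = image_size / 64.0
    a = SourceProfile(
        source_id="hospital-a",
        marker_glyph=GLYPH_L, marker_row=int(4 * s), marker_col=int(52 * s),
        border_band_intensity=-0.06, border_band_width=max(2, int(4 * s)),
        shoulder_offset=0, annotation_rate=0.0,
    )
    b = SourceProfile(
        source_id="repo-b",
        marker_glyph=GLYPH_R, marker_row=int(4 * s), marker_col=int(6 * s),
        border_band_intensity=0.20, border_band_width=max(2, int(4 * s)),
        shoulder_offset=int(5 * s), annotation_rate=0.3,
    )
    return a, b


def marker_only_profiles(image_size: int = 64) -> tuple[SourceProfile, SourceProfile]:
    """Sources identical except for the laterality-marker glyph and corner,
    isolating the marker as the sole spurious cue."""
    s = image_size / 64.0
    a = SourceProfile(source_id="hospital-a", marker_glyph=GLYPH_L,
                      marker_row=int(4 * s), marker_col=int(52 * s))
    b = SourceProfile(source_id="repo-b", marker_glyph=GLYPH_R,
                      marker_row=int(4 * s), marker_col=int(6 * s))
    return a, b


def signal_only_profiles(image_size: int = 64) -> tuple[SourceProfile, SourceProfile]:
    """Sources rendered identically (same glyph, border, shoulders) so the
    genuine lung opacity is the only learnable class difference."""
    s = image_size / 64.0
    a = SourceProfile(source_id="hospital-a", marker_glyph=GLYPH_L,
                      marker_row=int(4 * s), marker_col=int(52 * s))
    b = replace(a, source_id="hospital-b")
    return a, b


# ------------------------------------------------------------- generation

def _draw(rng: np.random.Generator, dist: dict[str, float]) -> str:
    keys = list(dist)
    probs = np.array([dist[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return keys[rng.choice(len(keys), p=probs)]


def generate_dataset(config: GenerationConfig, profile_a: SourceProfile,
                     profile_b: SourceProfile,
                     pathology: PathologySpec | None = None) -> DatasetManifest:
    """Generate ``2 * n_per_source`` records with confound strength rho.

    Half the records are latently positive. A record is placed in its
    label-determined source (positives -> B, negatives -> A) with
    probability ``(1 + rho) / 2``: at rho=1 the assignment is deterministic
    (worst-case confounding), at rho=0 source and label are independent.
    Positives render genuine pathology with probability
    ``pathology_penetrance``; under the ``radiographic_evidence`` labeling
    rule only records that actually rendered signal are labelled positive.
    """
    if profile_a.source_id == profile_b.source_id:
        raise ParameterError("source profiles must have distinct source_ids")
    pathology = pathology or PathologySpec()
    size = config.image_size
    for prof in (profile_a, profile_b):
        gh, gw = prof.marker_glyph.shape
        if gh + prof.marker_jitter > size or gw + prof.marker_jitter > size:
            raise GeometryError(f"glyph of {prof.source_id} does not fit a "
                                f"{size}px image")

    n_total = 2 * config.n_per_source
    master = np.random.default_rng(config.seed)
    latent = np.zeros(n_total, dtype=int)
    latent[:config.n_per_source] = 1
    master.shuffle(latent)
    p_match = (1.0 + config.confound_correlation) / 2.0
    match = master.random(n_total) < p_match

    proj_dists = {
        profile_a.source_id: config.projection_dist_a or _DEFAULT_PROJ["a"],
        profile_b.source_id: config.projection_dist_b or _DEFAULT_PROJ["b"],
    }
    sex_dists = {
        profile_a.source_id: config.sex_dist_a or _DEFAULT_SEX["a"],
        profile_b.source_id: config.sex_dist_b or _DEFAULT_SEX["b"],
    }
    profiles = {profile_a.source_id: profile_a, profile_b.source_id: profile_b}

    records = []
    for i in range(n_total):
        determined = profile_b.source_id if latent[i] else profile_a.source_id
        other = profile_a.source_id if latent[i] else profile_b.source_id
        source = determined if match[i] else other
        rng = np.random.default_rng([config.seed, i])
        has_signal = int(latent[i] and rng.random() < config.pathology_penetrance)
        covid = int(latent[i]) if config.labeling_rule == "latent_status" else has_signal
        projection = _draw(rng, proj_dists[source])
        sex = _draw(rng, sex_dists[source])
        aux = (rng.random(14) < 0.05).astype(int)
        aux[8] = has_signal    # Consolidation tracks the rendered opacity
        params = RecordParams(image_size=size, has_signal=has_signal,
                              projection=projection, sex_analogue=sex,
                              projection_cue=config.projection_cue,
                              sex_cue=config.sex_cue)
        img = render_image(params, profiles[source], pathology, rng)
        records.append(ImageRecord(
            image=img,
            record_id=f"r{i:05d}",
            patient_id=f"{source}-p{i:05d}",
            source_id=source,
            covid_label=covid,
            aux_labels=aux,
            projection=projection,
            sex_analogue=sex,
            has_signal=has_signal,
        ))
    return DatasetManifest(records)


# ----------------------------------------------------- oracle counterfactual

def oracle_marker_transform(profile_from: SourceProfile, profile_to: SourceProfile,
                            image_size: int, fill: float = 0.32) -> Callable[[np.ndarray], np.ndarray]:
    """Ground-truth marker counterfactual: erase ``profile_from``'s glyph
    region (filled with the canvas base intensity) and stamp
    ``profile_to``'s glyph at its canonical position.

    Used as the reference transform for classifier-flip evaluation,
    independent of any trained generator.
    """
    reg_from = marker_region(profile_from, image_size, dilate=1)

    def transform(image: np.ndarray) -> np.ndarray:
        out = np.array(image, dtype=np.float64, copy=True)
        sl = reg_from.slices
        out[sl] = fill
        _stamp(out, profile_to.marker_glyph, profile_to.marker_row,
               profile_to.marker_col, profile_to.marker_intensity)
        return out

    return transform
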