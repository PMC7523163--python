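"""Shared fixtures: synthetic datasets and trained models reused across tests.

Everything is generated programmatically at session start; the expensive
trained-model fixtures are session-scoped so each is built exactly once.
"""

from __future__ import annotations

import numpy as np
import pytest

import cxraudit as cx
from cxraudit.models import TrainHyperparams

HALF_PROJ = {"PA": 0.5, "AP": 0.5}


def make_dataset(size, n_per_source, rho, profiles, pathology, seed, **kwargs):
    cfg = cx.GenerationConfig(
        image_size=size, n_per_source=n_per_source, confound_correlation=rho,
        seed=seed, projection_dist_a=HALF_PROJ, projection_dist_b=HALF_PROJ,
        **kwargs)
    return cx.generate_dataset(cfg, profiles[0], profiles[1], pathology)


@pytest.fixture(scope="session")
def marker_bundle():
    """Worst-case confounded dataset whose only cue is the laterality marker,
    with a trained small CNN and a decorrelated external set (64 px)."""
    size = 64
    profiles = cx.marker_only_profiles(size)
    nopath = cx.PathologySpec(opacity_effect=0.0)
    manifest = make_dataset(size, 400, 1.0, profiles, nopath, seed=11)
    split = cx.assign_folds(manifest, (0.1, 0.1), seed=11)
    handle = cx.train_classifier(manifest, split, arch="simple-cnn",
                                 hp=TrainHyperparams(max_epochs=10), seed=11)
    external = make_dataset(size, 150, 0.0, profiles, nopath, seed=99)
    negatives = np.stack([r.image for r in manifest if r.covid_label == 0][:64])
    background = cx.BackgroundSet(negatives, description="train negatives",
                                  background_id="train-negatives")
    return {
        "size": size, "profiles": profiles, "manifest": manifest,
        "split": split, "handle": handle, "external": external,
        "background": background, "pathology": nopath,
    }


@pytest.fixture(scope="session")
def signal_bundle():
    """Identically rendered sources where genuine bilateral lung opacity is
    the only class difference, with a trained small CNN (64 px)."""
    size = 64
    profiles = cx.signal_only_profiles(size)
    pathology = cx.PathologySpec(opacity_effect=0.30)
    manifest = make_dataset(size, 400, 1.0, profiles, pathology, seed=21)
    split = cx.assign_folds(manifest, (0.1, 0.1), seed=21)
    handle = cx.train_classifier(manifest, split, arch="simple-cnn",
                                 hp=TrainHyperparams(max_epochs=10), seed=21)
    negatives = np.stack([r.image for r in manifest if r.covid_label == 0][:64])
    background = cx.BackgroundSet(negatives, background_id="train-negatives")
    return {
        "size": size, "profiles": profiles, "manifest": manifest,
        "split": split, "handle": handle, "background": background,
        "pathology": pathology,
    }


@pytest.fixture(scope="session")
def gan_bundle():
    """CycleGAN trained between two domains that differ only by the marker
    glyph (32 px desk scale)."""
    size = 32
    profiles = cx.marker_only_profiles(size)
    nopath = cx.PathologySpec(opacity_effect=0.0)
    manifest = make_dataset(size, 64, 1.0, profiles, nopath, seed=101)
    negs = cx.DatasetManifest([r for r in manifest if r.covid_label == 0])
    poss = cx.DatasetManifest([r for r in manifest if r.covid_label == 1])
    system = cx.train_cyclegan(negs, poss, epochs=60, seed=1, lr=1e-3)
    return {"size": size, "profiles": profiles, "negatives": negs,
            "positives": poss, "system": system, "pathology": nopath}


def marker_union_mask(profiles, size, dilate):
    mask = np.zeros((size, size), dtype=bool)
    for prof in profiles:
        mask[cx.marker_region(prof, size, dilate=dilate).slices] = True
    return mask
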