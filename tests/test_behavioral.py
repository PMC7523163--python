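"""Patch-swap mechanics, the empirical p-value estimator, and the planted
shortcut perturbation experiments."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cxraudit as cx
from cxraudit.attribution import FunctionModel
from cxraudit.behavioral import (PatchRegion, empirical_p_value,
                                 run_reposition_test, run_swap_test, swap_patches)
from cxraudit.errors import GeometryError, ParameterError
from cxraudit.models import TrainHyperparams

from conftest import make_dataset


class TestSwapPatches:
    def test_identical_content_swap_is_a_no_op(self):
        rng = np.random.default_rng(0)
        img = rng.random((8, 8))
        a, b = img.copy(), img.copy()
        reg = PatchRegion(2, 2, 3, 3)
        out_a, out_b = swap_patches(a, b, reg, reg)
        assert np.array_equal(out_a, a) and np.array_equal(out_b, b)

    def test_double_swap_recovers_originals(self):
        rng = np.random.default_rng(1)
        a, b = rng.random((8, 8)), rng.random((8, 8))
        ra, rb = PatchRegion(0, 0, 2, 4), PatchRegion(5, 3, 2, 4)
        m_a, m_b = swap_patches(a, b, ra, rb)
        back_a, back_b = swap_patches(m_a, m_b, ra, rb)
        assert np.array_equal(back_a, a) and np.array_equal(back_b, b)

    def test_four_by_four_hand_construction(self):
        a = np.arange(16.0).reshape(4, 4)
        b = 100 + np.arange(16.0).reshape(4, 4)
        ra, rb = PatchRegion(0, 0, 2, 2), PatchRegion(2, 2, 2, 2)
        m_a, m_b = swap_patches(a, b, ra, rb)
        expect_a = a.copy()
        expect_a[0:2, 0:2] = [[110, 111], [114, 115]]
        expect_b = b.copy()
        expect_b[2:4, 2:4] = [[0, 1], [4, 5]]
        assert np.array_equal(m_a, expect_a) and np.array_equal(m_b, expect_b)

    def test_dimension_mismatch_rejected(self):
        a, b = np.zeros((8, 8)), np.zeros((8, 8))
        with pytest.raises(GeometryError):
            swap_patches(a, b, PatchRegion(0, 0, 2, 2), PatchRegion(0, 0, 3, 2))

    def test_out_of_bounds_region_rejected(self):
        with pytest.raises(GeometryError):
            PatchRegion(0, 0, 3, 3).check_within((2, 2))


class TestEmpiricalPValue:
    def test_floor_at_one_thousand_null_draws(self):
        # no null modification exceeds the observed effect
        null = np.zeros(1000)
        p = empirical_p_value(5.0, null, "increase")
        assert p == pytest.approx(1 / 1001)
        assert p == pytest.approx(9.99e-4, rel=1e-3)

    def test_ceiling_when_all_nulls_exceed(self):
        assert empirical_p_value(0.0, np.ones(10), "increase") == 1.0

    def test_mid_count_brute_force(self):
        assert empirical_p_value(3.5, [1, 2, 3, 4, 5], "increase") == 0.5

    def test_ties_are_not_counted(self):
        assert empirical_p_value(2.0, [2.0, 2.0, 2.0], "increase") == 0.25
        assert empirical_p_value(2.0, [2.0, 2.0, 2.0], "decrease") == 0.25

    def test_decrease_direction_counts_more_negative_nulls(self):
        assert empirical_p_value(-1.0, [-2.0, -0.5, 0.0], "decrease") == 0.5

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(obs=st.floats(-10, 10), shift=st.floats(0.01, 5),
           null=st.lists(st.floats(-10, 10), min_size=1, max_size=50))
    def test_bounds_and_monotonicity(self, obs, shift, null):
        p = empirical_p_value(obs, null, "increase")
        n = len(null)
        assert 1 / (n + 1) <= p <= 1.0
        assert empirical_p_value(obs + shift, null, "increase") <= p


def region_blind_model(size, region):
    """Linear model whose weights vanish inside ``region``."""
    rng = np.random.default_rng(42)
    w = rng.normal(0, 1.0, size=(size, size))
    w[region.slices] = 0.0
    return FunctionModel(f=lambda x: (x * w).sum(axis=(1, 2)),
                         grad=lambda x: np.broadcast_to(w, x.shape).copy())


class TestSwapExperiment:
    def test_same_seed_reproduces_null_exactly(self, marker_bundle):
        clf = marker_bundle["handle"].classifier
        m = marker_bundle["manifest"]
        pos = next(r for r in m if r.covid_label == 1)
        neg = next(r for r in m if r.covid_label == 0)
        reg = cx.marker_region(marker_bundle["profiles"][1], 64, dilate=2)
        r1 = run_swap_test(clf, pos.image, neg.image, reg, reg, n=50, seed=9)
        r2 = run_swap_test(clf, pos.image, neg.image, reg, reg, n=50, seed=9)
        assert np.array_equal(r1[0].null_deltas, r2[0].null_deltas)
        assert np.array_equal(r1[1].null_deltas, r2[1].null_deltas)

    def test_region_blind_model_sees_no_targeted_effect(self):
        size = 32
        reg = PatchRegion(2, 2, 8, 8)
        model = region_blind_model(size, reg)
        rng = np.random.default_rng(3)
        pos, neg = rng.random((size, size)), rng.random((size, size))
        res_pos, res_neg = run_swap_test(model, pos, neg, reg, reg, n=200, seed=1)
        assert res_pos.delta_observed == pytest.approx(0.0, abs=1e-12)
        assert res_neg.delta_observed == pytest.approx(0.0, abs=1e-12)
        # against a continuous null, a zero effect is unremarkable
        assert 0.05 < res_pos.p and 0.05 < res_neg.p

    def test_marker_swap_flips_confounded_model(self, marker_bundle):
        clf = marker_bundle["handle"].classifier
        m = marker_bundle["manifest"]
        pos = next(r for r in m if r.covid_label == 1)
        neg = next(r for r in m if r.covid_label == 0)
        reg = cx.marker_region(marker_bundle["profiles"][1], 64, dilate=2)
        res_pos, res_neg = run_swap_test(clf, pos.image, neg.image, reg, reg,
                                         n=1000, seed=2)
        assert res_neg.delta_observed > 0          # gained the positive marker
        assert res_neg.p <= 0.05
        assert res_pos.delta_observed < 0          # lost it
        assert res_pos.p <= 0.05

    def test_result_invariants_hold(self, marker_bundle):
        clf = marker_bundle["handle"].classifier
        m = marker_bundle["manifest"]
        pos = next(r for r in m if r.covid_label == 1)
        neg = next(r for r in m if r.covid_label == 0)
        reg = cx.marker_region(marker_bundle["profiles"][1], 64, dilate=2)
        for res in run_swap_test(clf, pos.image, neg.image, reg, reg, n=40, seed=5):
            assert res.p == pytest.approx((res.r + 1) / (res.n + 1))
            assert 1 / (res.n + 1) <= res.p <= 1.0
            assert len(res.null_deltas) == res.n


class TestRepositionExperiment:
    def test_zero_null_size_rejected(self):
        model = region_blind_model(32, PatchRegion(0, 0, 1, 1))
        with pytest.raises(ParameterError):
            run_reposition_test(model, np.zeros((32, 32)),
                                PatchRegion(4, 4, 4, 4), [(0, 0)], n=0)

    def test_target_blind_model_sees_no_effect_at_all(self):
        # every modification (observed and null) lands on the targets; a
        # model blind to them registers exactly zero everywhere, and the
        # strict-count estimator collapses to its floor
        size = 32
        top = PatchRegion(0, 0, 6, size)
        model = region_blind_model(size, top)
        img = np.random.default_rng(6).random((size, size))
        src = PatchRegion(8, 10, 4, 8)
        res = run_reposition_test(model, img, src, [(0, 0), (0, size - 8)],
                                  n=200, seed=3)
        assert res.delta_observed == pytest.approx(0.0, abs=1e-12)
        assert np.all(res.null_deltas == 0.0)
        assert res.p == pytest.approx(1 / 201)

    def test_unspecific_source_region_gives_unremarkable_p(self, marker_bundle):
        # relocating a random (non-confound) patch is one more draw from
        # the null, so its p should sit in the body of the distribution
        clf = marker_bundle["handle"].classifier
        neg = next(r for r in marker_bundle["manifest"] if r.covid_label == 0)
        rng = np.random.default_rng(8)
        ps = []
        for rep in range(8):
            top, left = rng.integers(16, 44, size=2)
            src = PatchRegion(int(top), int(left), 4, 10)
            res = run_reposition_test(clf, neg.image, src,
                                      [(0, 0), (0, 54)], n=99, seed=100 + rep)
            ps.append(res.p)
        assert 0.15 < np.mean(ps) < 0.85

    def test_shoulder_confounded_model_detects_relocation(self):
        # sources differ only by shoulder height; relocating the shoulder
        # band to the top corners should raise the predicted log-odds
        from dataclasses import replace
        size = 64
        a, _ = cx.signal_only_profiles(size)
        b = replace(a, source_id="raised", shoulder_offset=10)
        nopath = cx.PathologySpec(opacity_effect=0.0)
        m = make_dataset(size, 150, 1.0, (a, b), nopath, seed=23)
        split = cx.assign_folds(m, (0.2, 0.1), seed=23)
        handle = cx.train_classifier(m, split, arch="simple-cnn",
                                     hp=TrainHyperparams(max_epochs=8), seed=23)
        neg = next(r for r in m if r.covid_label == 0)
        src = cx.shoulder_region(a, size)
        targets = [(0, 0), (0, size - src.width)]
        res = run_reposition_test(handle.classifier, neg.image, src, targets,
                                  n=1000, seed=4)
        assert res.delta_observed > 0
        assert res.p <= 0.05
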