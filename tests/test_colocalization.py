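"""Pearson-above-threshold colocalization and Costes block randomization."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from voxcube.colocalization import (
    auto_thresholds,
    pearson_above_threshold,
    randomization_test,
)
from voxcube.segmentation import DegenerateHistogramError
from voxcube.stack_io import ValidationError


def pearson_oracle(a, b):
    """Textbook formula, computed term by term."""
    n = len(a)
    ma, mb = sum(a) / n, sum(b) / n
    num = sum((x - ma) * (y - mb) for x, y in zip(a, b))
    den = math.sqrt(
        sum((x - ma) ** 2 for x in a) * sum((y - mb) ** 2 for y in b)
    )
    return num / den


class TestPearsonAboveThreshold:
    def test_affine_relation_gives_r_of_one(self):
        a = np.linspace(0, 10, 50)
        assert pearson_above_threshold(a, 2 * a + 3, (0, 0)) == pytest.approx(1.0)

    def test_negated_relation_gives_minus_one(self):
        a = np.linspace(1, 10, 50)
        assert pearson_above_threshold(a, -a, (0, -100)) == pytest.approx(-1.0)

    def test_hand_listed_pairs_match_textbook_formula(self):
        a = [1.0, 4.0, 2.0, 9.0, 7.0]
        b = [3.0, 1.0, 8.0, 6.0, 5.0]
        r = pearson_above_threshold(np.array(a), np.array(b), (0.0, 0.0))
        assert r == pytest.approx(pearson_oracle(a, b), rel=1e-12)

    def test_selection_respects_thresholds(self):
        a = np.array([0.0, 0.0, 5.0, 6.0, 7.0])
        b = np.array([9.0, 1.0, 5.0, 6.0, 7.0])
        # a >= 5 or b >= 9 selects indices {0, 2, 3, 4}
        r = pearson_above_threshold(a, b, (5.0, 9.0))
        assert r == pytest.approx(
            pearson_oracle([0.0, 5.0, 6.0, 7.0], [9.0, 5.0, 6.0, 7.0]), rel=1e-12
        )

    def test_too_few_selected_voxels_raises(self):
        with pytest.raises(ValidationError):
            pearson_above_threshold(
                np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0]), (3.0, 99.0)
            )

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        st.floats(0.1, 50), st.floats(-100, 100),
        st.floats(0.1, 50), st.floats(-100, 100),
    )
    def test_invariance_under_positive_affine_transforms(self, sa, oa, sb, ob):
        rng = np.random.default_rng(12)
        a = rng.uniform(0, 100, 200)
        b = a + rng.normal(0, 20, 200)
        r0 = pearson_above_threshold(a, b, (-np.inf, -np.inf))
        r1 = pearson_above_threshold(
            sa * a + oa, sb * b + ob, (-np.inf, -np.inf)
        )
        assert r1 == pytest.approx(r0, abs=1e-9)


def costes_scan_oracle(a, b, n_steps=256):
    """Direct descending scan with an independently fitted TLS line."""
    a, b = np.asarray(a, float).ravel(), np.asarray(b, float).ravel()
    # orthogonal regression via PCA of the centered cloud
    xy = np.stack([a - a.mean(), b - b.mean()])
    _, vecs = np.linalg.eigh(np.cov(xy))
    vx, vy = vecs[:, -1]  # principal axis
    m = vy / vx
    c = b.mean() - m * a.mean()
    for ta in np.linspace(a.max(), a.min(), n_steps):
        tb = m * ta + c
        below = (a < ta) & (b < tb)
        if below.sum() < 2:
            return ta, tb
        x, y = a[below], b[below]
        if x.std() == 0 or y.std() == 0:
            return ta, tb
        if np.corrcoef(x, y)[0, 1] <= 0:
            return ta, tb
    return ta, tb


class TestAutoThresholds:
    def test_identical_channels_descend_to_the_low_end(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0, 100, 2000)
        ta, tb = auto_thresholds(a, a)
        assert ta <= np.quantile(a, 0.05)

    def test_independent_noise_stops_near_the_top(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(0, 100, 5000)
        b = rng.uniform(0, 100, 5000)
        ta, _ = auto_thresholds(a, b)
        assert ta >= np.quantile(a, 0.9)

    def test_matches_direct_scan_oracle(self):
        rng = np.random.default_rng(5)
        a = rng.uniform(0, 100, 3000)
        b = 0.5 * a + rng.normal(0, 30, 3000)
        ta, tb = auto_thresholds(a, b)
        ta_o, tb_o = costes_scan_oracle(a, b)
        step = (a.max() - a.min()) / 255
        assert abs(ta - ta_o) <= step + 1e-9
        assert abs(tb - tb_o) <= abs(tb_o) * 0.05 + step

    def test_two_point_toy_returns_upper_values(self):
        ta, tb = auto_thresholds(np.array([0.0, 10.0]), np.array([0.0, 10.0]))
        assert ta == pytest.approx(10.0)
        assert tb == pytest.approx(10.0)

    def test_constant_channel_raises(self):
        with pytest.raises(DegenerateHistogramError):
            auto_thresholds(np.full(10, 3.0), np.arange(10.0))


class TestRandomizationTest:
    def test_identical_channels_reach_the_minimum_p(self):
        rng = np.random.default_rng(6)
        vol = rng.uniform(0, 100, size=(4, 18, 18))
        res = randomization_test(vol, vol.copy(), seed=1)
        assert res.r_above_threshold == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 11)
        assert len(res.random_rs) == 10
        assert all(r <= 1.0 for r in res.random_rs)

    def test_block_shuffle_conserves_each_plane_histogram(self):
        from voxcube.colocalization import _block_shuffle_plane

        rng = np.random.default_rng(7)
        plane = rng.uniform(0, 10, size=(17, 23))  # ragged edges
        shuffled = _block_shuffle_plane(plane, 3, rng)
        assert not np.array_equal(shuffled, plane)
        np.testing.assert_array_equal(
            np.sort(shuffled.ravel()), np.sort(plane.ravel())
        )

    def test_independent_channels_give_roughly_uniform_p(self):
        rng = np.random.default_rng(8)
        ps = []
        for seed in range(40):
            a = rng.uniform(0, 100, size=(2, 12, 12))
            b = rng.uniform(0, 100, size=(2, 12, 12))
            ps.append(randomization_test(a, b, seed=seed).p_value)
        # p takes values in {1/11, ..., 11/11}; under independence the mean
        # is near 0.5 and extremes on both sides occur
        assert 0.3 < np.mean(ps) < 0.75
        assert min(ps) <= 3 / 11 and max(ps) >= 8 / 11

    def test_zero_randomizations_rejected(self):
        with pytest.raises(ValidationError):
            randomization_test(
                np.random.default_rng(0).uniform(size=(2, 9, 9)),
                np.random.default_rng(1).uniform(size=(2, 9, 9)),
                n_randomizations=0,
            )

    def test_p_value_never_zero_and_bounded(self):
        rng = np.random.default_rng(9)
        a = rng.uniform(0, 100, size=(3, 12, 12))
        res = randomization_test(a, a + rng.normal(0, 5, a.shape).clip(-50),
                                 n_randomizations=19, seed=2)
        assert 0.0 < res.p_value <= 1.0
        assert res.n_randomizations == 19

    def test_seed_fixes_the_shuffle_sequence(self):
        rng = np.random.default_rng(10)
        a = rng.uniform(0, 100, size=(3, 12, 12))
        b = rng.uniform(0, 100, size=(3, 12, 12))
        r1 = randomization_test(a, b, seed=5)
        r2 = randomization_test(a, b, seed=5)
        assert r1.random_rs == r2.random_rs


def test_tracker_tmrm_ordering_on_simulated_co_culture():
    """A TMRM-like channel co-placed with population A's tracker halos must
    correlate more with tracker A than with tracker B, for every seed."""
    from voxcube import synthetic_stacks as synth

    wins = 0
    for seed in range(5):
        pops = [
            synth.cancer_spec(
                n_nuclei=40,
                channel_levels={
                    "tracker_green": (150.0, 20.0),
                    "tmrm": (120.0, 30.0),  # mitochondria active in cancer
                    "cea": (200.0, 30.0), "coll4": (20.0, 5.0),
                },
            ),
            synth.fibroblast_spec(
                n_nuclei=20,
                channel_levels={
                    "tracker_deepred": (150.0, 20.0),
                    "cea": (50.0, 10.0), "coll4": (80.0, 12.0),
                },
            ),
        ]
        stack, _ = synth.generate_stack((16, 128, 128), pops, seed=100 + seed)
        tmrm = stack.channel("tmrm")
        r_a = pearson_above_threshold(
            stack.channel("tracker_green"), tmrm, (0, 0)
        )
        r_b = pearson_above_threshold(
            stack.channel("tracker_deepred"), tmrm, (0, 0)
        )
        wins += r_a > r_b
    assert wins == 5
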