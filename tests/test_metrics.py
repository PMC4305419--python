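"""Similarity metrics and signed surface distances."""

import numpy as np
import pytest

from pirtsim.metrics import (
    confusion_metrics,
    radius_errors,
    surface_distance,
    surface_voxels,
)
from pirtsim.observations import Observation

from .conftest import ball_mask


def masks_from_counts(tp, fp, fn, tn):
    """Lay out a 1D arrangement with the requested confusion counts."""
    n = tp + fp + fn + tn
    pred = np.zeros((n, 1, 1), dtype=bool)
    obs = np.zeros((n, 1, 1), dtype=bool)
    pred[: tp + fp] = True
    obs[:tp] = True
    obs[tp + fp : tp + fp + fn] = True
    return pred, obs


class TestConfusionMetrics:
    def test_hand_worked_counts(self):
        pred, obs = masks_from_counts(tp=3, fp=1, fn=2, tn=10)
        rep = confusion_metrics(pred, obs, np.ones_like(pred))
        assert (rep.tp, rep.fp, rep.fn, rep.tn) == (3, 1, 2, 10)
        assert rep.ppv == pytest.approx(0.75)
        assert rep.sensitivity == pytest.approx(0.6)
        assert rep.specificity == pytest.approx(10 / 11)
        assert rep.jaccard == pytest.approx(0.5)
        assert rep.volume_similarity == pytest.approx(8 / 9)

    def test_perfect_agreement(self):
        m = ball_mask((16, 16, 16), (8, 8, 8), 4.0)
        rep = confusion_metrics(m, m)
        assert rep.ppv == rep.sensitivity == rep.jaccard == rep.volume_similarity == 1.0

    def test_empty_prediction_degenerate(self):
        pred = np.zeros((4, 4, 4), dtype=bool)
        obs = np.ones_like(pred)
        rep = confusion_metrics(pred, obs, np.ones_like(pred))
        assert rep.ppv is None  # undefined, not zero
        assert rep.sensitivity == 0.0
        assert rep.jaccard == 0.0

    def test_swapping_masks_swaps_ppv_and_sensitivity(self):
        pred, obs = masks_from_counts(tp=5, fp=3, fn=2, tn=7)
        region = np.ones_like(pred)
        a = confusion_metrics(pred, obs, region)
        b = confusion_metrics(obs, pred, region)
        assert a.ppv == pytest.approx(b.sensitivity)
        assert a.sensitivity == pytest.approx(b.ppv)
        assert a.jaccard == pytest.approx(b.jaccard)

    def test_jaccard_bounded_by_ppv_and_sensitivity(self):
        pred, obs = masks_from_counts(tp=4, fp=2, fn=3, tn=5)
        rep = confusion_metrics(pred, obs, np.ones_like(pred))
        assert rep.jaccard <= min(rep.ppv, rep.sensitivity)

    def test_counts_sum_to_region_size(self):
        pred = ball_mask((20, 20, 20), (10, 10, 10), 5.0)
        obs = ball_mask((20, 20, 20), (11, 10, 10), 5.0)
        rep = confusion_metrics(pred, obs, region_margin_mm=3.0)
        region = rep.tp + rep.fp + rep.fn + rep.tn
        assert 0 < region < 20**3  # restricted evaluation region

    def test_empty_region_rejected(self):
        m = np.ones((3, 3, 3), dtype=bool)
        with pytest.raises(ValueError, match="empty"):
            confusion_metrics(m, m, np.zeros_like(m))


class TestRadiusErrors:
    @staticmethod
    def obs(n_voxels, sequence="T1Gd"):
        mask = np.zeros((40, 40, 40), dtype=bool)
        mask.reshape(-1)[:n_voxels] = True
        return Observation(day=0, sequence=sequence, mask=mask)

    def test_identical_masks(self):
        o = self.obs(1000)
        assert radius_errors(o, o) == (0.0, 0.0)

    def test_hand_arithmetic(self):
        r_to_n = lambda r: int(round(4 / 3 * np.pi * r**3))
        rel, ab = radius_errors(self.obs(r_to_n(20.63)), self.obs(r_to_n(18.0)))
        assert ab == pytest.approx(2.63, abs=0.01)
        assert rel == pytest.approx(100 * 2.63 / 18.0, abs=0.1)

    def test_zero_reference_flagged(self):
        rel, ab = radius_errors(self.obs(10), self.obs(0))
        assert rel is None

    def test_sequence_mismatch(self):
        with pytest.raises(ValueError):
            radius_errors(self.obs(10), self.obs(10, sequence="T2"))


def brute_force_signed_distances(pred, obs, voxel_size):
    """O(n^2) oracle: nearest observed-surface voxel for each predicted one."""
    sp = np.argwhere(surface_voxels(pred)).astype(float) * voxel_size
    so = np.argwhere(surface_voxels(obs)).astype(float) * voxel_size
    inside = obs[tuple(np.argwhere(surface_voxels(pred)).T)]
    out = []
    for p, is_in in zip(sp, inside):
        d = np.sqrt(((so - p) ** 2).sum(axis=1)).min()
        out.append(-d if is_in else d)
    return np.sort(np.array(out))


class TestSurfaceDistance:
    def test_identical_masks_all_zero(self):
        m = ball_mask((16, 16, 16), (8, 8, 8), 4.0)
        res = surface_distance(m, m)
        assert res.median == 0.0 and res.sd == 0.0
        assert res.zero_count == surface_voxels(m).sum()
        assert res.distances.size == 0

    def test_concentric_balls_overestimate(self):
        pred = ball_mask((32, 32, 32), (16, 16, 16), 10.0)
        obs = ball_mask((32, 32, 32), (16, 16, 16), 8.0)
        res = surface_distance(pred, obs)
        assert res.median == pytest.approx(2.0, abs=0.5)
        assert np.all(res.distances > 0)  # model front beyond observed

    def test_nested_prediction_all_negative(self):
        pred = ball_mask((32, 32, 32), (16, 16, 16), 5.0)
        obs = ball_mask((32, 32, 32), (16, 16, 16), 9.0)
        res = surface_distance(pred, obs)
        assert np.all(res.distances < 0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(3):
            pred = np.zeros((16, 16, 16), dtype=bool)
            obs = np.zeros_like(pred)
            for m in (pred, obs):
                c = rng.integers(5, 11, size=3)
                r = rng.uniform(2.0, 4.5)
                m |= ball_mask(m.shape, c, r)
            res = surface_distance(pred, obs)
            sample = np.sort(np.concatenate([res.distances, np.zeros(res.zero_count)]))
            oracle = brute_force_signed_distances(pred, obs, 1.0)
            np.testing.assert_allclose(sample, oracle, atol=1e-9)

    def test_symmetric_variant_pools_both_surfaces(self):
        pred = ball_mask((24, 24, 24), (12, 12, 12), 7.0)
        obs = ball_mask((24, 24, 24), (12, 12, 12), 5.0)
        one_way = surface_distance(pred, obs)
        both = surface_distance(pred, obs, symmetric=True)
        assert both.n > one_way.n
        assert np.all(both.distances > 0)  # everywhere an over-estimate

    def test_empty_mask_rejected(self):
        m = ball_mask((8, 8, 8), (4, 4, 4), 2.0)
        with pytest.raises(ValueError):
            surface_distance(np.zeros_like(m), m)
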