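"""Phantom, T/B and virtual-patient generators."""

import numpy as np
import pytest

from pirtsim.hypoxia import hypoxic_volume
from pirtsim.rt_plan import dilate_mask
from pirtsim.synthetic import (
    VirtualPatientConfig,
    make_phantom,
    make_tb_map,
    make_virtual_patient,
    truncated_lognormal_params,
)

from .conftest import SMALL_PATIENT_CONFIG, ball_mask


class TestPhantom:
    def test_fraction_invariants(self):
        t = make_phantom((48, 48, 48))
        total = t.f_grey + t.f_white + t.f_csf
        assert np.all(total <= 1 + 1e-9)
        assert np.all(t.f_grey >= 0) and np.all(t.f_white >= 0)

    def test_centre_is_white_dominant(self):
        t = make_phantom((48, 48, 48))
        assert t.f_white[24 + 18, 24, 24] > 0.5

    def test_contains_all_three_tissues(self):
        t = make_phantom((48, 48, 48))
        assert (t.f_grey > 0.5).any() and (t.f_white > 0.5).any() and (t.f_csf > 0.5).any()

    def test_deterministic(self):
        a = make_phantom((32, 32, 32), seed=5)
        b = make_phantom((32, 32, 32), seed=5)
        np.testing.assert_array_equal(a.f_white, b.f_white)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            make_phantom((8, 8, 8))


class TestTruncatedLognormal:
    def test_moment_match(self):
        mu, sigma = truncated_lognormal_params(0.813, 0.223, 1.2)
        rng = np.random.default_rng(0)
        d = rng.lognormal(mu, sigma, 500_000)
        d = d[d < 1.2]
        assert d.mean() == pytest.approx(0.813, rel=0.01)
        assert d.std() == pytest.approx(0.223, rel=0.01)

    def test_invalid_mean(self):
        with pytest.raises(ValueError):
            truncated_lognormal_params(1.5, 0.2, 1.2)


@pytest.fixture(scope="module")
def phantom():
    return make_phantom((64, 64, 64))


@pytest.fixture(scope="module")
def tumour(phantom):
    # ~ 4.1 cm^3 ball inside the white matter
    return ball_mask(phantom.shape, (44, 32, 32), 9.9) & phantom.brain_mask


class TestTBMap:
    def test_background_moments(self, phantom, tumour):
        tb = make_tb_map(phantom, tumour, focus_fraction=0.0, seed=3)
        brain = phantom.brain_mask
        assert brain.sum() >= 1e5
        vals = tb.values[brain]
        assert vals.mean() == pytest.approx(0.813, rel=0.03)
        assert vals.std() == pytest.approx(0.223, rel=0.03)

    def test_no_focus_no_hypoxia(self, phantom, tumour):
        tb = make_tb_map(phantom, tumour, focus_fraction=0.0, seed=3)
        region = dilate_mask(tumour, 20.0)
        assert hypoxic_volume(tb, region).hv_cm3 == 0.0

    def test_focus_sets_hypoxic_volume(self, phantom, tumour):
        tb = make_tb_map(phantom, tumour, focus_fraction=0.13, seed=3)
        region = dilate_mask(tumour, 20.0)
        hv = hypoxic_volume(tb, region)
        expected = 0.13 * tumour.sum() / 1000.0
        assert hv.hv_cm3 == pytest.approx(expected, rel=0.02)
        assert hv.tb_max == pytest.approx(1.5)

    def test_focus_spans_tumour_boundary(self, phantom, tumour):
        tb = make_tb_map(phantom, tumour, focus_fraction=0.13, seed=3)
        hyp = tb.values >= 1.2
        assert (hyp & tumour).any() and (hyp & ~tumour).any()

    def test_deterministic(self, phantom, tumour):
        a = make_tb_map(phantom, tumour, seed=9)
        b = make_tb_map(phantom, tumour, seed=9)
        np.testing.assert_array_equal(a.values, b.values)

    def test_empty_tumour_with_focus_rejected(self, phantom):
        with pytest.raises(ValueError):
            make_tb_map(phantom, np.zeros(phantom.shape, dtype=bool),
                        focus_fraction=0.1)

    def test_subthreshold_focus_rejected(self, phantom, tumour):
        with pytest.raises(ValueError):
            make_tb_map(phantom, tumour, focus_level=1.1)


class TestVirtualPatient:
    def test_target_volume_reached(self, patient):
        """Second pre-RT T1Gd volume lands within 5% of the 18.8 cm^3 target."""
        v = patient.pre_obs[(2, "T1Gd")].volume_cm3
        assert v == pytest.approx(18.8, rel=0.05)

    def test_visit_interval(self, patient):
        d1 = patient.pre_obs[(1, "T1Gd")].day
        d2 = patient.pre_obs[(2, "T1Gd")].day
        assert d2 - d1 == pytest.approx(13.0)

    def test_plan_has_34_weekday_fractions(self, patient):
        assert patient.plan.n_fractions == 34

    def test_post_mri_three_days_after_last_fraction(self, patient):
        assert patient.post_mri_day == pytest.approx(
            patient.plan.fraction_days[-1] + 3.0
        )

    def test_treatment_shrinks_tumour(self, patient):
        assert (
            patient.post_obs["T2"].radius_mm
            < patient.pre_obs[(2, "T2")].radius_mm
        )

    def test_determinism_scaled_down(self):
        a = make_virtual_patient(SMALL_PATIENT_CONFIG, seed=7)
        b = make_virtual_patient(SMALL_PATIENT_CONFIG, seed=7)
        np.testing.assert_array_equal(a.post_rt_density.c, b.post_rt_density.c)
        np.testing.assert_array_equal(a.tb.values, b.tb.values)
        assert a.plan.fraction_days == b.plan.fraction_days

    def test_unreachable_volume_errors(self):
        cfg = VirtualPatientConfig(
            shape=(48, 48, 48), target_t1gd_volume_cm3=500.0, max_growth_days=50.0
        )
        with pytest.raises(RuntimeError, match="not reached"):
            make_virtual_patient(cfg, seed=0)
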