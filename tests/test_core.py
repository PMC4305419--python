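"""PDE solver: LQ survival, fraction kill, integration properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pirtsim.core import (
    CellDensityField,
    GrowthParams,
    RadiosensitivityParams,
    apply_rt_fraction,
    carrying_capacity,
    lq_survival,
    seed_initial_condition,
    simulate,
)
from pirtsim.rt_plan import DosePlan, Phase

from .conftest import uniform_field, zero_diffusion_field

RT = RadiosensitivityParams(alpha=0.055)


class TestLQSurvival:
    def test_zero_dose_survives_fully(self):
        assert lq_survival(0.0, RT) == 1.0

    def test_standard_fraction(self):
        # exp(-(0.055*1.8 + 0.0055*1.8^2)) evaluated by hand
        assert lq_survival(1.8, RT) == pytest.approx(0.889745, abs=1e-5)

    def test_oer_reduces_effective_dose(self):
        assert lq_survival(1.8, RT, oer=2.5) == pytest.approx(0.958437, abs=1e-5)

    def test_guards(self):
        with pytest.raises(ValueError):
            lq_survival(-1.0, RT)
        with pytest.raises(ValueError):
            lq_survival(1.0, RT, oer=0.5)

    @settings(derandomize=True, max_examples=50)
    @given(
        d=st.floats(0.1, 30.0),
        extra=st.floats(0.1, 5.0),
        oer=st.floats(1.0, 3.0),
    )
    def test_monotone_in_dose_and_oer(self, d, extra, oer):
        assert lq_survival(d + extra, RT, oer) < lq_survival(d, RT, oer)
        assert lq_survival(d, RT, oer) >= lq_survival(d, RT, 1.0)


class TestFractionKill:
    K = carrying_capacity()

    def test_saturated_voxel_unresponsive(self):
        c = np.full((2, 2, 2), self.K)
        out = apply_rt_fraction(c, np.full_like(c, 10.0), RT, self.K)
        np.testing.assert_allclose(out, c)

    def test_empty_voxel_stays_empty(self):
        c = np.zeros((2, 2, 2))
        out = apply_rt_fraction(c, np.full_like(c, 10.0), RT, self.K)
        np.testing.assert_array_equal(out, 0.0)

    def test_density_dependent_kill(self):
        # c = 0.1 K with S = 0.9: kill = 0.1 * 0.1K * 0.9 -> c' = 0.091 K
        c = np.full((1, 1, 1), 0.1 * self.K)
        dose = np.full_like(c, 1.0)
        params = RadiosensitivityParams(alpha=-np.log(0.9) / 1.0, alpha_beta_ratio=1e12)
        out = apply_rt_fraction(c, dose, params, self.K)
        assert out[0, 0, 0] == pytest.approx(0.091 * self.K, rel=1e-9)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            apply_rt_fraction(np.zeros((2, 2, 2)), np.zeros((3, 3, 3)), RT, self.K)

    def test_kill_never_increases_density(self):
        rng = np.random.default_rng(3)
        c = rng.uniform(0, self.K, (6, 6, 6))
        out = apply_rt_fraction(c, rng.uniform(0, 5, c.shape), RT, self.K)
        assert np.all(out <= c + 1e-9) and np.all(out >= 0)


class TestSeed:
    def test_total_cells(self):
        field = uniform_field((5, 5, 5))
        g = GrowthParams(D_w=12.84, rho=13.82)
        init = seed_initial_condition(field, (2, 2, 2), g.K, g.K)
        assert init.total_cells() == pytest.approx(g.K * field.voxel_volume_mm3)

    def test_clamped_to_carrying_capacity(self):
        field = uniform_field((3, 3, 3))
        init = seed_initial_condition(field, (1, 1, 1), 2e7, 1.91e6)
        assert init.c.max() == pytest.approx(1.91e6)

    def test_off_domain_rejected(self):
        field = uniform_field((3, 3, 3))
        field.mask[0, 0, 0] = False
        with pytest.raises(ValueError, match="off-domain"):
            seed_initial_condition(field, (0, 0, 0), 1e5, 1.91e6)


class TestSimulate:
    def test_null_dynamics_preserves_state(self):
        shape = (4, 4, 4)
        field = zero_diffusion_field(shape)
        g = GrowthParams(D_w=0.0, rho=0.0)
        rng = np.random.default_rng(0)
        c0 = rng.uniform(0, g.K, shape)
        init = CellDensityField(c0, 0.0)
        res = simulate(field, g, init, 50.0)
        np.testing.assert_array_equal(res.final.c, c0)

    def test_logistic_closed_form(self):
        """Single-voxel growth matches K c0 e^{rho t}/(K + c0(e^{rho t}-1))."""
        g = GrowthParams(D_w=0.0, rho=13.82)
        field = zero_diffusion_field((1, 1, 1))
        c0 = 0.01 * g.K
        init = CellDensityField(np.full((1, 1, 1), c0), 0.0)
        t_days = 150.0
        res = simulate(field, g, init, t_days)
        rt = g.rho * t_days / 365.0
        expected = g.K * c0 * np.exp(rt) / (g.K + c0 * (np.exp(rt) - 1.0))
        assert res.final.c[0, 0, 0] == pytest.approx(expected, rel=1e-3)

    def test_mass_conservation_without_growth(self):
        """Pure diffusion conserves total cell number to 1e-6 per 1000 steps."""
        shape = (16, 16, 16)
        field = uniform_field(shape)
        field.mask[:2] = False  # irregular no-flux boundary
        field.D[:2] = 0.0
        g = GrowthParams(D_w=12.84, rho=0.0)
        c0 = np.zeros(shape)
        c0[8, 8, 8] = g.K
        init = CellDensityField(c0, 0.0)
        dt = 0.9 / (6 * 12.84 / 365.0)
        res = simulate(field, g, init, 1000 * dt, dt_max_days=dt)
        assert res.n_steps >= 1000
        assert res.final.total_cells() == pytest.approx(
            init.total_cells(), rel=1e-6
        )

    def test_boundedness_under_treatment(self):
        shape = (12, 12, 12)
        field = uniform_field(shape)
        g = GrowthParams(D_w=12.84, rho=13.82)
        init = seed_initial_condition(field, (6, 6, 6), g.K, g.K)
        dose = np.full(shape, 1.8)
        plan = DosePlan(
            phases=(Phase(dose_per_fraction=dose, fraction_days=(10.0, 11.0, 12.0)),)
        )
        res = simulate(field, g, init, 30.0, plan=plan, rt_params=RT)
        assert res.fractions_applied == 3
        assert np.all(res.final.c >= 0) and np.all(res.final.c <= g.K * (1 + 1e-12))

    def test_time_step_convergence(self):
        """Halving dt changes the final total cell count by < 0.5%."""
        shape = (24, 24, 24)
        field = uniform_field(shape)
        g = GrowthParams(D_w=12.84, rho=13.82)
        init = seed_initial_condition(field, (12, 12, 12), 0.8 * g.K, g.K)
        totals = []
        for factor in (1.0, 0.5):
            res = simulate(field, g, init, 60.0, dt_max_days=2.64 * factor)
            totals.append(res.final.total_cells())
        assert abs(totals[1] / totals[0] - 1.0) < 0.005

    def test_oer_dose_equivalence(self):
        """OER-scaled sensitivity == reduced dose at full sensitivity."""
        from pirtsim.hypoxia import build_oer_map

        shape = (10, 10, 10)
        field = uniform_field(shape)
        g = GrowthParams(D_w=12.84, rho=13.82)
        init = seed_initial_condition(field, (5, 5, 5), 0.5 * g.K, g.K)
        oer = 2.5
        dose = np.full(shape, 1.8)
        days = (5.0, 6.0, 7.0)
        plan_full = DosePlan(phases=(Phase(dose, days),))
        plan_reduced = DosePlan(phases=(Phase(dose / oer, days),))
        hyp_all = build_oer_map(np.ones(shape, dtype=bool), oer)
        a = simulate(field, g, init, 10.0, plan=plan_full, oer_map=hyp_all, rt_params=RT)
        b = simulate(field, g, init, 10.0, plan=plan_reduced, rt_params=RT)
        np.testing.assert_allclose(a.final.c, b.final.c, rtol=1e-12)

    def test_requires_rt_params_with_plan(self):
        shape = (4, 4, 4)
        field = uniform_field(shape)
        g = GrowthParams(D_w=1.0, rho=1.0)
        init = seed_initial_condition(field, (2, 2, 2), g.K, g.K)
        plan = DosePlan(phases=(Phase(np.zeros(shape), (1.0,)),))
        with pytest.raises(ValueError, match="rt_params"):
            simulate(field, g, init, 5.0, plan=plan)


def test_carrying_capacity_guard():
    with pytest.raises(ValueError):
        carrying_capacity(0.0)
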