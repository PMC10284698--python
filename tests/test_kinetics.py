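"""Adhesion-kinetics closed forms, fitting, order selection, variability."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sterolfilm import kinetics as kin
from sterolfilm import synth


def rk4_sigma(t_grid, k, sigma0, order, n_sub=2000):
    """Independent RK4 integration of d(sigma)/dt = -k sigma**order.

    Steps land exactly on each requested time (n_sub substeps per
    interval), so no interpolation error enters the oracle.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    f = lambda s: -k * s**order
    out = np.empty_like(t_grid)
    s = sigma0
    t_prev = 0.0
    for j, t in enumerate(t_grid):
        span = t - t_prev
        if span > 0:
            h = span / n_sub
            for _ in range(n_sub):
                k1 = f(s)
                k2 = f(s + 0.5 * h * k1)
                k3 = f(s + 0.5 * h * k2)
                k4 = f(s + h * k3)
                s = s + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        out[j] = s
        t_prev = t
    return out


class TestBondDensitySolution:
    def test_initial_condition_and_zero_rate(self):
        assert kin.bond_density_solution(0.0, 2.0, 1.7, 3) == pytest.approx(1.7)
        assert kin.bond_density_solution(50.0, 0.0, 1.7, 2) == pytest.approx(1.7)

    def test_third_order_closed_form_value(self):
        # (1 + 2*0.5*1*3)^(-1/2) = 0.5, confirmed by the RK4 oracle
        assert kin.bond_density_solution(3.0, 0.5, 1.0, 3) == pytest.approx(0.5)
        oracle = rk4_sigma([3.0], 0.5, 1.0, 3)[0]
        assert abs(oracle - 0.5) < 1e-9

    @pytest.mark.parametrize("order", [1, 2, 3, 4])
    @pytest.mark.parametrize("k,sigma0", [(0.05, 1.0), (0.5, 1.0), (0.2, 2.5)])
    def test_matches_rk4_oracle(self, order, k, sigma0):
        t = np.linspace(0.0, 60.0, 13)
        closed = kin.bond_density_solution(t, k, sigma0, order)
        oracle = rk4_sigma(t, k, sigma0, order)
        assert np.max(np.abs(closed - oracle) / sigma0) < 1e-8

    def test_rejects_bad_order(self):
        with pytest.raises(ValueError):
            kin.bond_density_solution(1.0, 0.5, 1.0, 0)


class TestForceModel:
    def test_zero_at_contact_and_limit(self):
        assert kin.force_model(0.0, 2.0, 0.5, 3) == 0.0
        assert kin.force_model(1e9, 2.0, 0.5, 3) == pytest.approx(2.0, abs=1e-3)
        assert kin.force_model(3.0, 2.0, 0.5, 3) == pytest.approx(1.0)

    @settings(deadline=None, max_examples=50)
    @given(order=st.integers(1, 5),
           kappa=st.floats(1e-3, 10.0),
           scale=st.floats(0.1, 10.0))
    def test_monotone_nondecreasing(self, order, kappa, scale):
        t = np.linspace(0.0, 100.0, 200)
        f = kin.force_model(t, scale, kappa, order)
        assert np.all(np.diff(f) >= -1e-12)


class TestFitKinetics:
    def test_exact_recovery_noise_free(self):
        t = synth.default_contact_times()
        f = kin.force_model(t, 1.5, 0.3, 3)
        fit = kin.fit_kinetics(kin.ForceTimeSeries(t, f), 3)
        assert fit.success
        assert fit.rate_kappa == pytest.approx(0.3, rel=1e-6)
        assert fit.force_scale == pytest.approx(1.5, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_mean_rate_recovery_under_noise(self):
        params = synth.KineticsParams(seed=42)
        curves = synth.gen_adhesion_force_curves(params, n_curves=200)
        kappas = [kin.fit_kinetics(c, 3).rate_kappa for c in curves]
        assert abs(np.mean(kappas) - params.rate) / params.rate < 0.10

    def test_zero_force_series_flagged(self):
        t = np.arange(5, dtype=float)
        fit = kin.fit_kinetics(kin.ForceTimeSeries(t, np.zeros(5)), 3)
        assert not fit.success
        assert "low_information" in fit.flags


class TestSelectOrder:
    def test_recovers_generating_order_third(self):
        curves = synth.gen_adhesion_force_curves(synth.KineticsParams(seed=1),
                                                 n_curves=20)
        assert kin.select_order(curves).best_order == 3

    def test_recovers_first_order(self):
        params = synth.KineticsParams(order=1, rate=0.08, noise_cv=0.01, seed=5)
        curves = synth.gen_adhesion_force_curves(params, n_curves=10)
        assert kin.select_order(curves).best_order == 1

    def test_exact_second_order_single_short_curve(self):
        t = np.array([0.0, 10.0, 20.0, 40.0, 60.0])
        f = kin.force_model(t, 1.0, 0.1, 2)
        sel = kin.select_order(kin.ForceTimeSeries(t, f))
        assert sel.best_order == 2

    def test_empty_orders_rejected(self):
        c = synth.gen_adhesion_force_curves(synth.KineticsParams(), n_curves=1)[0]
        with pytest.raises(ValueError):
            kin.select_order(c, orders=[])


class TestNormalizeRepeatForces:
    def test_constant_series(self):
        s = kin.RepeatForceSeries(np.arange(1, 17), np.full(16, 3.3))
        norm, cv = kin.normalize_repeat_forces(s)
        assert np.allclose(norm.force, 1.0)
        assert cv == 0.0

    def test_two_point_arithmetic(self):
        s = kin.RepeatForceSeries([1, 2], [1.0, 3.0])
        norm, cv = kin.normalize_repeat_forces(s)
        assert np.allclose(norm.force, [0.5, 1.5])
        assert cv == pytest.approx(0.5)

    @settings(deadline=None, max_examples=30)
    @given(scale=st.floats(0.1, 100.0), seed=st.integers(0, 1000))
    def test_scale_invariance_and_idempotence(self, scale, seed):
        rng = np.random.default_rng(seed)
        f = rng.uniform(0.5, 2.0, 16)
        s = kin.RepeatForceSeries(np.arange(1, 17), f)
        s_scaled = kin.RepeatForceSeries(np.arange(1, 17), scale * f)
        n1, cv1 = kin.normalize_repeat_forces(s)
        n2, cv2 = kin.normalize_repeat_forces(s_scaled)
        assert np.allclose(n1.force, n2.force)
        n3, cv3 = kin.normalize_repeat_forces(n1)
        assert np.allclose(n3.force, n1.force)
        assert cv3 == pytest.approx(cv1)

    def test_fluctuating_surface_has_larger_cv_than_fixed(self):
        rng = np.random.default_rng(11)
        idx = np.arange(1, 17)
        scl = [kin.RepeatForceSeries(idx, 1.0 + 0.4 * rng.standard_normal(16),
                                     location_id=f"L{i}", condition="scl")
               for i in range(4)]
        sam = [kin.RepeatForceSeries(idx, 1.0 + 0.02 * rng.standard_normal(16),
                                     location_id=f"L{i}", condition="sam")
               for i in range(4)]
        df = kin.pooled_repeat_cv(scl + sam)
        pooled = df.groupby("condition")["pooled_cv"].first()
        assert pooled["scl"] > pooled["sam"]

    def test_zero_mean_rejected(self):
        s = kin.RepeatForceSeries([1, 2], [-1.0, 1.0])
        with pytest.raises(ValueError):
            kin.normalize_repeat_forces(s)
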