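import dataclasses
import math

import numpy as np
import pytest
from scipy.optimize import brentq

from ringmaps import presets
from ringmaps.geometry import sample_correlated_maps
from ringmaps.meanfield import (Grid, ModelParams, OrderParameters,
                                TunedInput, integrate_mf, moment_rhs,
                                moments_from_op, morph_coupling_kernel,
                                op_from_moments, order_param_rhs,
                                profile_at, steady_profile,
                                MORPH_EQUIV_DISTANCE)
from ringmaps.phase import solve_fixed_point


class TestSteadyProfile:
    def test_nonpositive_size_is_silent(self, grid):
        op = OrderParameters(amp=1.0, size=0.0, mu=0.0, psi0=0.0, x_phi=0.0)
        prof = steady_profile(op, presets.SINGLE_RING, grid)
        assert np.all(prof.values == 0.0)

    def test_maximal_size_all_active(self, grid):
        # size = pi puts every neuron above threshold (zero set is measure-0)
        op = OrderParameters(amp=1.0, size=np.pi, mu=0.0, psi0=0.3, x_phi=0.0)
        prof = steady_profile(op, ModelParams(d=0.5, J_mod=1.0, J_inh=1.0), grid)
        assert np.all(prof.values > 0.0)

    def test_nonnegative_everywhere(self, grid, cylinder_fp):
        prof = steady_profile(cylinder_fp, presets.CYLINDER_SHALLOW, grid)
        assert np.all(prof.values >= 0.0)

    def test_doubling_I0_doubles_values_same_support(self, grid):
        p = presets.SINGLE_RING
        fp1 = solve_fixed_point(p, grid=grid)
        fp2 = solve_fixed_point(p.with_(I0=2.0 * p.I0), grid=grid)
        assert fp2.size == pytest.approx(fp1.size, abs=1e-10)
        assert fp2.amp == pytest.approx(2.0 * fp1.amp, rel=1e-10)
        v1 = steady_profile(fp1, p, grid).values
        v2 = steady_profile(fp2, p, grid).values
        np.testing.assert_allclose(v2, 2.0 * v1, atol=1e-12)
        np.testing.assert_array_equal(v1 > 0, v2 > 0)


class TestMomentChart:
    def test_round_trip(self):
        p = presets.CYLINDER_SHALLOW
        op = OrderParameters(amp=3.0, size=1.0, mu=0.2, psi0=2.0, x_phi=0.1)
        back = op_from_moments(moments_from_op(op, p), p)
        for f in ("amp", "size", "mu", "psi0", "x_phi"):
            assert getattr(back, f) == pytest.approx(getattr(op, f), abs=1e-10)

    def test_zero_state(self):
        op = op_from_moments(np.zeros(5), presets.SINGLE_RING)
        assert op.amp == 0.0


class TestOrderParamRhs:
    def test_fixed_point_residual(self, grid, single_ring_fp):
        dv = order_param_rhs(single_ring_fp, presets.SINGLE_RING, grid=grid)
        assert abs(dv.amp) < 1e-6 * single_ring_fp.amp
        assert abs(dv.size) < 1e-7
        assert abs(dv.mu) < 1e-7

    def test_psi0_shift_leaves_first_four_unchanged(self, grid):
        p = presets.SINGLE_RING
        op = OrderParameters(amp=2.0, size=1.2, mu=0.1, psi0=0.7, x_phi=0.0)
        d1 = order_param_rhs(op, p, grid=grid)
        # a shift by an exact grid step is a symmetry of the discretized
        # system: machine precision
        step = 2 * np.pi / grid.n_theta
        d2 = order_param_rhs(dataclasses.replace(op, psi0=op.psi0 + 7 * step),
                             p, grid=grid)
        for f in ("amp", "size", "mu", "x_phi"):
            assert getattr(d1, f) == pytest.approx(getattr(d2, f), abs=1e-12)
        # an arbitrary shift is invariant up to quadrature error only
        d3 = order_param_rhs(dataclasses.replace(op, psi0=op.psi0 + 1.234),
                             p, grid=grid)
        for f in ("amp", "size", "mu", "x_phi"):
            assert getattr(d3, f) == pytest.approx(getattr(d1, f), abs=1e-4)

    def test_quadrature_consistency(self, grid, fine_grid):
        # trapezoid at n vs 2n: Richardson-style self-consistency
        p = presets.CYLINDER_SHALLOW
        op = OrderParameters(amp=4.0, size=1.0, mu=0.05, psi0=0.0, x_phi=0.05)
        d1 = order_param_rhs(op, p, grid=grid)
        d2 = order_param_rhs(op, p, grid=fine_grid)
        for f in ("amp", "size", "mu", "psi0", "x_phi"):
            assert getattr(d1, f) == pytest.approx(getattr(d2, f),
                                                   abs=2e-3 * max(1.0, op.amp))

    def test_malformed_input_spec(self, grid):
        op = OrderParameters(amp=1.0, size=1.0, mu=0.0, psi0=0.0, x_phi=0.0)
        with pytest.raises(TypeError):
            order_param_rhs(op, presets.SINGLE_RING, input_spec="A", grid=grid)
        with pytest.raises(ValueError):
            TunedInput(map_select="Q").s_of(0.0)


class TestIntegration:
    def test_constant_at_stable_fixed_point(self, grid, single_ring_fp):
        p = presets.SINGLE_RING
        m0 = moments_from_op(single_ring_fp, p)
        traj = integrate_mf(m0, p, t_end=50 * p.tau, grid=grid,
                            t_eval=np.array([50 * p.tau]))
        assert traj.event is None
        np.testing.assert_allclose(traj.final_moments, m0, atol=1e-5)

    def test_amplitude_instability_event(self, grid, single_ring_fp):
        p = presets.SINGLE_RING.with_(J_inh=0.3)  # well below critical
        m0 = moments_from_op(single_ring_fp, presets.SINGLE_RING)
        traj = integrate_mf(m0, p, t_end=3000.0, grid=grid,
                            amp_ceiling_factor=100.0)
        assert traj.event == "amplitude_instability"

    def test_static_input_pins_bump(self, grid):
        p = presets.SINGLE_RING
        fp = solve_fixed_point(p, grid=grid)
        xi = 2.2
        inp = TunedInput(map_select="A", location=xi, eps=0.2)
        start = dataclasses.replace(fp, psi0=xi - 1.0)
        traj = integrate_mf(moments_from_op(start, p), p, input_spec=inp,
                            t_end=100 * p.tau, grid=grid,
                            t_eval=np.array([100 * p.tau]))
        final = traj.final_op
        assert abs(np.angle(np.exp(1j * (final.psi0 - xi)))) < 0.05

    def test_rotational_equivariance(self, grid):
        p = presets.SINGLE_RING
        fp = solve_fixed_point(p, grid=grid)
        outs = []
        for shift in (0.0, 1.1):
            inp = TunedInput(map_select="A", location=0.8 + shift, eps=0.1)
            start = dataclasses.replace(fp, psi0=0.5 + shift)
            traj = integrate_mf(moments_from_op(start, p), p, input_spec=inp,
                                t_end=80 * p.tau, grid=grid,
                                t_eval=np.array([80 * p.tau]))
            outs.append(traj.final_op)
        a, b = outs
        assert np.angle(np.exp(1j * (b.psi0 - a.psi0))) == pytest.approx(1.1, abs=1e-3)
        # invariance up to quadrature symmetry breaking and ODE tolerance
        for f in ("amp", "size", "mu", "x_phi"):
            assert getattr(a, f) == pytest.approx(getattr(b, f), abs=3e-4)

    def test_em_deterministic_given_seed(self, grid):
        p = presets.SINGLE_RING.with_(sigma_noise=0.05)
        fp = solve_fixed_point(presets.SINGLE_RING, grid=grid)
        m0 = moments_from_op(fp, presets.SINGLE_RING)
        t1 = integrate_mf(m0, p, t_end=5 * p.tau, grid=grid, seed=42)
        t2 = integrate_mf(m0, p, t_end=5 * p.tau, grid=grid, seed=42)
        np.testing.assert_array_equal(t1.moments, t2.moments)

    def test_noise_deviation_shrinks_with_sigma(self, grid):
        base = presets.SINGLE_RING
        fp = solve_fixed_point(base, grid=grid)
        m0 = moments_from_op(fp, base)
        devs = []
        for sigma in (0.2, 0.02):
            p = base.with_(sigma_noise=sigma)
            traj = integrate_mf(m0, p, t_end=10 * p.tau, grid=grid, seed=1,
                                dt=p.tau / 25.0)
            devs.append(np.abs(traj.moments - m0).max())
        assert devs[1] < devs[0]

    def test_t_end_validation(self, grid):
        with pytest.raises(ValueError):
            integrate_mf(np.zeros(5), presets.SINGLE_RING, t_end=0.0, grid=grid)


class TestD0Limit:
    def test_matches_classical_ring_model(self, grid):
        # independent oracle: 1-map ring model closed form
        # 1 = (J/pi) * (delta - sin(delta) cos(delta))
        p = ModelParams(d=0.0, J_mod=3.0, J_inh=4.0)
        fp = solve_fixed_point(p, grid=grid)
        delta_oracle = brentq(
            lambda dd: (p.J_mod / math.pi) * (dd - math.sin(dd) * math.cos(dd)) - 1.0,
            1e-3, math.pi)
        assert fp.size == pytest.approx(delta_oracle, abs=2e-4)
        assert fp.mu == 0.0


class TestMorphKernel:
    def test_two_maps_peak_value(self):
        p = presets.SINGLE_RING
        k = morph_coupling_kernel(p, "two_maps")
        assert k(0.3, 0.1, 0.3, 0.1) == pytest.approx(2 * p.J_mod - p.J_inh)

    def test_symmetry(self, rng):
        p = presets.MORPH_CYLINDER
        for mode in ("two_maps", "full_morph"):
            k = morph_coupling_kernel(p, mode)
            a = rng.uniform(0, 2 * np.pi, 50)
            b = rng.uniform(-np.pi / 2, np.pi / 2, 50)
            c = rng.uniform(0, 2 * np.pi, 50)
            e = rng.uniform(-np.pi / 2, np.pi / 2, 50)
            np.testing.assert_allclose(k(a, b, c, e), k(c, e, a, b), atol=1e-12)

    def test_full_morph_vs_discrete_quadrature(self, rng):
        # K equally weighted maps converge to the continuum kernel as O(1/K)
        p = presets.MORPH_CYLINDER.with_(d=1.0)
        k_full = morph_coupling_kernel(p, "full_morph")
        a = rng.uniform(0, 2 * np.pi, 200)
        b = rng.uniform(-np.pi / 2, np.pi / 2, 200)
        devs = []
        for n_maps in (101, 401):
            k_disc = morph_coupling_kernel(p, "discrete_morph", n_maps=n_maps)
            devs.append(np.abs(k_disc(a, b, 0.0, 0.0)
                               - k_full(a, b, 0.0, 0.0)).max())
            assert devs[-1] < 6.0 * p.J_mod / n_maps
        assert devs[1] < devs[0] / 2.0

    def test_full_morph_close_to_equivalent_two_maps(self):
        # equivalence at the effective distance sqrt(2)/pi (leading Euler
        # factor); residual grows as (1/6 - 1/pi^2) dphi^2
        p = ModelParams(d=1.0, J_mod=1.0, J_inh=0.0)
        k_full = morph_coupling_kernel(p, "full_morph")
        k_two = morph_coupling_kernel(p.with_(d=MORPH_EQUIV_DISTANCE), "two_maps")
        dphi = np.linspace(-np.pi, np.pi, 201)  # phi_i - phi_j range
        dev = np.abs(k_full(0.0, dphi, 0.0, 0.0) - k_two(0.0, dphi, 0.0, 0.0))
        bound = 2.0 * (1.0 / 6.0 - 1.0 / np.pi ** 2) * dphi ** 2 * 1.2 + 1e-9
        assert np.all(dev <= bound)
        assert dev[np.abs(dphi) < 0.2].max() < 7e-3
        assert dev.max() < 0.45


class TestParamsValidation:
    @pytest.mark.parametrize("kw", [dict(d=1.4), dict(tau=0.0), dict(I0=-1.0),
                                    dict(eps=-0.1), dict(sigma_noise=-1.0)])
    def test_invalid(self, kw):
        base = dict(d=0.5, J_mod=1.0, J_inh=1.0)
        base.update(kw)
        with pytest.raises(ValueError):
            ModelParams(**base)


def test_profile_at_matches_grid_profile(grid, cylinder_fp):
    p = presets.CYLINDER_SHALLOW
    prof = steady_profile(cylinder_fp, p, grid)
    th, ph = np.meshgrid(grid.theta, grid.phi, indexing="ij")
    direct = profile_at(cylinder_fp, p, th, ph)
    np.testing.assert_allclose(direct, prof.values, atol=1e-12)
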