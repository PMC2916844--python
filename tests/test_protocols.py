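import math

import numpy as np
import pytest

from ringmaps import presets
from ringmaps.geometry import TWO_PI, circ_dist, sample_correlated_maps, signed_arc
from ringmaps.meanfield import Grid, ModelParams
from ringmaps.protocols import (RegimeMismatchError, Segment,
                                StimulusProtocol,
                                activity_correlation_timecourse,
                                dynamical_pattern_separation,
                                estimate_tuning_curves, jaccard_overlap,
                                shortest_path_task, slow_morph_protocol,
                                transition_width)

SEP_V = TWO_PI / (presets.MOVING_PERIOD_TAU * presets.CYLINDER_DEEP.tau)


@pytest.fixture(scope="module")
def sep_results(grid):
    """Pattern separation runs at the deep-cylinder preset (shared)."""
    p = presets.CYLINDER_DEEP
    labels = sample_correlated_maps(300, p.d, np.random.default_rng(7))
    kw = dict(labels=labels, eps=presets.MOVING_INPUT_EPS, grid=grid, seed=1)
    return {
        "labels": labels,
        "A+": dynamical_pattern_separation(p, SEP_V, "A", **kw),
        "B+": dynamical_pattern_separation(p, SEP_V, "B", **kw),
        "B-": dynamical_pattern_separation(p, -SEP_V, "B", **kw),
    }


class TestTuningCurves:
    def test_single_ring_preferred_is_circular_midpoint(self, grid):
        p = presets.SINGLE_RING
        labels = sample_correlated_maps(40, p.d, np.random.default_rng(0))
        tc = estimate_tuning_curves(p, "single_ring", labels=labels,
                                    n_locations=16, seed=1, eps=0.05,
                                    grid=grid)
        for m in ("A", "B"):
            active = ~tc.silent[m]
            err = circ_dist(tc.preferred[m][active],
                            labels.theta_mid[active])
            assert np.median(err) < 0.1
        # identical tuning across maps
        both = ~(tc.silent["A"] | tc.silent["B"])
        assert np.median(circ_dist(tc.preferred["A"][both],
                                   tc.preferred["B"][both])) < 0.1

    def test_double_ring_at_d1_preferred_equals_assigned(self, grid):
        p = presets.DOUBLE_RING
        labels = sample_correlated_maps(40, p.d, np.random.default_rng(2))
        tc = estimate_tuning_curves(p, "double_ring", labels=labels,
                                    n_locations=16, seed=3, eps=0.1,
                                    grid=grid)
        for m, assigned in (("A", labels.theta_A), ("B", labels.theta_B)):
            active = ~tc.silent[m]
            assert active.sum() > 10
            err = circ_dist(tc.preferred[m][active], assigned[active])
            assert np.median(err) < 0.12

    def test_cylinder_unreliable_coding(self, grid):
        # repeated presentations of one location from random initial
        # conditions: mid-|phi| neurons respond on some presentations only
        p = presets.CYLINDER_DEEP
        labels = sample_correlated_maps(120, p.d, np.random.default_rng(4))
        tc = estimate_tuning_curves(p, "cylinder", labels=labels,
                                    n_locations=4, n_presentations=8,
                                    seed=5, eps=0.1, grid=grid)
        resp = tc.per_presentation["A"]  # (n_pres, n_neurons, n_loc)
        peak = resp.max()
        responded = resp[:, :, 0] > 0.01 * peak  # (n_pres, n_neurons)
        frac = responded.mean(axis=0)
        mid = (np.abs(labels.phi) > 0.4) & (np.abs(labels.phi) < 1.2)
        assert np.any((frac[mid] > 0.0) & (frac[mid] < 1.0))

    def test_regime_mismatch_raises(self, grid):
        with pytest.raises(RegimeMismatchError):
            estimate_tuning_curves(presets.SINGLE_RING, "cylinder",
                                   n_locations=4, grid=grid, n_neurons=20)


class TestPatternSeparation:
    def test_opposite_maps_nearly_disjoint(self, sep_results):
        assert jaccard_overlap(sep_results["A+"].active,
                               sep_results["B+"].active) < 0.2

    def test_map_velocity_duality(self, sep_results):
        # (map A, +v) and (map B, -v) activate the same subset
        assert jaccard_overlap(sep_results["A+"].active,
                               sep_results["B-"].active) > 0.95

    def test_x_phi_signs(self, sep_results):
        assert sep_results["A+"].x_phi[-1] > 0.2
        assert sep_results["B+"].x_phi[-1] < -0.2

    def test_common_neurons_have_small_phi(self, grid):
        # a shallower cylinder leaves some neurons active in both maps; they
        # sit near phi = 0
        p = presets.CYLINDER_SHALLOW
        labels = sample_correlated_maps(300, p.d, np.random.default_rng(9))
        v = TWO_PI / (presets.MOVING_PERIOD_TAU * p.tau)
        kw = dict(labels=labels, eps=presets.MOVING_INPUT_EPS, grid=grid,
                  seed=2)
        res_a = dynamical_pattern_separation(p, v, "A", **kw)
        res_b = dynamical_pattern_separation(p, v, "B", **kw)
        both = res_a.active & res_b.active
        only_a = res_a.active & ~res_b.active
        assert both.sum() > 0 and only_a.sum() > 0
        assert np.abs(labels.phi[both]).max() < \
            np.abs(labels.phi[only_a]).max()

    def test_noise_robust_classification(self, grid):
        # white current noise leaves the active/silent split nearly unchanged
        p = presets.CYLINDER_DEEP
        labels = sample_correlated_maps(200, p.d, np.random.default_rng(11))
        kw = dict(labels=labels, eps=presets.MOVING_INPUT_EPS, grid=grid)
        clean = dynamical_pattern_separation(p, SEP_V, "A", seed=1, **kw)
        noisy = dynamical_pattern_separation(p.with_(sigma_noise=0.05),
                                             SEP_V, "A", seed=1, **kw)
        agreement = (clean.active == noisy.active).mean()
        assert agreement >= 0.95

    def test_zero_velocity_rejected(self, grid):
        with pytest.raises(ValueError):
            dynamical_pattern_separation(presets.CYLINDER_DEEP, 0.0, "A",
                                         grid=grid)

    def test_non_cylinder_rejected(self, grid):
        with pytest.raises(RegimeMismatchError):
            dynamical_pattern_separation(presets.SINGLE_RING, SEP_V, "A",
                                         grid=grid, n_neurons=20)


class TestShortestPathTask:
    def test_degenerate_pair_is_undecided(self, grid):
        p = presets.TASK_CYLINDER
        res = shortest_path_task(p, stimuli=[(0.0, 0.0)], seed=0, grid=grid)
        assert res.trials.readout.iloc[0] == "undecided"

    def test_ccw_quarter_turn_reads_ccw(self, grid):
        p = presets.TASK_CYLINDER
        res = shortest_path_task(p, stimuli=[(0.3, 0.3 + np.pi / 2)], seed=0,
                                 grid=grid)
        assert res.trials.readout.iloc[0] == "CCW"
        assert bool(res.trials.correct.iloc[0])

    def test_cw_quarter_turn_reads_cw(self, grid):
        p = presets.TASK_CYLINDER
        res = shortest_path_task(p, stimuli=[(0.3, 0.3 - np.pi / 2)], seed=0,
                                 grid=grid)
        assert res.trials.readout.iloc[0] == "CW"

    def test_chained_accuracy_monotone_away_from_degenerate(self, grid):
        res = shortest_path_task(presets.TASK_CYLINDER, n_trials=40, seed=3,
                                 grid=grid)
        tr = res.trials
        edges = [0, np.pi / 8, 7 * np.pi / 8, np.pi]
        acc = [tr[(tr.oriented.abs() >= lo) & (tr.oriented.abs() < hi)]
               .correct.mean()
               for lo, hi in zip(edges[:-1], edges[1:])]
        # middle band beats both degenerate bands
        assert acc[1] >= 0.9
        assert acc[1] >= acc[0] and acc[1] >= acc[2]

    def test_determinism(self, grid):
        a = shortest_path_task(presets.TASK_CYLINDER, n_trials=3, seed=9,
                               grid=grid)
        b = shortest_path_task(presets.TASK_CYLINDER, n_trials=3, seed=9,
                               grid=grid)
        assert a.trials.equals(b.trials)

    def test_non_cylinder_rejected(self, grid):
        with pytest.raises(RegimeMismatchError):
            shortest_path_task(presets.SINGLE_RING, n_trials=1, grid=grid)


@pytest.fixture(scope="module")
def dr_run(grid):
    return slow_morph_protocol(presets.DOUBLE_RING, mode="two_maps",
                               eps=0.15, seed=1, grid=grid,
                               T=200 * presets.DOUBLE_RING.tau,
                               n_samples=81)


class TestSlowMorph:
    def test_double_ring_mu_flips_near_mid(self, dr_run):
        T = dr_run.t[-1]
        assert dr_run.order_params["mu"][0] > 0.5
        assert dr_run.order_params["mu"][-1] < -0.5
        assert abs(dr_run.transition_time - T / 2) < 0.2 * T

    def test_correlation_traces_cross(self, dr_run):
        corr_a, corr_b = dr_run.corr_A, dr_run.corr_B
        assert corr_a[1] > 0.9 and corr_b[-1] > 0.9
        crossings = np.where(np.diff(np.sign(corr_a - corr_b)) != 0)[0]
        assert len(crossings) >= 1
        t_cross = dr_run.t[crossings[0]]
        assert abs(t_cross - dr_run.t[-1] / 2) < 0.25 * dr_run.t[-1]

    def test_cylinder_transition_later_than_double_ring(self, grid, dr_run):
        cyl = slow_morph_protocol(presets.MORPH_CYLINDER, mode="two_maps",
                                  eps=0.15, seed=1, grid=grid,
                                  T=200 * presets.MORPH_CYLINDER.tau,
                                  n_samples=81)
        assert cyl.transition_time > dr_run.transition_time

    def test_weakly_correlated_sharper_than_morph_equiv(self, grid):
        # needs the slow (default-T) schedule: at fast morphs the driven
        # overshoot masks the transition shape
        kw = dict(eps=0.15, seed=1, grid=grid, n_samples=101)
        two = slow_morph_protocol(presets.MORPH_CYLINDER, mode="two_maps", **kw)
        equiv = slow_morph_protocol(presets.MORPH_CYLINDER, mode="morph_equiv",
                                    **kw)
        w_two = transition_width(two.t, two.order_params["x_phi"])
        w_eq = transition_width(equiv.t, equiv.order_params["x_phi"])
        assert w_two < w_eq

    def test_full_morph_mode_runs_and_transitions(self):
        coarse = Grid(n_theta=64, n_phi=33)
        res = slow_morph_protocol(presets.MORPH_CYLINDER, mode="full_morph",
                                  eps=0.15, seed=1, grid=coarse, n_samples=81)
        x = res.order_params["x_phi"]
        assert x[15] > 0 and x[-1] < 0
        assert res.transition_time is not None
        assert res.transition_time > res.t[-1] / 2


class TestCorrelationTimecourse:
    def test_identical_run_gives_unity(self, rng):
        frames = rng.random((5, 8, 8)) + 0.1
        other = rng.random((5, 8, 8)) + 0.1
        corr_a, corr_b = activity_correlation_timecourse(frames, frames, other)
        np.testing.assert_allclose(corr_a, 1.0, atol=1e-12)
        assert np.all(corr_b < 1.0)

    def test_piecewise_identical_step(self, rng):
        ref_a = rng.random((6, 10)) + 0.1
        ref_b = rng.random((6, 10)) + 0.1
        run = np.concatenate([ref_a[:3], ref_b[3:]])
        corr_a, corr_b = activity_correlation_timecourse(run, ref_a, ref_b)
        np.testing.assert_allclose(corr_a[:3], 1.0, atol=1e-12)
        np.testing.assert_allclose(corr_b[3:], 1.0, atol=1e-12)

    def test_zero_variance_flagged_nan(self):
        run = np.ones((2, 5))
        ref = np.random.default_rng(0).random((2, 5))
        corr_a, _ = activity_correlation_timecourse(run, ref, ref)
        assert np.all(np.isnan(corr_a))

    def test_misaligned_shapes_rejected(self):
        with pytest.raises(ValueError):
            activity_correlation_timecourse(np.ones((2, 3)), np.ones((2, 4)),
                                            np.ones((2, 4)))


def test_protocol_duration_validation():
    with pytest.raises(ValueError):
        Segment(duration=-1.0)
    proto = StimulusProtocol([Segment(1.0), Segment(2.0)])
    assert proto.total_duration == 3.0
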