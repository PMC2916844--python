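"""In-silico stimulation protocols and their readouts.

All protocols drive the reduced mean-field dynamics (or, for the stored
morph continuum, the field simulator) with tuned inputs and read out neuron
responses through the quasi-steady profile at the neurons' labels:

- tuning curves under static tuned inputs, per stimulated map;
- dynamical pattern separation under a smoothly moving input;
- the delayed shortest-path discrimination task (memory effect);
- the slow-morph remapping protocol with activity-correlation readout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Callable, Optional, Sequence, Union

import numpy as np

from .geometry import NeuronLabels, TWO_PI, sample_correlated_maps, signed_arc, wrap_angle
from .meanfield import (FieldSimulator, Grid, MFTrajectory, ModelParams,
                        OrderParameters, TunedInput, integrate_mf,
                        moments_from_op, op_from_moments, rates_from_moments,
                        MORPH_EQUIV_DISTANCE)
from .phase import Regime, classify_regime, solve_fixed_point

__all__ = [
    "StimulusProtocol",
    "Segment",
    "TuningCurve",
    "PatternSeparationResult",
    "ShortestPathResult",
    "SlowMorphResult",
    "RegimeMismatchError",
    "run_schedule",
    "random_initial_moments",
    "estimate_tuning_curves",
    "dynamical_pattern_separation",
    "shortest_path_task",
    "slow_morph_protocol",
    "activity_correlation_timecourse",
    "jaccard_overlap",
]

#: A neuron counts as silent in a map when its peak (averaged) response
#: stays below this fraction of the population peak.
SILENT_FRACTION = 0.01

#: |x_phi| below this fraction of its admissible half-range reads out as
#: "undecided" (avoids sign flips from numerical noise near degenerate
#: stimulus pairs).
UNDECIDED_FRACTION = 0.05


class RegimeMismatchError(RuntimeError):
    """The protocol's regime precondition does not hold for these parameters."""


@dataclass
class Segment:
    duration: float
    input_spec: Optional[TunedInput] = None

    def __post_init__(self):
        if self.duration < 0.0:
            raise ValueError("segment durations must be >= 0")


@dataclass
class StimulusProtocol:
    """Piecewise schedule of tuned-input segments."""

    segments: Sequence[Segment]

    @property
    def total_duration(self) -> float:
        return float(sum(s.duration for s in self.segments))


def run_schedule(m_init: np.ndarray, params: ModelParams,
                 protocol: StimulusProtocol, grid: Grid, seed=None,
                 t0: float = 0.0, samples_per_segment: int = 9):
    """Integrate a piecewise schedule; returns (trajectory, segment end indices)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ts, ms, ends = [], [], []
    m = np.asarray(m_init, dtype=float)
    t = t0
    for seg in protocol.segments:
        if seg.duration == 0.0:
            ends.append(len(ts))
            continue
        t_eval = np.linspace(t, t + seg.duration, samples_per_segment)
        traj = integrate_mf(m, params, input_spec=seg.input_spec,
                            t_end=t + seg.duration, t0=t, grid=grid,
                            t_eval=t_eval, seed=rng)
        ts.append(traj.t)
        ms.append(traj.moments)
        m = traj.moments[-1]
        t = traj.t[-1]
        ends.append(sum(len(x) for x in ts) - 1)
        if traj.event is not None:
            full = MFTrajectory(t=np.concatenate(ts), moments=np.vstack(ms),
                                params=params, event=traj.event)
            return full, ends
    full = MFTrajectory(t=np.concatenate(ts), moments=np.vstack(ms),
                        params=params, event=None)
    return full, ends


def _x_half_range(size: float, d: float) -> float:
    """Admissible half-range of x_phi for a bump of the given size."""
    return max(math.pi / 2.0 - size / d, 0.0) if d > 0 else 0.0


def random_initial_moments(params: ModelParams, rng, grid: Grid,
                           fp: Optional[OrderParameters] = None,
                           psi0_center: Optional[float] = None,
                           psi0_halfwidth: float = math.pi) -> np.ndarray:
    """A random localized state on the attractor family (random angles/branch).

    ``psi0_center``/``psi0_halfwidth`` restrict the bump angle draw (used by
    the tuning protocol so that the slow travel towards a weak tuned input
    does not dominate the settling time); the marginal offset x_phi is always
    drawn uniformly over its full admissible range.
    """
    if fp is None:
        fp = solve_fixed_point(params, grid=grid)
    w = _x_half_range(fp.size, params.d)
    if psi0_center is None:
        psi0 = rng.uniform(0.0, TWO_PI)
    else:
        psi0 = psi0_center + rng.uniform(-psi0_halfwidth, psi0_halfwidth)
    op = OrderParameters(
        amp=fp.amp, size=fp.size,
        mu=fp.mu * (1.0 if rng.random() < 0.5 else -1.0),
        psi0=wrap_angle(psi0),
        x_phi=rng.uniform(-w, w) if w > 0 else 0.0)
    return moments_from_op(op, params)


# ---------------------------------------------------------------------------
# tuning curves
# ---------------------------------------------------------------------------

@dataclass
class TuningCurve:
    """Per-neuron responses versus input location, for each stimulated map."""

    labels: NeuronLabels
    locations: np.ndarray                       # (n_loc,)
    responses: dict                             # map name -> (n_neurons, n_loc)
    preferred: dict = dc_field(default_factory=dict)   # map name -> (n_neurons,) angle or nan
    silent: dict = dc_field(default_factory=dict)      # map name -> bool mask
    per_presentation: dict = dc_field(default_factory=dict)  # map -> (n_pres, n_neurons, n_loc)


def _preferred_angle(locations: np.ndarray, resp: np.ndarray) -> float:
    """Argmax over the location grid, refined by circular quadratic interpolation."""
    k = int(np.argmax(resp))
    n = len(locations)
    y0, y1, y2 = resp[(k - 1) % n], resp[k], resp[(k + 1) % n]
    denom = y0 - 2.0 * y1 + y2
    shift = 0.0 if abs(denom) < 1e-15 else 0.5 * (y0 - y2) / denom
    shift = float(np.clip(shift, -0.5, 0.5))
    dloc = TWO_PI / n
    return float(wrap_angle(locations[k] + shift * dloc))


def estimate_tuning_curves(params: ModelParams, regime: Union[str, Regime],
                           labels: Optional[NeuronLabels] = None,
                           stimulation: str = "fixed_random",
                           n_locations: int = 16, n_presentations: int = 1,
                           seed=0, eps: float = 0.05,
                           t_settle: Optional[float] = None,
                           grid: Optional[Grid] = None,
                           n_neurons: int = 200) -> TuningCurve:
    """Simulated tuning curves per stimulated map (A and B).

    Each presentation starts from a random state on the attractor family and
    settles under a static tuned input; responses are the quasi-steady rates
    at the neuron labels, averaged over presentations.
    """
    if grid is None:
        grid = Grid(n_theta=128, n_phi=65)
    regime = Regime(regime)
    actual = classify_regime(params, grid=grid).label
    if actual != regime:
        raise RegimeMismatchError(
            f"parameters are in the {actual.value} regime, not {regime.value}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if labels is None:
        labels = sample_correlated_maps(n_neurons, params.d, rng)
    if t_settle is None:
        t_settle = 60.0 * params.tau
    fp = solve_fixed_point(params, grid=grid)
    locations = np.linspace(0.0, TWO_PI, n_locations, endpoint=False)
    responses, per_pres = {}, {}
    for map_name in ("A", "B"):
        resp = np.zeros((n_presentations, labels.n, n_locations))
        for p in range(n_presentations):
            for k, xi in enumerate(locations):
                inp = TunedInput(map_select=map_name, location=float(xi), eps=eps)
                m0 = random_initial_moments(params, rng, grid, fp=fp,
                                            psi0_center=float(xi),
                                            psi0_halfwidth=0.75)
                traj = integrate_mf(m0, params, input_spec=inp, t_end=t_settle,
                                    grid=grid, t_eval=np.array([t_settle]))
                resp[p, :, k] = rates_from_moments(
                    traj.final_moments, params, labels.theta_mid, labels.phi,
                    input_spec=inp, t=t_settle)
        responses[map_name] = resp.mean(axis=0)
        per_pres[map_name] = resp
    tc = TuningCurve(labels=labels, locations=locations, responses=responses,
                     per_presentation=per_pres)
    pop_peak = max(r.max() for r in responses.values())
    for map_name, resp in responses.items():
        peak = resp.max(axis=1)
        silent = peak < SILENT_FRACTION * pop_peak
        pref = np.full(labels.n, np.nan)
        for i in range(labels.n):
            if not silent[i]:
                pref[i] = _preferred_angle(locations, resp[i])
        tc.preferred[map_name] = pref
        tc.silent[map_name] = silent
    return tc


# ---------------------------------------------------------------------------
# dynamical pattern separation
# ---------------------------------------------------------------------------

@dataclass
class PatternSeparationResult:
    labels: NeuronLabels
    t: np.ndarray
    x_phi: np.ndarray
    active: np.ndarray          # bool per neuron (responds during final cycle)
    peak_response: np.ndarray   # per neuron
    trajectory: MFTrajectory


def jaccard_overlap(a: np.ndarray, b: np.ndarray) -> float:
    """|A and B| / |A or B| for boolean masks (1.0 when both empty)."""
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def dynamical_pattern_separation(params: ModelParams, velocity: float,
                                 map_select: Union[str, float],
                                 t_end: Optional[float] = None, seed=0,
                                 labels: Optional[NeuronLabels] = None,
                                 eps: float = 0.05,
                                 grid: Optional[Grid] = None,
                                 n_neurons: int = 400) -> PatternSeparationResult:
    """Moving tuned input in one map; classify responsive vs silent neurons.

    Requires cylinder-regime parameters and a nonzero angular velocity.  The
    active subset is read from the final full input revolution, after the
    bump offset x_phi has settled at one end of its admissible range.
    """
    if velocity == 0.0:
        raise ValueError("velocity must be nonzero")
    if grid is None:
        grid = Grid(n_theta=128, n_phi=65)
    res = classify_regime(params, grid=grid)
    if res.label != Regime.cylinder:
        raise RegimeMismatchError(
            f"dynamical pattern separation needs the cylinder regime, got {res.label.value}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if labels is None:
        labels = sample_correlated_maps(n_neurons, params.d, rng)
    period = TWO_PI / abs(velocity)
    if t_end is None:
        t_end = 2.5 * period
    inp = TunedInput(map_select=map_select,
                     location=lambda t: wrap_angle(velocity * t), eps=eps)
    fp = res.fixed_point
    m0 = moments_from_op(
        OrderParameters(amp=fp.amp, size=fp.size, mu=fp.mu, psi0=0.0, x_phi=0.0),
        params)
    n_rec = 161
    t_eval = np.linspace(0.0, t_end, n_rec)
    traj = integrate_mf(m0, params, input_spec=inp, t_end=t_end, grid=grid,
                        t_eval=t_eval, seed=rng)
    x_tr = traj.order_parameters()["x_phi"]
    final = traj.t >= (t_end - period)
    peak = np.zeros(labels.n)
    for t_i, m_i in zip(traj.t[final], traj.moments[final]):
        r = rates_from_moments(m_i, params, labels.theta_mid, labels.phi,
                               input_spec=inp, t=t_i)
        peak = np.maximum(peak, r)
    active = peak > SILENT_FRACTION * peak.max()
    return PatternSeparationResult(labels=labels, t=traj.t, x_phi=x_tr,
                                   active=active, peak_response=peak,
                                   trajectory=traj)


# ---------------------------------------------------------------------------
# shortest-path discrimination task
# ---------------------------------------------------------------------------

@dataclass
class ShortestPathResult:
    trials: "object"            # pandas DataFrame of TrialRecords
    accuracy: float             # over decided, non-degenerate trials
    params: ModelParams
    half_range: float           # admissible |x_phi| range of the bump


def shortest_path_task(params: ModelParams, n_trials: int = 200,
                       durations: tuple = None, seed=0, eps: float = 0.4,
                       grid: Optional[Grid] = None, map_select: str = "A",
                       band: tuple = (math.pi / 8, 7 * math.pi / 8),
                       stimuli: Optional[Sequence] = None) -> ShortestPathResult:
    """Chained delayed discrimination: is the shortest arc xi1 -> xi2 CW or CCW?

    Trials run back-to-back with no activity reset; the readout is the sign
    of x_phi at the end of the second stimulus (positive = CCW under
    stimulation of map A).  Accuracy is reported over decided trials with
    |oriented distance| inside ``band``.

    ``stimuli`` may supply explicit (xi1, xi2) pairs instead of random
    draws; the run is then started deterministically at psi0 = 0, x_phi = 0.
    """
    import pandas as pd

    if stimuli is not None:
        n_trials = len(stimuli)
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if grid is None:
        grid = Grid(n_theta=128, n_phi=65)
    res = classify_regime(params, grid=grid)
    if res.label != Regime.cylinder:
        raise RegimeMismatchError(
            f"the memory task needs the cylinder regime, got {res.label.value}")
    if durations is None:
        durations = (80.0 * params.tau, 30.0 * params.tau, 80.0 * params.tau)
    t_stim1, t_delay, t_stim2 = durations
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fp = res.fixed_point
    w = _x_half_range(fp.size, params.d)
    dead_band = UNDECIDED_FRACTION * w
    if stimuli is None:
        m = random_initial_moments(params, rng, grid, fp=fp)
    else:
        m = moments_from_op(OrderParameters(amp=fp.amp, size=fp.size, mu=0.0,
                                            psi0=0.0, x_phi=0.0), params)
    # pre-stimulus settling, no tuned input
    traj = integrate_mf(m, params, t_end=20.0 * params.tau, grid=grid,
                        t_eval=np.array([20.0 * params.tau]))
    m = traj.final_moments
    t = traj.t[-1]
    rows = []
    for trial in range(n_trials):
        if stimuli is not None:
            xi1, xi2 = (float(x) for x in stimuli[trial])
        else:
            xi1 = float(rng.uniform(0.0, TWO_PI))
            xi2 = float(rng.uniform(0.0, TWO_PI))
        for dur, loc in ((t_stim1, xi1), (t_delay, None), (t_stim2, xi2)):
            inp = (None if loc is None
                   else TunedInput(map_select=map_select, location=loc, eps=eps))
            traj = integrate_mf(m, params, input_spec=inp, t_end=t + dur, t0=t,
                                grid=grid, t_eval=np.array([t + dur]), seed=rng)
            m = traj.final_moments
            t = traj.t[-1]
        x_end = op_from_moments(m, params).x_phi
        oriented = float(signed_arc(xi1, xi2))
        if abs(x_end) < dead_band:
            readout = "undecided"
        else:
            readout = "CCW" if x_end > 0 else "CW"
        truth = "CCW" if oriented > 0 else ("CW" if oriented < 0 else "undecided")
        rows.append({"trial": trial, "xi1": xi1, "xi2": xi2,
                     "oriented": oriented, "x_phi_end": float(x_end),
                     "readout": readout,
                     "correct": readout == truth and readout != "undecided"})
    trials = pd.DataFrame(rows)
    in_band = (trials["oriented"].abs() >= band[0]) & \
              (trials["oriented"].abs() <= band[1])
    sel = trials[in_band]
    accuracy = float(sel["correct"].mean()) if len(sel) else float("nan")
    return ShortestPathResult(trials=trials, accuracy=accuracy, params=params,
                              half_range=w)


# ---------------------------------------------------------------------------
# slow morph protocol
# ---------------------------------------------------------------------------

@dataclass
class SlowMorphResult:
    t: np.ndarray
    morph_index: np.ndarray
    order_params: dict          # arrays: amp, size, mu, psi0, x_phi
    corr_A: np.ndarray
    corr_B: np.ndarray
    transition_time: Optional[float]
    mode: str
    params: ModelParams


def _pearson_frames(run: np.ndarray, ref: np.ndarray) -> np.ndarray:
    out = np.full(run.shape[0], np.nan)
    for i in range(run.shape[0]):
        a = run[i].ravel()
        b = ref[i].ravel()
        sa, sb = a.std(), b.std()
        if sa > 0 and sb > 0:
            out[i] = float(np.corrcoef(a, b)[0, 1])
    return out


def activity_correlation_timecourse(run_frames: np.ndarray,
                                    ref_a_frames: np.ndarray,
                                    ref_b_frames: np.ndarray):
    """Per-frame Pearson correlation of a run against two reference runs.

    Frames with zero variance yield NaN (flagged undefined).
    """
    if not (run_frames.shape == ref_a_frames.shape == ref_b_frames.shape):
        raise ValueError("run and reference frame stacks must be aligned")
    return (_pearson_frames(run_frames, ref_a_frames),
            _pearson_frames(run_frames, ref_b_frames))


def _crossing_time(t: np.ndarray, y: np.ndarray,
                   settle_frac: float = 0.15) -> Optional[float]:
    """First sign-change time of y after its early plateau, interpolated.

    The first ``settle_frac`` of the run is skipped so that transients around
    the protocol start (the readout sits at 0 before the input displaces it)
    do not register as a transition.
    """
    k = int(settle_frac * len(y))
    s = np.sign(y)
    idx = np.where(s[k:-1] * s[k + 1:] < 0)[0]
    if len(idx) == 0:
        return None
    i = int(idx[0]) + k
    y0, y1 = y[i], y[i + 1]
    return float(t[i] + (t[i + 1] - t[i]) * (-y0) / (y1 - y0))


def transition_width(t: np.ndarray, y: np.ndarray,
                     level: float = 0.5) -> Optional[float]:
    """Duration of the swing between +level and -level of the signal's extreme.

    A smaller width means a sharper transition between the two saturated
    branches of the readout.
    """
    y = np.asarray(y, dtype=float)
    t_cross = _crossing_time(t, y)
    if t_cross is None:
        return None
    scale = level * np.max(np.abs(y))
    before = (t < t_cross) & (np.sign(y) == np.sign(y[int(0.15 * len(y))]))
    above = np.where(before & (np.abs(y) >= scale))[0]
    after = np.where((t > t_cross) & (np.abs(y) >= scale))[0]
    if len(above) == 0 or len(after) == 0:
        return None
    return float(t[after[0]] - t[above[-1]])


def slow_morph_protocol(params: ModelParams, mode: str = "two_maps",
                        eps: float = 0.05, T: Optional[float] = None,
                        seed=0, grid: Optional[Grid] = None,
                        n_samples: int = 121,
                        t_settle: Optional[float] = None) -> SlowMorphResult:
    """Slow linear morph of the stimulated environment from map A to map B.

    The input location makes one full circle over the morph duration T while
    the stimulated map index ramps linearly 0 -> 1.  Reference runs repeat
    the identical input trajectory with the map index frozen at 0 (A) and 1
    (B); correlation traces compare the run's activity frames to the
    references.  Modes: ``two_maps`` (stored pair at params.d),
    ``morph_equiv`` (stored pair at the morph-equivalent distance),
    ``full_morph`` (stored continuum, field simulator).

    The transition time is read from the regime's order parameter (mu for
    double ring, x_phi for cylinder), as the first zero crossing after the
    morph starts.
    """
    if grid is None:
        grid = Grid(n_theta=128, n_phi=65)
    if mode == "morph_equiv":
        params = params.with_(d=MORPH_EQUIV_DISTANCE)
    if T is None:
        T = 400.0 * params.tau
    if t_settle is None:
        t_settle = 40.0 * params.tau
    omega = TWO_PI / T

    def location(t):
        return wrap_angle(omega * max(t, 0.0))

    def morph_index(t):
        return float(np.clip(t / T, 0.0, 1.0))

    t_eval = np.linspace(0.0, T, n_samples)
    if mode in ("two_maps", "morph_equiv"):
        run = _morph_run_moments(params, eps, location, morph_index, t_eval,
                                 t_settle, grid, seed)
        ref_a = _morph_run_moments(params, eps, location, lambda t: 0.0,
                                   t_eval, t_settle, grid, seed)
        ref_b = _morph_run_moments(params, eps, location, lambda t: 1.0,
                                   t_eval, t_settle, grid, seed,
                                   init_map=1.0)
        frames = {}
        for name, (traj, inp) in (("run", run), ("A", ref_a), ("B", ref_b)):
            stack = np.stack([
                rates_from_moments(m_i, params, grid.TH, grid.PH,
                                   input_spec=inp, t=t_i)
                for t_i, m_i in zip(traj.t, traj.moments)])
            frames[name] = stack
        cols = run[0].order_parameters()
        t_out = run[0].t
    elif mode == "full_morph":
        run = _morph_run_field(params, eps, location, morph_index, t_eval,
                               t_settle, grid, seed)
        ref_a = _morph_run_field(params, eps, location, lambda t: 0.0,
                                 t_eval, t_settle, grid, seed)
        ref_b = _morph_run_field(params, eps, location, lambda t: 1.0,
                                 t_eval, t_settle, grid, seed, init_map=1.0)
        frames = {"run": run[0], "A": ref_a[0], "B": ref_b[0]}
        cols = run[1]
        t_out = t_eval
    else:
        raise ValueError(f"unknown slow-morph mode {mode!r}")

    corr_a, corr_b = activity_correlation_timecourse(frames["run"],
                                                     frames["A"], frames["B"])
    regime = classify_regime(params, grid=grid).label
    signal = cols["mu"] if regime == Regime.double_ring else cols["x_phi"]
    transition = _crossing_time(t_out, np.asarray(signal))
    return SlowMorphResult(t=t_out, morph_index=np.array([morph_index(t) for t in t_out]),
                           order_params=cols, corr_A=corr_a, corr_B=corr_b,
                           transition_time=transition, mode=mode, params=params)


def _morph_run_moments(params, eps, location, morph_index, t_eval, t_settle,
                       grid, seed, init_map: float = 0.0):
    inp = TunedInput(map_select=morph_index, location=location, eps=eps)
    init_inp = TunedInput(map_select=init_map, location=location(0.0), eps=eps)
    rng = np.random.default_rng(seed)
    fp = solve_fixed_point(params, grid=grid)
    start = OrderParameters(amp=fp.amp, size=fp.size,
                            mu=abs(fp.mu) if init_map == 0.0 else -abs(fp.mu),
                            psi0=location(0.0), x_phi=0.0)
    m = moments_from_op(start, params)
    settle = integrate_mf(m, params, input_spec=init_inp, t_end=0.0,
                          t0=-t_settle, grid=grid,
                          t_eval=np.array([0.0]), seed=rng)
    traj = integrate_mf(settle.final_moments, params, input_spec=inp,
                        t_end=float(t_eval[-1]), t0=0.0, grid=grid,
                        t_eval=t_eval, seed=rng)
    return traj, inp


def _morph_run_field(params, eps, location, morph_index, t_eval, t_settle,
                     grid, seed, init_map: float = 0.0):
    # the stored morph continuum interpolates two uncorrelated references,
    # so the stimulus family uses the d = 1 coordinates
    inp = TunedInput(map_select=morph_index, location=location, eps=eps,
                     input_d=1.0)
    init_inp = TunedInput(map_select=init_map, location=location(0.0),
                          eps=eps, input_d=1.0)
    p = params.with_(d=1.0)
    sim = FieldSimulator(p, mode="full_morph", grid=grid)
    m_field = np.maximum(np.cos(grid.TH - location(0.0)) - 0.3, 0.0) * np.ones_like(grid.PH)
    _, settled = sim.run(m_field, t_end=0.0, t0=-t_settle,
                         input_spec=init_inp, seed=seed)
    _, fields = sim.run(settled[-1], t_end=float(t_eval[-1]), t0=0.0,
                        input_spec=inp, record_times=t_eval, seed=seed)
    stack = np.stack(fields)
    cols = {k: np.empty(len(fields)) for k in ("amp", "size", "mu", "psi0", "x_phi")}
    for i, f in enumerate(fields):
        op = op_from_moments(sim.moments(f), p)
        for k in cols:
            cols[k][i] = getattr(op, k)
    return stack, cols
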