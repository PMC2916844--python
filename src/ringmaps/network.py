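"""Finite-N rate-network simulator and order-parameter estimation.

The microscopic dynamics for N threshold-linear units is

    tau dm_i/dt = -m_i + [ sum_j W_ij m_j + I_i(t) ]_+

with ``W_ij = kernel(labels_i, labels_j) / N`` (the 1/N normalization makes
the mean-field limit exact as N grows).  The noisy variant integrates the
current-based form

    tau du_i = (-u_i + sum_j W_ij [u_j]_+ + I_i) dt + sigma sqrt(2 tau) dW_i

with the Euler-Maruyama scheme (rates are [u]_+).

Because every stored map contributes a single circular harmonic, the dense
N x N matrix is exactly low rank (2 vectors per map plus the uniform term);
above ``DENSE_LIMIT`` neurons the product is evaluated implicitly, with
results identical to the dense path to floating-point tolerance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .geometry import MorphSequence, NeuronLabels, signed_arc, wrap_angle
from .meanfield import (Grid, ModelParams, OrderParameters, TunedInput,
                        _join, _split, rescaled_profile)

__all__ = [
    "CouplingMatrix",
    "NetworkState",
    "NetworkTrajectory",
    "SimulationError",
    "DENSE_LIMIT",
    "build_coupling",
    "simulate_network",
    "estimate_order_params",
]

DENSE_LIMIT = 5000


class SimulationError(RuntimeError):
    def __init__(self, message, t_last=None, state_last=None):
        super().__init__(message)
        self.t_last = t_last
        self.state_last = state_last


@dataclass
class CouplingMatrix:
    """Synaptic couplings, stored dense or as exact low-rank factors."""

    labels: NeuronLabels
    params: ModelParams
    mode: str                      # two_maps | discrete_morph
    n_morph_maps: Optional[int] = None
    dense_weights: Optional[np.ndarray] = None
    #: (n_components, N) cosine/sine factor rows; recurrent drive is
    #: (2 J / (K N)) * sum_c cos_row_c * (cos_row_c . m) + sin_row_c * (...)
    _factors: Optional[np.ndarray] = None

    @property
    def n(self) -> int:
        return self.labels.n

    @property
    def is_dense(self) -> bool:
        return self.dense_weights is not None

    @property
    def weights(self) -> np.ndarray:
        """Dense N x N matrix (materialized on demand for low-rank storage)."""
        if self.dense_weights is not None:
            return self.dense_weights
        return _dense_from_kernel(self.labels, self.params, self.mode,
                                  self.n_morph_maps)

    def matvec(self, m: np.ndarray) -> np.ndarray:
        """Recurrent input sum_j W_ij m_j."""
        if self.dense_weights is not None:
            return self.dense_weights @ m
        p, n = self.params, self.n
        acc = np.zeros(n)
        n_maps = self._factors.shape[0] // 2
        for k in range(n_maps):
            c, s = self._factors[2 * k], self._factors[2 * k + 1]
            acc += c * (c @ m) + s * (s @ m)
        scale = 2.0 * p.J_mod / n_maps
        return (scale * acc - p.J_inh * m.sum()) / n


def _map_angle_set(labels: NeuronLabels, mode: str, n_morph_maps):
    if mode == "two_maps":
        return [labels.theta_A, labels.theta_B]
    if mode == "discrete_morph":
        arc = signed_arc(labels.theta_A, labels.theta_B)
        s_grid = np.linspace(0.0, 1.0, n_morph_maps)
        return [wrap_angle(labels.theta_A + s * arc) for s in s_grid]
    raise ValueError(f"unknown coupling mode {mode!r}")


def _dense_from_kernel(labels, params, mode, n_morph_maps):
    maps = _map_angle_set(labels, mode, n_morph_maps)
    n = labels.n
    acc = np.zeros((n, n))
    for ang in maps:
        acc += np.cos(ang[:, None] - ang[None, :])
    w = (2.0 * params.J_mod / len(maps)) * acc - params.J_inh
    return w / n


def build_coupling(labels: Union[NeuronLabels, MorphSequence],
                   params: ModelParams, n_morph_maps: Optional[int] = None,
                   force_dense: Optional[bool] = None) -> CouplingMatrix:
    """Coupling matrix from a pair of maps or a morph sequence.

    Passing a MorphSequence (or ``n_morph_maps``) sums K per-map cosine
    kernels with total map weight 2 J_mod; the two-map kernel matches
    ``meanfield.morph_coupling_kernel('two_maps')`` evaluated at label pairs.
    """
    if isinstance(labels, MorphSequence):
        n_morph_maps = labels.n_maps
        labels = labels.labels
    mode = "two_maps" if n_morph_maps is None else "discrete_morph"
    if mode == "discrete_morph" and n_morph_maps < 2:
        raise ValueError("a morph coupling needs n_morph_maps >= 2")
    n = labels.n
    dense = n <= DENSE_LIMIT if force_dense is None else force_dense
    cm = CouplingMatrix(labels=labels, params=params, mode=mode,
                        n_morph_maps=n_morph_maps)
    if dense:
        cm.dense_weights = _dense_from_kernel(labels, params, mode, n_morph_maps)
    else:
        maps = _map_angle_set(labels, mode, n_morph_maps)
        rows = []
        for ang in maps:
            rows.append(np.cos(ang))
            rows.append(np.sin(ang))
        cm._factors = np.vstack(rows)
    return cm


@dataclass
class NetworkState:
    """Per-neuron rates (or currents, in the noisy scheme) at one time."""

    values: np.ndarray
    time: float
    kind: str = "rates"  # rates | currents

    @property
    def rates(self) -> np.ndarray:
        return self.values if self.kind == "rates" else np.maximum(self.values, 0.0)


@dataclass
class NetworkTrajectory:
    t: np.ndarray
    rates: np.ndarray  # (n_times, N)
    labels: NeuronLabels
    params: ModelParams

    @property
    def final_rates(self) -> np.ndarray:
        return self.rates[-1]

    def order_parameter_frame(self):
        import pandas as pd
        rows = []
        for ti, r in zip(self.t, self.rates):
            op = estimate_order_params(r, self.labels)
            rows.append({"t": ti, "amp": op.amp, "size": op.size, "mu": op.mu,
                         "psi0": op.psi0, "x_phi": op.x_phi})
        return pd.DataFrame(rows)


def _external_current(labels, params, input_spec, t):
    base = params.I0 * np.ones(labels.n)
    if input_spec is not None and input_spec.eps_of(params) != 0.0:
        base = base * (1.0 + input_spec.field(labels.theta_mid, labels.phi,
                                              t, params))
    return base


def simulate_network(state0: Union[np.ndarray, NetworkState],
                     coupling: CouplingMatrix, params: ModelParams,
                     input_spec: Optional[TunedInput] = None,
                     t_end: float = 100.0, seed=None, t0: float = 0.0,
                     record_times: Optional[np.ndarray] = None,
                     dt: Optional[float] = None,
                     rate_ceiling_factor: float = 1e6) -> NetworkTrajectory:
    """Integrate the N-neuron rate network.

    Deterministic runs (sigma_noise = 0) use adaptive RK45 and are
    reproducible bit-for-bit; noisy runs use fixed-step Euler-Maruyama on the
    currents (dt = tau/100 by default) with per-neuron white noise, and are
    reproducible given the seed.  NaN or divergence raises SimulationError
    carrying the last valid state.
    """
    labels = coupling.labels
    x0 = state0.values if isinstance(state0, NetworkState) else np.asarray(state0, dtype=float)
    if x0.shape != (labels.n,):
        raise ValueError("state size does not match the coupling matrix")
    if record_times is None:
        record_times = np.linspace(t0, t_end, 51)
    record_times = np.asarray(record_times, dtype=float)
    ceiling = rate_ceiling_factor * params.I0
    if params.sigma_noise > 0.0:
        return _simulate_em(x0, coupling, params, input_spec, t0, t_end, seed,
                            record_times, dt, ceiling)

    def rhs(t, m):
        drive = coupling.matvec(m) + _external_current(labels, params, input_spec, t)
        return (-m + np.maximum(drive, 0.0)) / params.tau

    def blowup(t, m):
        return float(np.max(np.abs(m))) - ceiling

    blowup.terminal = True
    blowup.direction = 1.0
    sol = solve_ivp(rhs, (t0, t_end), x0, method="RK45", rtol=1e-6, atol=1e-8,
                    t_eval=record_times, events=blowup)
    if sol.status == -1 or np.any(~np.isfinite(sol.y)):
        raise SimulationError(f"network integration failed: {sol.message}",
                              t_last=sol.t[-1] if len(sol.t) else t0,
                              state_last=sol.y[:, -1] if sol.y.size else x0)
    if sol.status == 1:
        raise SimulationError(
            "network activity diverged (amplitude instability)",
            t_last=float(sol.t_events[0][0]), state_last=sol.y_events[0][0])
    return NetworkTrajectory(t=sol.t, rates=sol.y.T.copy(), labels=labels,
                             params=params)


def _simulate_em(x0, coupling, params, input_spec, t0, t_end, seed,
                 record_times, dt, ceiling):
    labels = coupling.labels
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if dt is None:
        dt = params.tau / 100.0
    n_steps = int(math.ceil((t_end - t0) / dt))
    u = x0.copy()  # currents; initial rates [u]_+ equal x0 where positive
    t = t0
    out, k_out = [], 0
    sqdt = params.sigma_noise * math.sqrt(2.0 * dt / params.tau)
    while k_out < len(record_times) and record_times[k_out] <= t + 1e-12:
        out.append(np.maximum(u, 0.0)); k_out += 1
    for _ in range(n_steps):
        rates = np.maximum(u, 0.0)
        drive = coupling.matvec(rates) + _external_current(labels, params,
                                                           input_spec, t)
        u = u + (dt / params.tau) * (-u + drive) + sqdt * rng.standard_normal(labels.n)
        t += dt
        if not np.all(np.isfinite(u)) or np.max(np.abs(u)) > ceiling:
            raise SimulationError("network activity diverged", t_last=t,
                                  state_last=u)
        while k_out < len(record_times) and record_times[k_out] <= t + 1e-12:
            out.append(np.maximum(u, 0.0)); k_out += 1
    return NetworkTrajectory(t=record_times[: len(out)], rates=np.array(out),
                             labels=labels, params=params)


# ---------------------------------------------------------------------------
# order-parameter estimation from activity
# ---------------------------------------------------------------------------

def _moments_from_rates(rates: np.ndarray, labels: NeuronLabels) -> np.ndarray:
    m0 = float(rates.mean())
    m_a = complex(np.mean(rates * np.exp(-1j * labels.theta_A)))
    m_b = complex(np.mean(rates * np.exp(-1j * labels.theta_B)))
    return _join(m0, m_a, m_b)


def estimate_order_params(rates: np.ndarray, labels: NeuronLabels,
                          grid: Optional[Grid] = None,
                          modulation_floor: float = 0.02) -> OrderParameters:
    """Order parameters from per-neuron rates (Fig. 9-style estimator).

    The mean and first circular harmonics in each map coordinate give
    (mu, psi0, x_phi) directly; the size is recovered by matching the
    modulation-to-mean ratio of the analytic bump profile, and the amplitude
    by rescaling.  Requires no knowledge of the coupling parameters.

    When the total relative modulation falls below ``modulation_floor`` the
    angular estimates are sampling noise, so the uniform solution
    (size = pi, mu = 0, amp = mean rate) is reported instead.
    """
    rates = np.asarray(rates, dtype=float)
    if rates.ndim != 1 or len(rates) != labels.n:
        raise ValueError("rates must be a vector matching the labels")
    if labels.n < 10:
        raise ValueError("need at least 10 neurons to estimate order parameters")
    if grid is None:
        grid = Grid(n_theta=128, n_phi=65)
    d = labels.d
    m0, m_a, m_b = _split(_moments_from_rates(rates, labels))
    r_a, r_b = abs(m_a), abs(m_b)
    big_r = r_a + r_b
    if m0 <= 0.0 or big_r <= modulation_floor * m0:
        return OrderParameters(amp=float(max(m0, 0.0)),
                               size=math.pi if m0 > 0 else 0.0,
                               mu=0.0, psi0=0.0, x_phi=0.0)
    mu = float(np.clip((r_a - r_b) / big_r, -1.0, 1.0))
    psi_a, psi_b = -np.angle(m_a), -np.angle(m_b)
    half = signed_arc(psi_a, psi_b) / 2.0
    psi0 = float(wrap_angle(psi_a + half))
    x_phi = 0.0 if d == 0.0 else float(-half / d)

    tr = grid.trig(d)

    def ratio(size):
        """(|m_A| + |m_B|) / m0 of the unit profile; decreasing in size."""
        g = rescaled_profile(size, mu, d, grid, x_phi=x_phi, psi0=0.0)
        g0 = grid.average(g)
        if g0 <= 0.0:
            return np.inf
        g_a = abs(grid.average(g * tr["cosA"]) - 1j * grid.average(g * tr["sinA"]))
        g_b = abs(grid.average(g * tr["cosB"]) - 1j * grid.average(g * tr["sinB"]))
        return (g_a + g_b) / g0

    target = big_r / m0
    lo, hi = 1e-3, math.pi
    f_lo, f_hi = ratio(lo) - target, ratio(hi) - target
    if f_hi > 0.0:
        size = math.pi
    elif f_lo < 0.0:
        size = lo
    else:
        size = brentq(lambda s: ratio(s) - target, lo, hi, xtol=1e-8)
    g = rescaled_profile(size, mu, d, grid, x_phi=x_phi, psi0=0.0)
    g0 = grid.average(g)
    amp = m0 / g0 if g0 > 0 else 0.0
    return OrderParameters(amp=float(amp), size=float(size), mu=mu,
                           psi0=psi0, x_phi=x_phi)
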