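"""Reduced mean-field dynamics of a ring network storing two correlated maps.

The network activity ``m(theta, phi, t)`` obeys threshold-linear rate dynamics

    tau dm/dt = -m + [ J_mod (<m cos(th_A - th_A')> + <m cos(th_B - th_B')>)
                       - J_inh <m> + I(theta, phi, t) ]_+

where ``<.>`` is the population average over the uniform (theta, phi) density
and ``th_A = theta + d phi``, ``th_B = theta - d phi``.  Because the coupling
contains only the first circular harmonic of each map plus a uniform term, the
dynamics closes exactly on five real moments

    m0 = <m>,   m_A = <m e^{-i th_A}>,   m_B = <m e^{-i th_B}>,

integrated here as the state vector ``[m0, Re m_A, Im m_A, Re m_B, Im m_B]``.

The five user-facing order parameters are reconstructed from the moments:

    amp   = J_mod (|m_A| + |m_B|)              bump amplitude scale
    size  = arccos((J_inh m0 - I0) / amp)      half-width of the active region
    mu    = (|m_A| - |m_B|) / (|m_A| + |m_B|)  map preference in [-1, 1]
    psi0  = (psi_A + psi_B)/2                  bump angle on the middle map
    x_phi = (psi_A - psi_B)/(2 d)              bump offset along phi

with ``psi_A = -arg m_A`` and ``psi_B = -arg m_B``, and the steady activity
profile is

    m(theta, phi) = amp [ cos(u) cos(d v) - mu sin(u) sin(d v) - cos(size) ]_+

for ``u = theta - psi0``, ``v = phi - x_phi``.  A change of the uniform input
``I0`` rescales ``amp`` but leaves (size, mu, psi0, x_phi) untouched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Callable, Optional, Union

import numpy as np
from scipy.integrate import solve_ivp

from .geometry import PHI_HALF_WIDTH, TWO_PI, signed_arc, wrap_angle

__all__ = [
    "ModelParams",
    "OrderParameters",
    "Grid",
    "ActivityProfile",
    "TunedInput",
    "MFTrajectory",
    "IntegrationFailureError",
    "MORPH_EQUIV_DISTANCE",
    "moments_from_op",
    "op_from_moments",
    "moment_rhs",
    "order_param_rhs",
    "steady_profile",
    "rescaled_profile",
    "profile_at",
    "rates_from_moments",
    "integrate_mf",
    "morph_coupling_kernel",
    "FieldSimulator",
]

#: Effective pair distance equivalent (to first order) to storing the whole
#: morph sequence between two uncorrelated maps: matching the first term of
#: the Euler product for sin(x)/x, cos(d x) ~ 1 - d^2 x^2 / 2 against
#: 1 - x^2 / pi^2 gives d = sqrt(2)/pi.
MORPH_EQUIV_DISTANCE = math.sqrt(2.0) / math.pi


class IntegrationFailureError(RuntimeError):
    """ODE integration failed; carries the last valid state."""

    def __init__(self, message, t_last=None, moments_last=None):
        super().__init__(message)
        self.t_last = t_last
        self.moments_last = moments_last


@dataclass(frozen=True)
class ModelParams:
    """Constitutive parameters of the network."""

    d: float            # map distance in [0, 1]
    J_mod: float        # per-map cosine coupling amplitude
    J_inh: float        # uniform inhibition strength
    I0: float = 1.0     # uniform external current
    eps: float = 0.0    # tuned-input fraction of the baseline
    tau: float = 10.0   # rate time constant
    sigma_noise: float = 0.0  # input-current white-noise amplitude

    def __post_init__(self):
        if not (0.0 <= self.d <= 1.0):
            raise ValueError(f"d={self.d} outside [0, 1]")
        if self.tau <= 0.0:
            raise ValueError("tau must be positive")
        if self.I0 <= 0.0:
            raise ValueError("I0 must be positive")
        if self.eps < 0.0:
            raise ValueError("eps must be >= 0")
        if self.sigma_noise < 0.0:
            raise ValueError("sigma_noise must be >= 0")

    def with_(self, **kw) -> "ModelParams":
        return replace(self, **kw)


@dataclass
class OrderParameters:
    """The five macroscopic variables of the reduced dynamics."""

    amp: float
    size: float
    mu: float
    psi0: float
    x_phi: float

    def __post_init__(self):
        if self.amp < 0.0:
            raise ValueError("amp must be >= 0")
        if not (-1.0 - 1e-12 <= self.mu <= 1.0 + 1e-12):
            raise ValueError(f"mu={self.mu} outside [-1, 1]")
        self.mu = float(np.clip(self.mu, -1.0, 1.0))
        self.psi0 = float(wrap_angle(self.psi0))

    def as_array(self) -> np.ndarray:
        return np.array([self.amp, self.size, self.mu, self.psi0, self.x_phi])


@dataclass(frozen=True)
class Grid:
    """Regular product quadrature grid on (theta, phi).

    theta: uniform periodic nodes on [0, 2 pi) (trapezoid = midpoint there);
    phi:   trapezoid nodes including both endpoints of [-pi/2, pi/2].
    Averages are normalized population means.
    """

    n_theta: int = 256
    n_phi: int = 129

    def __post_init__(self):
        if self.n_theta < 16 or self.n_phi < 16:
            raise ValueError("grid resolutions must be >= 16 per axis")

    @property
    def theta(self) -> np.ndarray:
        return _grid_nodes(self.n_theta, self.n_phi)[0]

    @property
    def phi(self) -> np.ndarray:
        return _grid_nodes(self.n_theta, self.n_phi)[1]

    @property
    def w_phi(self) -> np.ndarray:
        return _grid_nodes(self.n_theta, self.n_phi)[2]

    @property
    def TH(self) -> np.ndarray:
        return self.theta[:, None]

    @property
    def PH(self) -> np.ndarray:
        return self.phi[None, :]

    def average(self, values: np.ndarray) -> float:
        """Population average of a field sampled on the grid."""
        return float((values * self.w_phi[None, :]).sum(axis=1).mean(axis=0))

    def trig(self, d: float):
        return _trig_tables(self.n_theta, self.n_phi, float(d))


@lru_cache(maxsize=32)
def _grid_nodes(n_theta: int, n_phi: int):
    theta = np.linspace(0.0, TWO_PI, n_theta, endpoint=False)
    phi = np.linspace(-PHI_HALF_WIDTH, PHI_HALF_WIDTH, n_phi)
    w = np.ones(n_phi)
    w[0] = w[-1] = 0.5
    w /= w.sum()
    return theta, phi, w


@lru_cache(maxsize=128)
def _trig_tables(n_theta: int, n_phi: int, d: float):
    theta, phi, _ = _grid_nodes(n_theta, n_phi)
    th_a = theta[:, None] + d * phi[None, :]
    th_b = theta[:, None] - d * phi[None, :]
    return {
        "cosA": np.cos(th_a), "sinA": np.sin(th_a),
        "cosB": np.cos(th_b), "sinB": np.sin(th_b),
    }


@dataclass
class ActivityProfile:
    """Nonnegative activity over the (theta, phi) grid."""

    grid_theta: np.ndarray
    grid_phi: np.ndarray
    values: np.ndarray


# --------------------------------------------------------------------------
# tuned external input
# --------------------------------------------------------------------------

MapSelect = Union[str, float, Callable[[float], float]]


@dataclass
class TunedInput:
    """Spatially tuned component of the external current.

    The current is ``I0 (1 + eps cos(theta_s - xi))`` where ``theta_s`` is the
    neuron's angle on the stimulated map: ``s = 0`` stimulates map A,
    ``s = 1`` map B, intermediate ``s`` a morph map.  ``map_select`` may be
    'A', 'B', a float morph index, or a callable of time; ``location`` an
    angle or a callable of time.
    """

    map_select: MapSelect = "A"
    location: Union[float, Callable[[float], float]] = 0.0
    eps: Optional[float] = None
    #: distance scale of the *stimulus* map family; None -> the stored d.
    input_d: Optional[float] = None

    def s_of(self, t: float) -> float:
        s = self.map_select
        if callable(s):
            s = s(t)
        if isinstance(s, str):
            if s not in ("A", "B"):
                raise ValueError(f"malformed map_select {self.map_select!r}")
            s = 0.0 if s == "A" else 1.0
        return float(s)

    def xi_of(self, t: float) -> float:
        loc = self.location
        return float(loc(t)) if callable(loc) else float(loc)

    def eps_of(self, params: ModelParams) -> float:
        return params.eps if self.eps is None else float(self.eps)

    def field(self, theta, phi, t: float, params: ModelParams) -> np.ndarray:
        """The multiplicative tuned term eps*cos(theta_s - xi) at (theta, phi)."""
        eps = self.eps_of(params)
        if eps == 0.0:
            return np.zeros(np.broadcast(np.asarray(theta), np.asarray(phi)).shape)
        s = self.s_of(t)
        d_in = params.d if self.input_d is None else self.input_d
        theta_s = np.asarray(theta) + d_in * (1.0 - 2.0 * s) * np.asarray(phi)
        return eps * np.cos(theta_s - self.xi_of(t))


# --------------------------------------------------------------------------
# moments <-> order parameters
# --------------------------------------------------------------------------

def _split(m: np.ndarray):
    m = np.asarray(m, dtype=float)
    return m[0], m[1] + 1j * m[2], m[3] + 1j * m[4]


def _join(m0: float, mA: complex, mB: complex) -> np.ndarray:
    return np.array([m0, mA.real, mA.imag, mB.real, mB.imag])


def moments_from_op(op: OrderParameters, params: ModelParams) -> np.ndarray:
    """Invert the order-parameter map; needs J_mod > 0 and J_inh > 0."""
    if params.J_mod <= 0.0 or params.J_inh <= 0.0:
        raise ValueError("moments_from_op requires J_mod > 0 and J_inh > 0")
    big_r = op.amp / params.J_mod
    r_a = big_r * (1.0 + op.mu) / 2.0
    r_b = big_r * (1.0 - op.mu) / 2.0
    psi_a = op.psi0 + params.d * op.x_phi
    psi_b = op.psi0 - params.d * op.x_phi
    m0 = (op.amp * math.cos(op.size) + params.I0) / params.J_inh
    return _join(m0, r_a * np.exp(-1j * psi_a), r_b * np.exp(-1j * psi_b))


def op_from_moments(m: np.ndarray, params: ModelParams) -> OrderParameters:
    m0, m_a, m_b = _split(m)
    r_a, r_b = abs(m_a), abs(m_b)
    big_r = r_a + r_b
    amp = params.J_mod * big_r
    if big_r <= 0.0 or amp <= 0.0:
        return OrderParameters(amp=0.0, size=0.0, mu=0.0, psi0=0.0, x_phi=0.0)
    mu = (r_a - r_b) / big_r
    psi_a = -np.angle(m_a) if r_a > 0 else -np.angle(m_b)
    psi_b = -np.angle(m_b) if r_b > 0 else psi_a
    half = signed_arc(psi_a, psi_b) / 2.0
    psi0 = wrap_angle(psi_a + half)
    x_phi = 0.0 if params.d == 0.0 else float(-half / params.d)
    cos_size = (params.J_inh * m0 - params.I0) / amp
    size = math.acos(min(1.0, max(-1.0, cos_size)))
    return OrderParameters(amp=float(amp), size=size, mu=float(mu),
                           psi0=float(psi0), x_phi=x_phi)


# --------------------------------------------------------------------------
# profiles
# --------------------------------------------------------------------------

def rescaled_profile(size: float, mu: float, d: float, grid: Grid,
                     x_phi: float = 0.0, psi0: float = 0.0) -> np.ndarray:
    """Unit-amplitude steady profile [cos u cos dv - mu sin u sin dv - cos(size)]_+."""
    if size <= 0.0:
        return np.zeros((grid.n_theta, grid.n_phi))
    u = grid.TH - psi0
    v = grid.PH - x_phi
    vals = np.cos(u) * np.cos(d * v) - mu * np.sin(u) * np.sin(d * v) - math.cos(size)
    return np.maximum(vals, 0.0)


def steady_profile(op: OrderParameters, params: ModelParams, grid: Grid) -> ActivityProfile:
    """Steady-state activity profile for the given order parameters."""
    vals = op.amp * rescaled_profile(op.size, op.mu, params.d, grid,
                                     x_phi=op.x_phi, psi0=op.psi0)
    return ActivityProfile(grid_theta=grid.theta.copy(), grid_phi=grid.phi.copy(),
                           values=vals)


def profile_at(op: OrderParameters, params: ModelParams, theta_mid, phi) -> np.ndarray:
    """Evaluate the steady profile at arbitrary neuron labels."""
    if op.size <= 0.0 or op.amp <= 0.0:
        return np.zeros(np.broadcast(np.asarray(theta_mid), np.asarray(phi)).shape)
    u = np.asarray(theta_mid) - op.psi0
    v = np.asarray(phi) - op.x_phi
    vals = (np.cos(u) * np.cos(params.d * v)
            - op.mu * np.sin(u) * np.sin(params.d * v) - math.cos(op.size))
    return op.amp * np.maximum(vals, 0.0)


def rates_from_moments(m: np.ndarray, params: ModelParams, theta_mid, phi,
                       input_spec: Optional[TunedInput] = None,
                       t: float = 0.0, noise: float = 0.0) -> np.ndarray:
    """Input-implied rates [h]_+ at arbitrary labels for given moments.

    At a fixed point this equals the network activity; during slow protocols
    it is the quasi-steady rate the activity relaxes to.
    """
    m0, m_a, m_b = _split(m)
    theta_mid = np.asarray(theta_mid, dtype=float)
    phi = np.asarray(phi, dtype=float)
    th_a = theta_mid + params.d * phi
    th_b = theta_mid - params.d * phi
    h = params.J_mod * ((m_a * np.exp(1j * th_a)).real + (m_b * np.exp(1j * th_b)).real)
    h = h - params.J_inh * m0 + params.I0 + noise
    if input_spec is not None:
        h = h + params.I0 * input_spec.field(theta_mid, phi, t, params)
    return np.maximum(h, 0.0)


# --------------------------------------------------------------------------
# dynamics
# --------------------------------------------------------------------------

def moment_rhs(t: float, m: np.ndarray, params: ModelParams, grid: Grid,
               input_spec: Optional[TunedInput] = None,
               noise: float = 0.0) -> np.ndarray:
    """Time derivative of the five-moment state vector."""
    m0, m_a, m_b = _split(m)
    tr = grid.trig(params.d)
    h = params.J_mod * (m_a.real * tr["cosA"] - m_a.imag * tr["sinA"]
                        + m_b.real * tr["cosB"] - m_b.imag * tr["sinB"])
    h = h - params.J_inh * m0 + params.I0 + noise
    if input_spec is not None and input_spec.eps_of(params) != 0.0:
        h = h + params.I0 * input_spec.field(grid.TH, grid.PH, t, params)
    rate = np.maximum(h, 0.0)
    new0 = grid.average(rate)
    new_a = grid.average(rate * tr["cosA"]) - 1j * grid.average(rate * tr["sinA"])
    new_b = grid.average(rate * tr["cosB"]) - 1j * grid.average(rate * tr["sinB"])
    return (_join(new0, new_a, new_b) - np.asarray(m, dtype=float)) / params.tau


def order_param_rhs(op: OrderParameters, params: ModelParams,
                    input_spec: Optional[TunedInput] = None,
                    grid: Optional[Grid] = None, t: float = 0.0) -> OrderParameters:
    """Time derivatives of (amp, size, mu, psi0, x_phi), via the moment chart.

    Returned as an OrderParameters-shaped container of derivatives.  With
    eps = 0 the first four components are invariant under shifts of psi0.
    """
    if grid is None:
        grid = Grid()
    if input_spec is not None and not isinstance(input_spec, TunedInput):
        raise TypeError("input_spec must be a TunedInput or None")
    m = moments_from_op(op, params)
    dm = moment_rhs(t, m, params, grid, input_spec)
    _, m_a, m_b = _split(m)
    d0, da, db = dm[0], dm[1] + 1j * dm[2], dm[3] + 1j * dm[4]
    r_a, r_b = abs(m_a), abs(m_b)
    psi_a = op.psi0 + params.d * op.x_phi
    psi_b = op.psi0 - params.d * op.x_phi
    ra_dot = (da * np.exp(1j * psi_a)).real
    rb_dot = (db * np.exp(1j * psi_b)).real
    psia_dot = -(da * np.exp(1j * psi_a)).imag / r_a if r_a > 1e-14 else 0.0
    psib_dot = -(db * np.exp(1j * psi_b)).imag / r_b if r_b > 1e-14 else 0.0
    if r_a <= 1e-14:
        psia_dot = psib_dot
    if r_b <= 1e-14:
        psib_dot = psia_dot
    big_r = r_a + r_b
    r_dot = ra_dot + rb_dot
    amp_dot = params.J_mod * r_dot
    mu_dot = (ra_dot - rb_dot - op.mu * r_dot) / big_r
    psi0_dot = 0.5 * (psia_dot + psib_dot)
    x_dot = 0.0 if params.d == 0.0 else (psia_dot - psib_dot) / (2.0 * params.d)
    sin_size = math.sin(op.size)
    if sin_size > 1e-10:
        size_dot = -(params.J_inh * d0 / op.amp
                     - math.cos(op.size) * amp_dot / op.amp) / sin_size
    else:
        size_dot = 0.0
    out = OrderParameters.__new__(OrderParameters)
    out.amp, out.size, out.mu, out.psi0, out.x_phi = (
        float(amp_dot), float(size_dot), float(mu_dot), float(psi0_dot), float(x_dot))
    return out


@dataclass
class MFTrajectory:
    """Sampled trajectory of the reduced dynamics."""

    t: np.ndarray
    moments: np.ndarray          # (n_times, 5)
    params: ModelParams
    event: Optional[str] = None  # 'amplitude_instability' or None
    inputs: Optional[TunedInput] = None

    @property
    def final_moments(self) -> np.ndarray:
        return self.moments[-1]

    @property
    def final_op(self) -> OrderParameters:
        return op_from_moments(self.moments[-1], self.params)

    def order_parameters(self) -> dict:
        keys = ("amp", "size", "mu", "psi0", "x_phi")
        cols = {k: np.empty(len(self.t)) for k in keys}
        for i, m in enumerate(self.moments):
            op = op_from_moments(m, self.params)
            for k in keys:
                cols[k][i] = getattr(op, k)
        return cols

    def to_frame(self):
        import pandas as pd
        cols = self.order_parameters()
        cols["t"] = self.t
        return pd.DataFrame(cols)[["t", "amp", "size", "mu", "psi0", "x_phi"]]


def integrate_mf(op0: Union[OrderParameters, np.ndarray], params: ModelParams,
                 input_spec: Optional[TunedInput] = None, t_end: float = 100.0,
                 grid: Optional[Grid] = None, seed=None,
                 t_eval: Optional[np.ndarray] = None, t0: float = 0.0,
                 rtol: float = 1e-6, atol: float = 1e-8,
                 amp_ceiling_factor: float = 1e6,
                 dt: Optional[float] = None) -> MFTrajectory:
    """Integrate the reduced dynamics from ``op0`` (or a raw moment vector).

    Deterministic runs use adaptive RK45; if ``params.sigma_noise > 0`` a
    fixed-step Euler scheme (dt = tau/100) is used with a white-noise term in
    the uniform input current, sampled once per step as
    ``sigma * sqrt(2 tau / dt) * xi`` (the reduced ODEs themselves carry no
    additive noise).  Divergence of the amplitude beyond
    ``amp_ceiling_factor * I0`` is reported via ``event`` on the returned
    trajectory, never silently swallowed.
    """
    if t_end <= t0:
        raise ValueError("t_end must exceed t0")
    if grid is None:
        grid = Grid()
    m_init = (moments_from_op(op0, params) if isinstance(op0, OrderParameters)
              else np.asarray(op0, dtype=float).copy())
    ceiling = amp_ceiling_factor * params.I0
    if params.sigma_noise > 0.0:
        return _integrate_em(m_init, params, input_spec, t0, t_end, grid,
                             seed, t_eval, ceiling, dt=dt)

    def rhs(t, m):
        return moment_rhs(t, m, params, grid, input_spec)

    def blowup(t, m):
        _, m_a, m_b = _split(m)
        return params.J_mod * (abs(m_a) + abs(m_b)) - ceiling

    blowup.terminal = True
    blowup.direction = 1.0
    sol = solve_ivp(rhs, (t0, t_end), m_init, method="RK45", rtol=rtol,
                    atol=atol, t_eval=t_eval, events=blowup, dense_output=False)
    if sol.status == -1:
        raise IntegrationFailureError(
            f"mean-field integration failed: {sol.message}",
            t_last=sol.t[-1] if len(sol.t) else t0,
            moments_last=sol.y[:, -1] if sol.y.size else m_init)
    event = "amplitude_instability" if sol.status == 1 else None
    return MFTrajectory(t=sol.t, moments=sol.y.T.copy(), params=params,
                        event=event, inputs=input_spec)


def _integrate_em(m_init, params, input_spec, t0, t_end, grid, seed, t_eval,
                  ceiling, dt=None):
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if dt is None:
        dt = params.tau / 100.0
    n_steps = int(math.ceil((t_end - t0) / dt))
    if t_eval is None:
        t_eval = np.linspace(t0, t_end, min(n_steps + 1, 501))
    t_eval = np.asarray(t_eval, dtype=float)
    out = np.empty((len(t_eval), 5))
    m = m_init.copy()
    t = t0
    k_out = 0
    sig = params.sigma_noise * math.sqrt(2.0 * params.tau / dt)
    event = None
    while k_out < len(t_eval) and t_eval[k_out] <= t + 1e-12:
        out[k_out] = m
        k_out += 1
    for _ in range(n_steps):
        noise = sig * rng.standard_normal()
        m = m + dt * moment_rhs(t, m, params, grid, input_spec, noise=noise)
        t = t + dt
        _, m_a, m_b = _split(m)
        if params.J_mod * (abs(m_a) + abs(m_b)) > ceiling:
            event = "amplitude_instability"
            out = out[:k_out]
            t_eval = t_eval[:k_out]
            break
        while k_out < len(t_eval) and t_eval[k_out] <= t + 1e-12:
            out[k_out] = m
            k_out += 1
    return MFTrajectory(t=t_eval[: len(out)], moments=out, params=params,
                        event=event, inputs=input_spec)


# --------------------------------------------------------------------------
# coupling kernels (two maps / morph sequence)
# --------------------------------------------------------------------------

def _sinc(x):
    return np.sinc(np.asarray(x) / np.pi)  # sin(x)/x with sinc(0)=1


def morph_coupling_kernel(params: ModelParams, mode: str = "two_maps",
                          n_maps: Optional[int] = None) -> Callable:
    """Pairwise synaptic kernel (before the 1/N normalization).

    Returns ``kernel(theta_mid_i, phi_i, theta_mid_j, phi_j)``; all arguments
    broadcast.  Modes:

    - ``two_maps``:  J_mod [cos(dth_A) + cos(dth_B)] - J_inh
                     = 2 J_mod cos(dth_mid) cos(d dphi) - J_inh
    - ``full_morph``: continuum of morph maps between the labels' map-A and
      map-B angles, total map weight kept at 2 J_mod:
                     2 J_mod cos(dth_mid) sin(d dphi)/(d dphi) - J_inh
    - ``discrete_morph`` (requires ``n_maps``): equally spaced morph maps,
                     (2 J_mod / K) sum_k cos(dth(s_k)) - J_inh
    """
    j, j0, d = params.J_mod, params.J_inh, params.d

    if mode == "two_maps":
        def kernel(mid_i, phi_i, mid_j, phi_j):
            dth = np.asarray(mid_i) - np.asarray(mid_j)
            dph = np.asarray(phi_i) - np.asarray(phi_j)
            return 2.0 * j * np.cos(dth) * np.cos(d * dph) - j0
        return kernel
    if mode == "full_morph":
        def kernel(mid_i, phi_i, mid_j, phi_j):
            dth = np.asarray(mid_i) - np.asarray(mid_j)
            dph = np.asarray(phi_i) - np.asarray(phi_j)
            return 2.0 * j * np.cos(dth) * _sinc(d * dph) - j0
        return kernel
    if mode == "discrete_morph":
        if n_maps is None or n_maps < 2:
            raise ValueError("discrete_morph requires n_maps >= 2")
        s_grid = np.linspace(0.0, 1.0, n_maps)

        def kernel(mid_i, phi_i, mid_j, phi_j):
            dth = np.asarray(mid_i) - np.asarray(mid_j)
            dph = np.asarray(phi_i) - np.asarray(phi_j)
            acc = 0.0
            for s in s_grid:
                acc = acc + np.cos(dth + d * (1.0 - 2.0 * s) * dph)
            return 2.0 * j * acc / n_maps - j0
        return kernel
    raise ValueError(f"unknown kernel mode {mode!r}")


# --------------------------------------------------------------------------
# field simulator (mean-field limit on the grid, arbitrary phi-kernel)
# --------------------------------------------------------------------------

class FieldSimulator:
    """Neural-field integration of the full (theta, phi) activity.

    Exact mean-field limit for an arbitrary phi-kernel; used for the stored
    morph continuum (``mode='full_morph'``) where the five-moment reduction
    does not apply, and as an independent oracle for the two-map reduction.
    The theta dependence of the coupling is a single harmonic, so the
    recurrent input is evaluated through the per-phi first circular harmonic
    of the activity.
    """

    def __init__(self, params: ModelParams, mode: str = "two_maps",
                 grid: Optional[Grid] = None):
        self.params = params
        self.grid = grid if grid is not None else Grid(n_theta=128, n_phi=65)
        self.mode = mode
        dphi = self.grid.phi[:, None] - self.grid.phi[None, :]
        if mode == "two_maps":
            k = np.cos(params.d * dphi)
        elif mode == "full_morph":
            k = _sinc(params.d * dphi)
        else:
            raise ValueError(f"unknown field mode {mode!r}")
        # weighted kernel matrix: b(phi) = sum_j K[phi, phi_j] a(phi_j)
        self._K = 2.0 * params.J_mod * k * self.grid.w_phi[None, :]
        self._exp_th = np.exp(1j * self.grid.theta)[:, None]

    def recurrent(self, m_field: np.ndarray) -> np.ndarray:
        a = (m_field * np.conj(self._exp_th)).mean(axis=0)  # (n_phi,) complex
        b = self._K @ a
        m0 = self.grid.average(m_field)
        return (self._exp_th * b[None, :]).real - self.params.J_inh * m0

    def drive(self, m_field: np.ndarray, t: float,
              input_spec: Optional[TunedInput] = None,
              noise: float = 0.0) -> np.ndarray:
        h = self.recurrent(m_field) + self.params.I0 + noise
        if input_spec is not None and input_spec.eps_of(self.params) != 0.0:
            h = h + self.params.I0 * input_spec.field(
                self.grid.TH, self.grid.PH, t, self.params)
        return np.maximum(h, 0.0)

    def run(self, m0_field: np.ndarray, t_end: float,
            input_spec: Optional[TunedInput] = None, t0: float = 0.0,
            dt: Optional[float] = None, seed=None,
            record_times: Optional[np.ndarray] = None):
        """Fixed-step integration (RK4 deterministic, Euler with common input
        noise when sigma_noise > 0).  Returns (times, list of fields)."""
        p = self.params
        noisy = p.sigma_noise > 0.0
        if dt is None:
            dt = p.tau / 100.0 if noisy else p.tau / 20.0
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        n_steps = int(math.ceil((t_end - t0) / dt))
        if record_times is None:
            record_times = np.array([t_end])
        record_times = np.asarray(record_times, dtype=float)
        m = np.array(m0_field, dtype=float)
        t = t0
        out, k_out = [], 0
        sig = p.sigma_noise * math.sqrt(2.0 * p.tau / dt)
        while k_out < len(record_times) and record_times[k_out] <= t + 1e-12:
            out.append(m.copy()); k_out += 1
        for _ in range(n_steps):
            if noisy:
                noise = sig * rng.standard_normal()
                m = m + (dt / p.tau) * (-m + self.drive(m, t, input_spec, noise))
            else:
                def f(mm, tt):
                    return (-mm + self.drive(mm, tt, input_spec)) / p.tau
                k1 = f(m, t)
                k2 = f(m + 0.5 * dt * k1, t + 0.5 * dt)
                k3 = f(m + 0.5 * dt * k2, t + 0.5 * dt)
                k4 = f(m + dt * k3, t + dt)
                m = m + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            t += dt
            while k_out < len(record_times) and record_times[k_out] <= t + 1e-12:
                out.append(m.copy()); k_out += 1
        return record_times[: len(out)], out

    def moments(self, m_field: np.ndarray) -> np.ndarray:
        """Five-moment estimate of a field state (w.r.t. the stored d)."""
        tr = self.grid.trig(self.params.d)
        g = self.grid
        return _join(
            g.average(m_field),
            g.average(m_field * tr["cosA"]) - 1j * g.average(m_field * tr["sinA"]),
            g.average(m_field * tr["cosB"]) - 1j * g.average(m_field * tr["sinB"]))
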