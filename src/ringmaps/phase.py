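"""Fixed points and regime classification over the (distance, coupling) plane.

At a fixed point with the gauge psi0 = 0, x_phi = 0 the bump shape
``g = [cos u cos(d v) - mu sin u sin(d v) - cos(size)]_+`` must satisfy

    1  = 2 J_mod < g * cos u cos(d v) >          (shape: size)
    mu = -2 J_mod < g * sin u sin(d v) >         (shape: map preference)
    amp = I0 / (J_inh <g> - cos(size))           (amplitude)

The shape pair (size, mu) depends only on (J_mod, d); the inhibition enters
the amplitude alone, so the phase diagram lives in the (d, J_mod) plane with
an amplitude-instability sheet ``J_inh < cos(size)/<g>`` on top.

Boundaries:

- homogeneous/Turing:  J_mod = 2 / (1 + sinc(d)),  sinc(d) = sin(pi d)/(pi d)
  (the uniform state destabilizes into a bump; equals the size -> pi limit of
  the shape equation).
- amplitude:           J_inh = cos(size)/<g>; in the size -> pi homogeneous
  limit this evaluates to exactly -1.
- double-ring onset:   zero of  2 J_mod < H(cos u cos dv - cos size*) *
  (sin u sin dv)^2 > - 1  (first order expansion of the mu equation around
  the mu = 0 branch).
- cylinder onset:      size* = d pi / 2 (the bump exactly fits the admissible
  phi interval at x_phi = 0; smaller bumps are free to slide along phi).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .meanfield import Grid, ModelParams, OrderParameters, rescaled_profile

__all__ = [
    "Regime",
    "RegimeLabel",
    "PhaseBoundary",
    "FixedPointError",
    "solve_fixed_point",
    "boundary_curve",
    "homogeneous_boundary",
    "amplitude_boundary",
    "double_ring_onset",
    "DoubleRingOnset",
    "cylinder_boundary",
    "classify_regime",
    "scan_phase_diagram",
    "sinc",
]


class Regime(str, Enum):
    homogeneous = "homogeneous"
    single_ring = "single_ring"
    double_ring = "double_ring"
    cylinder = "cylinder"
    amplitude_unstable = "amplitude_unstable"


@dataclass
class RegimeLabel:
    label: Regime
    fixed_point: Optional[OrderParameters] = None
    margins: dict = field(default_factory=dict)


@dataclass
class PhaseBoundary:
    kind: str  # homogeneous_turing | amplitude_critical | double_ring_onset | cylinder_onset
    curve: np.ndarray  # (n, 2) sampled (parameter, critical value) pairs


@dataclass
class DoubleRingOnset:
    """J_mod window in which the mu != 0 branch exists (empty if None)."""
    exists: bool
    j_lower: Optional[float] = None
    j_upper: Optional[float] = None


class FixedPointError(RuntimeError):
    def __init__(self, message, residual=None):
        super().__init__(message)
        self.residual = residual


def sinc(d: float) -> float:
    """sin(pi d)/(pi d) with the d = 0 limit 1."""
    return 1.0 if d == 0.0 else math.sin(math.pi * d) / (math.pi * d)


def homogeneous_boundary(d: float) -> float:
    """Critical J_mod separating the homogeneous state from localized bumps."""
    if not (0.0 <= d <= 1.0):
        raise ValueError(f"d={d} outside [0, 1]")
    return 2.0 / (1.0 + sinc(d))


# ---------------------------------------------------------------------------
# shape equations
# ---------------------------------------------------------------------------

def _shape_integrals(size: float, mu: float, d: float, grid: Grid):
    """(<g q0>, <g q1>, <g>) for g the unit-amplitude profile."""
    g = rescaled_profile(size, mu, d, grid)
    q0 = np.cos(grid.TH) * np.cos(d * grid.PH)
    q1 = np.sin(grid.TH) * np.sin(d * grid.PH)
    return grid.average(g * q0), grid.average(g * q1), grid.average(g)


def _size_residual(size: float, mu: float, params: ModelParams, grid: Grid) -> float:
    gq0, _, _ = _shape_integrals(size, mu, params.d, grid)
    return 2.0 * params.J_mod * gq0 - 1.0


def _solve_size(mu: float, params: ModelParams, grid: Grid) -> Optional[float]:
    """Solve the size equation at fixed mu; None below the Turing threshold."""
    hi = math.pi
    if _size_residual(hi, mu, params, grid) < 0.0:
        return None
    return brentq(lambda s: _size_residual(s, mu, params, grid), 1e-4, hi,
                  xtol=1e-12)


def _mu_gain(params: ModelParams, grid: Grid, size: float) -> float:
    """First-order coefficient of the mu equation around the mu=0 branch."""
    q0 = np.cos(grid.TH) * np.cos(params.d * grid.PH)
    q1 = np.sin(grid.TH) * np.sin(params.d * grid.PH)
    active = (q0 - math.cos(size)) > 0.0
    return 2.0 * params.J_mod * grid.average(active * q1 ** 2)


def solve_fixed_point(params: ModelParams, init: Optional[OrderParameters] = None,
                      grid: Optional[Grid] = None, force_mu0: bool = False,
                      tol: float = 1e-9) -> OrderParameters:
    """Localized fixed point of the reduced dynamics (gauge psi0 = x_phi = 0).

    The branch is chosen from the sign of ``init.mu`` (mirrored inits reach
    the mirrored branch); with ``force_mu0`` the mu = 0 branch is returned
    even where it is unstable.  Raises FixedPointError below the Turing
    threshold or when the amplitude has no positive solution.
    """
    if grid is None:
        grid = Grid()
    size0 = _solve_size(0.0, params, grid)
    if size0 is None:
        raise FixedPointError(
            "no localized fixed point: J_mod below the Turing threshold",
            residual=_size_residual(math.pi, 0.0, params, grid))
    mu_sign = 0.0 if init is None else float(np.sign(init.mu))
    mu_star, size_star = 0.0, size0
    if not force_mu0 and params.d > 0.0:
        branch = _solve_mu_branch(params, grid)
        if branch is not None:
            mu_pos, size_pos = branch
            if mu_sign != 0.0 or _mu_gain(params, grid, size0) > 1.0:
                sgn = mu_sign if mu_sign != 0.0 else 1.0
                mu_star, size_star = sgn * mu_pos, size_pos
    gq0, gq1, g0 = _shape_integrals(size_star, mu_star, params.d, grid)
    resid = math.hypot(2.0 * params.J_mod * gq0 - 1.0,
                       mu_star + 2.0 * params.J_mod * gq1)
    if resid > 1e-6:
        raise FixedPointError("fixed-point residual above tolerance",
                              residual=resid)
    denom = params.J_inh * g0 - math.cos(size_star)
    if denom <= 0.0:
        raise FixedPointError(
            "no positive amplitude: inhibition below the critical value "
            f"(J_inh_crit = {math.cos(size_star) / g0:.6g})", residual=denom)
    amp = params.I0 / denom
    return OrderParameters(amp=amp, size=size_star, mu=mu_star, psi0=0.0,
                           x_phi=0.0)


def _mu_branch_residual(mu: float, params: ModelParams, grid: Grid):
    size = _solve_size(mu, params, grid)
    if size is None:
        return None, None
    _, gq1, _ = _shape_integrals(size, mu, params.d, grid)
    # fixed point: mu = -2 J <g q1>; divide out the mu = 0 root
    return (-2.0 * params.J_mod * gq1) / mu - 1.0, size


def _solve_mu_branch(params: ModelParams, grid: Grid):
    """Positive-mu branch of the shape equations, or None if it does not exist."""
    eps = 1e-4
    f_lo, _ = _mu_branch_residual(eps, params, grid)
    if f_lo is None or f_lo <= 0.0:
        return None
    f_hi, size_hi = _mu_branch_residual(1.0, params, grid)
    if f_hi is None:
        return None
    if f_hi >= 0.0:
        # branch pinned at full localization (reached at d = 1)
        return 1.0, size_hi
    mu = brentq(lambda m: _mu_branch_residual(m, params, grid)[0], eps, 1.0,
                xtol=1e-10)
    size = _solve_size(mu, params, grid)
    return mu, size


# ---------------------------------------------------------------------------
# boundaries
# ---------------------------------------------------------------------------

def boundary_curve(kind: str, d_values, grid: Optional[Grid] = None,
                   **kw) -> PhaseBoundary:
    """Sample a named boundary over a distance scan as a PhaseBoundary.

    Kinds: ``homogeneous_turing``, ``double_ring_onset`` (lower edge; NaN
    where no onset exists), ``cylinder_onset`` (NaN at d = 0 / out of range),
    ``amplitude_critical`` (critical inhibition along the mu = 0 branch; a
    ``J_mod`` keyword is required).
    """
    if grid is None:
        grid = Grid()
    d_values = np.asarray(d_values, dtype=float)
    vals = np.full(len(d_values), np.nan)
    for i, d in enumerate(d_values):
        if kind == "homogeneous_turing":
            vals[i] = homogeneous_boundary(d)
        elif kind == "double_ring_onset":
            onset = double_ring_onset(d, grid=grid, **kw)
            if onset.exists:
                vals[i] = onset.j_lower
        elif kind == "cylinder_onset":
            jc = cylinder_boundary(d, grid=grid, **kw)
            if jc is not None:
                vals[i] = jc
        elif kind == "amplitude_critical":
            params = ModelParams(d=d, J_mod=kw["J_mod"], J_inh=1.0)
            size = _solve_size(0.0, params, grid)
            if size is not None:
                _, _, g0 = _shape_integrals(size, 0.0, d, grid)
                vals[i] = math.cos(size) / g0
        else:
            raise ValueError(f"unknown boundary kind {kind!r}")
    return PhaseBoundary(kind=kind, curve=np.column_stack([d_values, vals]))


def amplitude_boundary(shape: OrderParameters, params: ModelParams,
                       grid: Optional[Grid] = None) -> float:
    """Critical inhibition for a localized fixed-point shape (size, mu).

    Below the returned J_inh the activity amplitude diverges.  In the
    homogeneous limit size -> pi the value is exactly -1.
    """
    if grid is None:
        grid = Grid()
    _, _, g0 = _shape_integrals(shape.size, shape.mu, params.d, grid)
    return math.cos(shape.size) / g0


def double_ring_onset(d: float, params_template: Optional[ModelParams] = None,
                      grid: Optional[Grid] = None,
                      j_max: float = 40.0) -> DoubleRingOnset:
    """J_mod window where the mu != 0 (double ring) branch exists at distance d.

    Found as the zeros of the first-order mu-expansion of the shape equation;
    for small d (high correlation) there is no onset.
    """
    if grid is None:
        grid = Grid()
    if d <= 0.0:
        return DoubleRingOnset(exists=False)

    def f(j):
        p = ModelParams(d=d, J_mod=j, J_inh=1.0)
        size = _solve_size(0.0, p, grid)
        if size is None:
            return -1.0
        return _mu_gain(p, grid, size) - 1.0

    j_lo = homogeneous_boundary(d) * (1.0 + 1e-6)
    js = np.linspace(j_lo, j_max, 200)
    vals = np.array([f(j) for j in js])
    pos = np.where(vals > 0.0)[0]
    if len(pos) == 0:
        return DoubleRingOnset(exists=False)
    i0, i1 = pos[0], pos[-1]
    lower = js[i0] if i0 == 0 else brentq(f, js[i0 - 1], js[i0], xtol=1e-9)
    upper = (None if i1 == len(js) - 1
             else brentq(f, js[i1], js[i1 + 1], xtol=1e-9))
    return DoubleRingOnset(exists=True, j_lower=float(lower),
                           j_upper=None if upper is None else float(upper))


def cylinder_boundary(d: float, grid: Optional[Grid] = None,
                      j_max: float = 1e4) -> Optional[float]:
    """Critical J_mod above which the bump fits inside the phi interval.

    Solves size*(J_mod, d) = d pi / 2 on the mu = 0 branch; None when no
    such coupling exists below ``j_max`` (in particular for d = 0).
    """
    if grid is None:
        grid = Grid()
    if d <= 0.0:
        return None
    target = d * math.pi / 2.0

    def f(j):
        size = _solve_size(0.0, ModelParams(d=d, J_mod=j, J_inh=1.0), grid)
        return (math.pi if size is None else size) - target

    j_lo = homogeneous_boundary(d) * (1.0 + 1e-6)
    if f(j_lo) <= 0.0:
        return j_lo
    hi = 2.0 * j_lo
    while f(hi) > 0.0:
        hi *= 2.0
        if hi > j_max:
            return None
    return float(brentq(f, j_lo, hi, xtol=1e-9))


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_regime(params: ModelParams, grid: Optional[Grid] = None,
                    mu_tol: float = 1e-3,
                    assume_amplitude_stable: bool = False) -> RegimeLabel:
    """Label a parameter point with its regime and diagnostic margins.

    With ``assume_amplitude_stable`` the inhibition gate is skipped and the
    shape regime (which depends on (d, J_mod) alone) is returned; the
    amplitude is then reported for an inhibition at twice the critical value.
    """
    if grid is None:
        grid = Grid()
    j_hom = homogeneous_boundary(params.d)
    margins = {"turing": params.J_mod - j_hom}
    if params.J_mod <= j_hom:
        if params.J_inh <= -1.0 and not assume_amplitude_stable:
            margins["amplitude"] = params.J_inh + 1.0
            return RegimeLabel(Regime.amplitude_unstable, margins=margins)
        margins["amplitude"] = params.J_inh + 1.0
        return RegimeLabel(Regime.homogeneous, margins=margins)
    fp_init = OrderParameters(amp=1.0, size=2.0, mu=0.5, psi0=0.0, x_phi=0.0)
    solve_params = params
    if assume_amplitude_stable:
        size0 = _solve_size(0.0, params, grid)
        if size0 is not None:
            _, _, g0 = _shape_integrals(size0, 0.0, params.d, grid)
            j_safe = 2.0 * abs(math.cos(size0) / g0) + 1.0
            solve_params = params.with_(J_inh=max(params.J_inh, j_safe))
    try:
        fp = solve_fixed_point(solve_params, init=fp_init, grid=grid)
    except FixedPointError as err:
        if "inhibition" in str(err):
            margins["amplitude"] = err.residual
            return RegimeLabel(Regime.amplitude_unstable, margins=margins)
        raise
    j_inh_crit = amplitude_boundary(fp, solve_params, grid)
    margins["amplitude"] = solve_params.J_inh - j_inh_crit
    if solve_params.J_inh <= j_inh_crit:
        return RegimeLabel(Regime.amplitude_unstable, fixed_point=fp,
                           margins=margins)
    margins["mu"] = abs(fp.mu)
    if abs(fp.mu) > mu_tol:
        return RegimeLabel(Regime.double_ring, fixed_point=fp, margins=margins)
    margins["cylinder"] = params.d * math.pi / 2.0 - fp.size
    if fp.size < params.d * math.pi / 2.0:
        return RegimeLabel(Regime.cylinder, fixed_point=fp, margins=margins)
    return RegimeLabel(Regime.single_ring, fixed_point=fp, margins=margins)


def scan_phase_diagram(d_values, j_values, J_inh: Optional[float] = 10.0,
                       I0: float = 1.0, grid: Optional[Grid] = None,
                       mu_tol: float = 1e-3):
    """Grid scan of regimes; returns a long-format pandas DataFrame.

    With ``J_inh=None`` the scan labels the inhibition-independent shape
    plane (inhibition held safely above critical at every point).
    """
    import pandas as pd

    if grid is None:
        grid = Grid(n_theta=128, n_phi=65)
    assume = J_inh is None
    rows = []
    for d in np.asarray(d_values, dtype=float):
        for j in np.asarray(j_values, dtype=float):
            params = ModelParams(d=d, J_mod=j, J_inh=J_inh if not assume else 1.0,
                                 I0=I0)
            res = classify_regime(params, grid=grid, mu_tol=mu_tol,
                                  assume_amplitude_stable=assume)
            fp = res.fixed_point
            rows.append({
                "d": d, "J_mod": j, "label": res.label.value,
                "amp": fp.amp if fp else np.nan,
                "size": fp.size if fp else np.nan,
                "mu": fp.mu if fp else np.nan,
                **{f"margin_{k}": v for k, v in res.margins.items()},
            })
    return pd.DataFrame(rows)
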