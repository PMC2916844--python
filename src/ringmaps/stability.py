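"""Linear stability of homogeneous and localized solutions.

The reduced dynamics is linearized in the moment chart
``m = [m0, Re m_A, Im m_A, Re m_B, Im m_B]``.  The Jacobian of the
threshold-linear drive has entries

    d<[h]_+ c_k>/dm_l = < H(h) c_k b_l >

with ``H`` the Heaviside function, ``c = (1, cos th_A, -sin th_A, cos th_B,
-sin th_B)`` the moment projectors and ``b = dh/dm = (-J_inh, J_mod cos th_A,
-J_mod sin th_A, J_mod cos th_B, -J_mod sin th_B)``; all entries are
quadratures over the active region of the bump.

For the uniform solution exactly two independent conditions govern
stability: the amplitude mode (eigenvalue ``-(1 + J_inh)/tau``) and the
spatial-modulation (Turing) pair (leading eigenvalue
``(-1 + J_mod (1 + sinc d)/2)/tau``), whose zero crossing reproduces the
homogeneous boundary.

Zero modes generated by the continuous symmetries (bump rotation; bump
translation along phi in the cylinder regime) are projected out of the
stability verdict: marginality is structural, not an instability.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np

from .meanfield import (Grid, ModelParams, OrderParameters, moment_rhs,
                        moments_from_op)
from .phase import sinc

__all__ = [
    "StabilityReport",
    "homogeneous_stability",
    "localized_stability",
    "moment_jacobian",
    "numerical_jacobian",
    "symmetry_tangents",
]

MARGINAL_TOL = 1e-6


@dataclass
class StabilityReport:
    eigenvalues: np.ndarray
    stable: bool
    failing_mode: str  # none | amplitude | turing | mu_symmetry_breaking
    marginal_indices: list = dc_field(default_factory=list)
    conditions: dict = dc_field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({
            "eigenvalues": [[z.real, z.imag] for z in np.atleast_1d(self.eigenvalues)],
            "stable": bool(self.stable),
            "failing_mode": self.failing_mode,
            "marginal_indices": list(map(int, self.marginal_indices)),
            "conditions": {k: float(v) for k, v in self.conditions.items()},
        }, indent=2)


def homogeneous_stability(params: ModelParams) -> StabilityReport:
    """Stability of the uniform solution m = I0 / (1 + J_inh).

    Two independent eigenvalue conditions: the amplitude mode and the
    spatially modulated (Turing) modes; the latter's sign change reproduces
    the homogeneous boundary in closed form.
    """
    lam_amp = -(1.0 + params.J_inh) / params.tau
    s = sinc(params.d)
    lam_tur_plus = (-1.0 + params.J_mod * (1.0 + s) / 2.0) / params.tau
    lam_tur_minus = (-1.0 + params.J_mod * (1.0 - s) / 2.0) / params.tau
    eigs = np.array([lam_amp, lam_tur_plus, lam_tur_plus,
                     lam_tur_minus, lam_tur_minus])
    stable = bool(np.all(eigs < 0.0))
    if stable:
        mode = "none"
    elif lam_amp >= max(lam_tur_plus, 0.0):
        mode = "amplitude"
    else:
        mode = "turing"
    return StabilityReport(
        eigenvalues=eigs, stable=stable, failing_mode=mode,
        conditions={"amplitude": lam_amp, "turing": lam_tur_plus})


def moment_jacobian(m: np.ndarray, params: ModelParams,
                    grid: Optional[Grid] = None) -> np.ndarray:
    """Analytic (quadrature) Jacobian of the moment dynamics at state m."""
    if grid is None:
        grid = Grid()
    tr = grid.trig(params.d)
    m = np.asarray(m, dtype=float)
    h = params.J_mod * (m[1] * tr["cosA"] - m[2] * tr["sinA"]
                        + m[3] * tr["cosB"] - m[4] * tr["sinB"])
    h = h - params.J_inh * m[0] + params.I0
    active = (h > 0.0).astype(float)
    one = np.ones_like(tr["cosA"])
    c = [one, tr["cosA"], -tr["sinA"], tr["cosB"], -tr["sinB"]]
    b = [-params.J_inh * one, params.J_mod * tr["cosA"],
         -params.J_mod * tr["sinA"], params.J_mod * tr["cosB"],
         -params.J_mod * tr["sinB"]]
    jac = np.empty((5, 5))
    for k in range(5):
        for l in range(5):
            jac[k, l] = grid.average(active * c[k] * b[l])
    return (jac - np.eye(5)) / params.tau


def numerical_jacobian(m: np.ndarray, params: ModelParams,
                       grid: Optional[Grid] = None, step: float = 1e-6) -> np.ndarray:
    """Central-difference Jacobian of the moment dynamics (cross-check path)."""
    if grid is None:
        grid = Grid()
    m = np.asarray(m, dtype=float)
    jac = np.empty((5, 5))
    for l in range(5):
        dm = np.zeros(5)
        dm[l] = step
        f_plus = moment_rhs(0.0, m + dm, params, grid)
        f_minus = moment_rhs(0.0, m - dm, params, grid)
        jac[:, l] = (f_plus - f_minus) / (2.0 * step)
    return jac


def symmetry_tangents(m: np.ndarray, params: ModelParams) -> np.ndarray:
    """Tangent vectors of the continuous symmetries at state m.

    Row 0: global bump rotation (always a symmetry at eps = 0);
    row 1: translation along phi (marginal only in the cylinder regime).
    """
    m = np.asarray(m, dtype=float)
    re_a, im_a, re_b, im_b = m[1], m[2], m[3], m[4]
    t_rot = np.array([0.0, im_a, -re_a, im_b, -re_b])
    t_x = params.d * np.array([0.0, im_a, -re_a, -im_b, re_b])
    return np.vstack([t_rot, t_x])


def _mode_directions(m: np.ndarray) -> dict:
    """Unit vectors for naming unstable directions at a gauge-fixed point."""
    def unit(v):
        n = np.linalg.norm(v)
        return v / n if n > 0 else v
    return {
        "amplitude": unit(np.array([1.0, 1.0, 0.0, 1.0, 0.0])),
        "mu_symmetry_breaking": unit(np.array([0.0, 1.0, 0.0, -1.0, 0.0])),
    }


def localized_stability(fixed_point: OrderParameters, params: ModelParams,
                        grid: Optional[Grid] = None,
                        residual_tol: float = 1e-6,
                        marginal_tol: float = MARGINAL_TOL) -> StabilityReport:
    """Stability of a localized fixed point (single/double ring, cylinder).

    The mu perturbation decouples from the (amplitude, size) block at mu = 0
    fixed points; its sign change reproduces the double-ring onset, and the
    amplitude block's instability reproduces the critical inhibition.
    """
    if grid is None:
        grid = Grid()
    m = moments_from_op(fixed_point, params)
    resid = np.linalg.norm(moment_rhs(0.0, m, params, grid)) * params.tau
    if resid > residual_tol * max(1.0, float(np.linalg.norm(m))):
        raise ValueError(f"state is not a fixed point (residual {resid:.3g})")
    jac = moment_jacobian(m, params, grid)
    eigvals, eigvecs = np.linalg.eig(jac)
    tangents = [symmetry_tangents(m, params)[0]]  # rotation, always marginal
    if fixed_point.size < params.d * math.pi / 2.0 - 1e-9:
        # bump interior to the phi range: translation along phi is marginal too
        tangents.append(symmetry_tangents(m, params)[1])
    basis = np.array([t / np.linalg.norm(t) for t in tangents
                      if np.linalg.norm(t) > 1e-12])
    marginal = []
    if len(basis):
        q, _ = np.linalg.qr(basis.T)
        # the symmetry zero modes appear as a near-zero cluster whose
        # eigenvectors lie in the tangent span; quadrature error displaces
        # them from 0 by O(grid spacing), hence the loose magnitude cut
        for i, lam in enumerate(eigvals):
            if abs(lam) * params.tau > 0.05:
                continue
            v = eigvecs[:, i]
            residual = np.linalg.norm(v - q @ (q.conj().T @ v))
            if residual < 0.5:
                marginal.append(i)
    marginal = marginal[: len(basis)]
    rest = [i for i in range(5) if i not in marginal]
    unstable = [i for i in rest if eigvals[i].real > marginal_tol / params.tau]
    stable = len(unstable) == 0
    mode = "none"
    if not stable:
        i_worst = max(unstable, key=lambda i: eigvals[i].real)
        v = eigvecs[:, i_worst].real
        v = v / np.linalg.norm(v)
        dirs = _mode_directions(m)
        mode = max(dirs, key=lambda k: abs(np.dot(v, dirs[k])))
    conditions = {
        "leading_nonmarginal": float(max((eigvals[i].real for i in rest),
                                         default=-np.inf)),
        "residual": float(resid),
    }
    return StabilityReport(eigenvalues=eigvals, stable=stable,
                           failing_mode=mode, marginal_indices=marginal,
                           conditions=conditions)
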