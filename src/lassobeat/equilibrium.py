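"""Static equilibria of the axoneme-rod composite.

At equilibrium the bending vector U = (U1, U2) satisfies the
integro-differential torque balance

    Ba U' - H_perp - Dp (e_p x e_p) int_0^s U = 0,      Ca U3' = 0,

with boundary conditions ``Ba U(L) + Hhat_perp = 0`` and ``U3(L) = 0``, where
``H_perp = (-H2, H1)`` and ``e_p = (cos phi_p, sin phi_p)``.  The twist
equation forces U3 = 0 under any actuation — equilibria are twistless, so all
centerline torsion comes from rotations of the bending vector.

Substituting G(s) = int_0^s U converts the balance into a linear two-point
boundary value problem

    Ba G'' - Dp (e_p x e_p) G = H_perp,  G(0) = 0,  Ba G'(L) = -Hhat_perp,

solved here by adaptive collocation; an independent semi-analytic route
exploits the rank-1 structure of e_p x e_p (the component of G along e_p
obeys a scalar ODE with exponential homogeneous solutions; the orthogonal
component is a double quadrature) and serves as an oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid, solve_bvp
from scipy.interpolate import CubicSpline

try:  # scipy >= 1.12
    from scipy.integrate import cumulative_simpson
except ImportError:  # pragma: no cover
    cumulative_simpson = None

from .elastic import (
    AxonemeParams,
    ForcePattern,
    PFRParams,
    target_bending_from_forces,
    total_energy,
)
from .geometry import (
    BendingTwistField,
    curvature_torsion_from_bending,
    _dds,
)

__all__ = [
    "EquilibriumSolution",
    "solve_equilibrium",
    "semi_analytic_equilibrium",
    "planarity_classification",
    "bending_trace_metrics",
]


@dataclass
class EquilibriumSolution:
    """Equilibrium strain field with solver diagnostics."""

    U: BendingTwistField
    residual_norm: float
    energy: float
    trace_area: float

    @property
    def grid(self):
        return self.U.grid


def _h_perp(f: ForcePattern) -> np.ndarray:
    """(n, 2) array of the rotated force vector (-H2, H1)."""
    return np.column_stack([-f.H2, f.H1])


def _h_perp_tip(f: ForcePattern) -> np.ndarray:
    return np.array([-f.H2_tip, f.H1_tip])


def _signed_area(U1: np.ndarray, U2: np.ndarray, h: float) -> float:
    """Signed area swept by the open (U1, U2) trace about the origin."""
    dU1, dU2 = _dds(U1, h), _dds(U2, h)
    return 0.5 * float(np.trapezoid(U1 * dU2 - U2 * dU1, dx=h))


def _residual(f, p, q, U1, U2, h) -> float:
    """Max-norm residual of the nondimensionalized balance equation."""
    G1 = cumulative_trapezoid(U1, dx=h, initial=0.0)
    G2 = cumulative_trapezoid(U2, dx=h, initial=0.0)
    ep = q.e_p
    proj = ep[0] * G1 + ep[1] * G2
    Hp = _h_perp(f)
    dU1, dU2 = p.Ba * _dds(U1, h), p.Ba * _dds(U2, h)
    r1 = dU1 - Hp[:, 0] - q.Dp * ep[0] * proj
    r2 = dU2 - Hp[:, 1] - q.Dp * ep[1] * proj
    scale = p.Ba / f.grid.L**2  # natural torque-gradient scale
    mag = max(
        np.abs(Hp).max(initial=0.0),
        np.abs(np.r_[dU1, dU2]).max(initial=0.0),
        q.Dp * np.abs(proj).max(initial=0.0),
        scale,
    )
    return float(np.abs(np.r_[r1[1:-1], r2[1:-1]]).max() / mag)


def _finish(f, p, q, U1, U2, residual=None) -> EquilibriumSolution:
    grid = f.grid
    U = BendingTwistField(grid, U1, U2, np.zeros(grid.n_nodes))
    assert float(np.abs(U.U3).max()) == 0.0  # twistless by construction
    energy = total_energy(U, f, p, q)["total"]
    area = _signed_area(U1, U2, grid.h)
    if residual is None:
        residual = _residual(f, p, q, U1, U2, grid.h)
    return EquilibriumSolution(U, residual_norm=residual, energy=energy, trace_area=area)


def solve_equilibrium(
    f: ForcePattern, p: AxonemeParams, q: PFRParams, tol: float = 1e-9
) -> EquilibriumSolution:
    """Solve the equilibrium balance for the bending vector.

    The Dp = 0 case is exact: the equilibrium is the target bending obtained
    by direct quadrature of the force pattern.  For Dp > 0 the G-substituted
    boundary value problem is solved by adaptive collocation and U = G' is
    read off the collocation solution (no numerical differentiation).
    """
    grid = f.grid
    if q.Dp == 0.0:
        # exact by quadrature: Ba dU*/ds = H_perp and Ba U*(L) = -Hhat_perp
        t = target_bending_from_forces(f, p.Ba)
        bc_res = np.abs(
            p.Ba * np.array([t.U1_star[-1], t.U2_star[-1]]) + _h_perp_tip(f)
        ).max() / (p.Ba / grid.L)
        return _finish(f, p, q, t.U1_star, t.U2_star, residual=float(bc_res))

    s = grid.s
    Hp = _h_perp(f)
    spl1 = CubicSpline(s, Hp[:, 0])
    spl2 = CubicSpline(s, Hp[:, 1])
    ep = q.e_p
    P = np.outer(ep, ep)
    tip = _h_perp_tip(f)

    def rhs(x, y):
        # y = [G1, G2, G1', G2']
        G = y[:2]
        forcing = np.vstack([spl1(x), spl2(x)])
        return np.vstack([y[2:], (forcing + q.Dp * (P @ G)) / p.Ba])

    def bc(ya, yb):
        return np.r_[ya[:2], p.Ba * yb[2:] + tip]

    y0 = np.zeros((4, grid.n_nodes))
    sol = solve_bvp(rhs, bc, s, y0, tol=tol, max_nodes=200000)
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"equilibrium collocation failed: {sol.message}")
    y = sol.sol(s)
    res = float(sol.rms_residuals.max()) if sol.rms_residuals.size else 0.0
    return _finish(f, p, q, y[2], y[3], residual=res)


def semi_analytic_equilibrium(
    f: ForcePattern, p: AxonemeParams, q: PFRParams
) -> EquilibriumSolution:
    """Rank-1 decomposition oracle for the equilibrium problem.

    Writing G = g_par e_p + g_perp e_p^perp, the perpendicular component
    solves Ba g'' = f_perp by double quadrature, while the parallel component
    solves Ba g'' - Dp g = f_par with closed-form sinh/cosh homogeneous
    solutions and a variation-of-parameters particular solution evaluated by
    cumulative Simpson quadrature.  Only U = G' is needed, so the first
    derivative of each representation is assembled directly.
    """
    grid = f.grid
    s, h = grid.s, grid.h
    ep = q.e_p
    eq = np.array([-ep[1], ep[0]])
    Hp = _h_perp(f)
    f_par = Hp @ ep
    f_perp = Hp @ eq
    tip = _h_perp_tip(f)

    def cumint(y):
        if cumulative_simpson is not None:
            return np.r_[0.0, cumulative_simpson(y, dx=h)]
        return cumulative_trapezoid(y, dx=h, initial=0.0)

    # perpendicular: Ba g'' = f_perp, g(0)=0, Ba g'(L) = -tip.eq
    I1 = cumint(f_perp)
    gp_perp = (I1 - I1[-1] - tip @ eq) / p.Ba  # g'(s)

    if q.Dp == 0.0:
        I1p = cumint(f_par)
        gp_par = (I1p - I1p[-1] - tip @ ep) / p.Ba
    else:
        lam = np.sqrt(q.Dp / p.Ba)
        # particular solution: g_p(s) = (1/(Ba lam)) [sinh(lam s) A(s) - cosh(lam s) B(s)]
        A = cumint(np.cosh(lam * s) * f_par)
        B = cumint(np.sinh(lam * s) * f_par)
        gp_part = (np.cosh(lam * s) * A - np.sinh(lam * s) * B) / p.Ba
        # homogeneous g_h = alpha sinh(lam s)/lam satisfies g(0)=0; fix alpha by
        # Ba g'(L) = -tip.ep
        alpha = (-(tip @ ep) / p.Ba - gp_part[-1]) / np.cosh(lam * grid.L)
        gp_par = alpha * np.cosh(lam * s) + gp_part

    U_vec = np.outer(gp_par, ep) + np.outer(gp_perp, eq)
    return _finish(f, p, q, U_vec[:, 0], U_vec[:, 1])


def planarity_classification(
    phi_p: float, f: ForcePattern, angle_tol: float = 1e-9
) -> bool | None:
    """Predict whether the equilibrium shape is planar.

    Under planar actuation (H2 = H2_tip = 0, H1 not identically zero) the
    equilibrium is planar iff the attachment angle is a multiple of pi/2 —
    i.e. the joining line is parallel or orthogonal to the spontaneous
    bending plane.  Returns None for zero actuation (undefined).
    """
    if not f.is_planar():
        raise ValueError("classification requires planar actuation")
    if np.abs(f.H1).max(initial=0.0) == 0.0 and f.H1_tip == 0.0:
        return None
    rem = np.mod(phi_p, np.pi / 2)
    return bool(min(rem, np.pi / 2 - rem) <= angle_tol)


def bending_trace_metrics(
    sol: EquilibriumSolution, kappa_floor: float | None = None
) -> dict[str, float]:
    """Geometry of the (U1, U2) trace: angle range, swept area, torsion range."""
    ct = curvature_torsion_from_bending(sol.U, kappa_floor=kappa_floor)
    out = {
        "signed_area": sol.trace_area,
        "psi_range": np.nan,
        "tau_min": np.nan,
        "tau_max": np.nan,
    }
    if ct.valid_mask.any():
        psi = ct.psi[ct.valid_mask]
        tau = ct.tau[ct.valid_mask]
        out.update(
            psi_range=float(psi.max() - psi.min()),
            tau_min=float(tau.min()),
            tau_max=float(tau.max()),
        )
    return out
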