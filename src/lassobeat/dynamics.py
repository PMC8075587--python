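"""Viscous beat dynamics of the axoneme-rod composite.

Linearized force balance under resistive-force-theory drag gives, for the
bending vector U = (U1, U2) and the twist U3,

    mu_perp dU/dt = -Ba d4U/ds4 + d3(H_perp)/ds3 + Dp (e_p x e_p) d2U/ds2,
    mu_r    dU3/dt = Ca d2U3/ds2,

with, at the distal end s = L,

    Ba U + Hhat_perp = 0,
    (Ba dU/ds - H_perp - Dp (e_p x e_p) int_0^s U) = 0,   U3 = 0,

and at the base s = 0 the force/moment-type conditions

    Ba d2U/ds2 - dH_perp/ds - Dp (e_p x e_p) U = 0,
    Ba d3U/ds3 - d2H_perp/ds2 - Dp (e_p x e_p) dU/ds = 0,

plus a torque-free base for the twist (dU3/ds = 0 at s = 0; the printed
distal pair U3 = dU3/ds = 0 over-determines the second-order twist equation,
and the choice is immaterial because U3 = 0 is the attractor either way).
The twist equation is unforced — dynein sliding forces cannot twist the
axoneme — so the beat becomes twistless after a transient, the dynamic
counterpart of the static result.

Discretization: centered finite differences on a uniform grid (fourth order
in the deep interior, second order on the rows bordering the boundary
blocks, high-order one-sided stencils in the boundary rows — the wavelike
solutions carry large high derivatives, so stencil order is what limits the
global error); the distal integro bracket uses the same cumulative trapezoid
as the statics; theta-scheme time stepping with theta = 1/2
(Crank-Nicolson), operators factorized once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.linalg import lu_factor, lu_solve
from scipy.signal import find_peaks

from .elastic import AxonemeParams, ForcePattern, PFRParams
from .geometry import (
    ArcGrid,
    BendingTwistField,
    FramedCurve,
    curvature_torsion_from_bending,
    integrate_frame,
)

__all__ = [
    "DragCoefficients",
    "BeatSolution",
    "assemble_dynamic_operators",
    "solve_dynamics",
    "periodic_steady_state",
    "torsion_kymograph",
    "shapes_over_beat",
]


@dataclass(frozen=True)
class DragCoefficients:
    """Resistive-force-theory drag per unit length.

    mu_perp, mu_par: normal and tangential translational coefficients
    (force * time / length^2); mu_rot: rotational coefficient about the
    tangent (force * time).  For a slender filament mu_perp/mu_par ~ 2.
    """

    mu_perp: float = 1.0
    mu_par: float = 0.5
    mu_rot: float = 1e-3

    def __post_init__(self) -> None:
        if min(self.mu_perp, self.mu_par, self.mu_rot) <= 0:
            raise ValueError("drag coefficients must be positive")


@dataclass
class BeatSolution:
    """Time-resolved strain fields over the simulated window."""

    grid: ArcGrid
    times: np.ndarray
    U1: np.ndarray  # (nt, n)
    U2: np.ndarray
    U3: np.ndarray
    period: float
    steps_per_period: int
    converged_periodic: bool = False
    period_mismatch: float = np.inf

    def field_at(self, k: int) -> BendingTwistField:
        return BendingTwistField(self.grid, self.U1[k], self.U2[k], self.U3[k])


# ---------------------------------------------------------------------------
# operator assembly
# ---------------------------------------------------------------------------

def _onesided_weights(m: int, npts: int, h: float) -> np.ndarray:
    """Finite-difference weights for the m-th derivative at the first of
    ``npts`` equispaced nodes (order npts - m).  Negate odd-derivative
    weights and reverse for the far end."""
    from math import factorial

    k = np.arange(npts)
    A = np.vander(k, npts, increasing=True).T / np.array(
        [factorial(i) for i in range(npts)]
    )[:, None]
    b = np.zeros(npts)
    b[m] = 1.0
    return np.linalg.solve(A, b) / h**m


_C4_D4 = np.array([-1 / 6, 2.0, -13 / 2, 28 / 3, -13 / 2, 2.0, -1 / 6])
_C4_D2 = np.array([-1 / 12, 4 / 3, -5 / 2, 4 / 3, -1 / 12])
_C4_D3 = np.array([1 / 8, -1.0, 13 / 8, 0.0, -13 / 8, 1.0, -1 / 8])


def _d3_interior(H: np.ndarray, h: float) -> np.ndarray:
    """Third derivative of the forcing: fourth-order central stencils in the
    deep interior, second-order central at the two rows adjacent to the
    boundary blocks, one-sided at the ends (the end values feed rows that the
    boundary conditions overwrite)."""
    n = len(H)
    out = np.zeros(n)
    out[2:-2] = (-H[:-4] + 2 * H[1:-3] - 2 * H[3:-1] + H[4:]) / (2 * h**3)
    core = np.correlate(H, _C4_D3, mode="valid") / h**3
    out[3 : n - 3] = core
    c = np.array([-2.5, 9.0, -12.0, 7.0, -1.5]) / h**3
    out[0] = c @ H[:5]
    out[1] = c @ H[1:6]
    out[-1] = -(c @ H[-5:][::-1])
    out[-2] = -(c @ H[-6:-1][::-1])
    return out


def assemble_dynamic_operators(
    p: AxonemeParams,
    q: PFRParams,
    drag: DragCoefficients,
    grid: ArcGrid,
) -> dict[str, np.ndarray]:
    """Discrete operators of the bending-vector dynamics.

    Returns the interior PDE generator ``A`` (rows zeroed where boundary
    conditions live), the boundary operator ``B`` (nonzero only on those
    rows), the singular mass matrix ``M`` (mu_perp on interior rows) and the
    trapezoid weights used in the distal integro-term.  Unknown ordering is
    [U1 nodes, U2 nodes].
    """
    n, h = grid.n_nodes, grid.h
    if n < 32:
        raise ValueError("dynamics grid too coarse: need n >= 32")
    Ba, Dp = p.Ba, q.Dp
    ep = q.e_p
    P = np.outer(ep, ep)

    # fourth-order central stencils in the deep interior, second-order at the
    # single row adjacent to each boundary block
    D4 = np.zeros((n, n))
    D2 = np.zeros((n, n))
    for i in (2, n - 3):
        D4[i, i - 2 : i + 3] = np.array([1.0, -4.0, 6.0, -4.0, 1.0]) / h**4
        D2[i, i - 1 : i + 2] = np.array([1.0, -2.0, 1.0]) / h**2
    for i in range(3, n - 3):
        D4[i, i - 3 : i + 4] = _C4_D4 / h**4
        D2[i, i - 2 : i + 3] = _C4_D2 / h**2

    A = np.zeros((2 * n, 2 * n))
    for c in range(2):
        for cp in range(2):
            blk = A[c * n : (c + 1) * n, cp * n : (cp + 1) * n]
            if c == cp:
                blk -= Ba * D4
            blk += Dp * P[c, cp] * D2

    w = np.full(n, h)  # trapezoid weights for int_0^L
    w[0] = w[-1] = h / 2

    # one-sided stencils for the boundary rows: sixth order, because the
    # truncation constants of low-order stencils multiply high (wavelike)
    # derivatives of the solution and would dominate the global error
    w1 = _onesided_weights(1, 7, h)
    w2 = _onesided_weights(2, 8, h)
    w3 = _onesided_weights(3, 9, h)

    B = np.zeros((2 * n, 2 * n))
    bc_rows = []
    for c in range(2):
        base = c * n
        # distal: Ba U(L) = -Hhat_perp
        r = base + n - 1
        B[r, r] = Ba
        bc_rows.append(r)
        # distal bracket: Ba U'(L) - Dp P int_0^L U = H_perp(L)
        r = base + n - 2
        B[r, base + n - len(w1) : base + n] += -Ba * w1[::-1]
        for cp in range(2):
            B[r, cp * n : (cp + 1) * n] -= Dp * P[c, cp] * w
        bc_rows.append(r)
        # base: Ba U''(0) - Dp P U(0) = H_perp'(0)
        r = base + 0
        B[r, base : base + len(w2)] += Ba * w2
        for cp in range(2):
            B[r, cp * n] -= Dp * P[c, cp]
        bc_rows.append(r)
        # base: Ba U'''(0) - Dp P U'(0) = H_perp''(0)
        r = base + 1
        B[r, base : base + len(w3)] += Ba * w3
        for cp in range(2):
            B[r, cp * n : cp * n + len(w1)] -= Dp * P[c, cp] * w1
        bc_rows.append(r)

    bc_rows = np.array(sorted(bc_rows))
    A[bc_rows, :] = 0.0
    M = np.zeros(2 * n)
    M[:] = drag.mu_perp
    M[bc_rows] = 0.0
    return {"A": A, "B": B, "M": np.diag(M), "bc_rows": bc_rows, "weights": w}


def _bc_rhs(f: ForcePattern, grid: ArcGrid) -> np.ndarray:
    """Right-hand sides of the eight boundary-condition rows."""
    n, h = grid.n_nodes, grid.h
    Hp = np.column_stack([-f.H2, f.H1])
    tip = np.array([-f.H2_tip, f.H1_tip])
    w1 = _onesided_weights(1, 7, h)
    w2 = _onesided_weights(2, 8, h)
    rhs = np.zeros(2 * n)
    for c in range(2):
        base = c * n
        rhs[base + n - 1] = -tip[c]
        rhs[base + n - 2] = Hp[-1, c]
        rhs[base + 0] = w1 @ Hp[: len(w1), c]
        rhs[base + 1] = w2 @ Hp[: len(w2), c]
    return rhs


def _interior_forcing(f: ForcePattern, grid: ArcGrid, bc_rows: np.ndarray) -> np.ndarray:
    n, h = grid.n_nodes, grid.h
    Hp = np.column_stack([-f.H2, f.H1])
    F = np.concatenate([_d3_interior(Hp[:, 0], h), _d3_interior(Hp[:, 1], h)])
    F[bc_rows] = 0.0
    return F


# ---------------------------------------------------------------------------
# time stepping
# ---------------------------------------------------------------------------

def solve_dynamics(
    forces: Callable[[float], ForcePattern],
    p: AxonemeParams,
    q: PFRParams,
    drag: DragCoefficients,
    grid: ArcGrid,
    period: float,
    n_periods: int = 8,
    steps_per_period: int = 400,
    theta: float = 0.5,
    U0: BendingTwistField | None = None,
    twist_diffusivity: float | None = None,
) -> BeatSolution:
    """Integrate the beat equations over ``n_periods`` of the actuation.

    ``forces(t)`` must return the force pattern on ``grid`` at time ``t``.
    The implicit theta-scheme (default Crank-Nicolson) is unconditionally
    stable; the operators are assembled and factorized once.  The twist
    equation is integrated alongside with zero forcing and decays to zero.
    """
    ops = assemble_dynamic_operators(p, q, drag, grid)
    n = grid.n_nodes
    dt = period / steps_per_period
    nt = n_periods * steps_per_period

    A, B, bc_rows = ops["A"], ops["B"], ops["bc_rows"]
    Mdt = ops["M"] / dt
    L_mat = Mdt - theta * A + B
    R_mat = Mdt + (1 - theta) * A
    lu = lu_factor(L_mat)
    # startup steps use backward Euler: the theta = 1/2 right-hand side
    # applies the stiff generator to the initial data, which amplifies any
    # boundary-inconsistent or rough component catastrophically
    n_startup = 2
    lu_be = lu_factor(Mdt - A + B)

    # twist: mu_r dU3/dt = Ca U3'' with U3(L) = 0, U3'(0) = 0
    if twist_diffusivity is None:
        twist_diffusivity = p.Ca / drag.mu_rot
    h = grid.h
    T2 = np.zeros((n, n))
    for i in range(1, n - 1):
        T2[i, i - 1 : i + 2] = twist_diffusivity * np.array([1, -2, 1]) / h**2
    # twist is a pure relaxation to zero: integrate it with backward Euler,
    # which is strongly stable (no oscillatory tail for stiff modes)
    Bt = np.zeros((n, n))
    Bt[0, :3] = np.array([-3.0, 4.0, -1.0]) / (2 * h)
    Bt[-1, -1] = 1.0
    T2[[0, -1], :] = 0.0
    mt = np.ones(n) / dt
    mt[[0, -1]] = 0.0
    lu_t = lu_factor(np.diag(mt) - T2 + Bt)

    X = np.zeros(2 * n)
    U3 = np.zeros(n)
    if U0 is not None:
        X = np.concatenate([U0.U1, U0.U2])
        U3 = U0.U3.copy()

    f_now = forces(0.0)
    F_now = _interior_forcing(f_now, grid, bc_rows)
    times = np.empty(nt + 1)
    out1 = np.empty((nt + 1, n))
    out2 = np.empty((nt + 1, n))
    out3 = np.empty((nt + 1, n))
    times[0], out1[0], out2[0], out3[0] = 0.0, X[:n], X[n:], U3

    for k in range(nt):
        t_next = (k + 1) * dt
        f_next = forces(t_next)
        F_next = _interior_forcing(f_next, grid, bc_rows)
        if k < n_startup:
            rhs = Mdt @ X + F_next + _bc_rhs(f_next, grid)
            X = lu_solve(lu_be, rhs)
        else:
            rhs = R_mat @ X + theta * F_next + (1 - theta) * F_now
            rhs += _bc_rhs(f_next, grid)
            X = lu_solve(lu, rhs)
        U3 = lu_solve(lu_t, np.diag(mt) @ U3)
        if not np.all(np.isfinite(X)):
            raise RuntimeError(f"dynamics blew up at step {k + 1}, t = {t_next:g}")
        f_now, F_now = f_next, F_next
        times[k + 1], out1[k + 1], out2[k + 1], out3[k + 1] = t_next, X[:n], X[n:], U3

    return BeatSolution(
        grid, times, out1, out2, out3, period=period, steps_per_period=steps_per_period
    )


def periodic_steady_state(
    b: BeatSolution, threshold: float = 1e-3
) -> BeatSolution:
    """Extract the last period and check beat-to-beat convergence.

    period_mismatch is the relative L2(s, t) distance between the last two
    simulated periods; the returned (last-period) solution is flagged
    converged when it falls below the threshold.
    """
    spp = b.steps_per_period
    if len(b.times) < 3 * spp + 1:
        raise ValueError("need at least 3 integrated periods")
    last = slice(-spp - 1, None)
    prev = slice(-2 * spp - 1, -spp - 1)  # same phases, one period earlier
    diff = 0.0
    norm = 0.0
    for comp in (b.U1, b.U2):
        diff += float(np.sum((comp[last][:-1] - comp[prev]) ** 2))
        norm += float(np.sum(comp[last][:-1] ** 2))
    mismatch = np.sqrt(diff / norm) if norm > 0 else 0.0
    return BeatSolution(
        b.grid,
        b.times[last] - b.times[last][0],
        b.U1[last].copy(),
        b.U2[last].copy(),
        b.U3[last].copy(),
        period=b.period,
        steps_per_period=spp,
        converged_periodic=bool(mismatch < threshold),
        period_mismatch=float(mismatch),
    )


# ---------------------------------------------------------------------------
# beat post-processing
# ---------------------------------------------------------------------------

def torsion_kymograph(
    b: BeatSolution,
    kappa_floor: float | None = None,
    peak_fraction: float = 0.3,
) -> dict:
    """Torsion field tau(s, t) over the beat with tracked torsional peaks.

    Peaks are local extrema of |tau| above ``peak_fraction`` of the global
    maximum; the dominant positive and negative peaks are tracked across
    phases (positions unwrapped along s) and their mean propagation speed is
    reported, positive meaning base-to-tip travel.

    The default curvature floor is 10% of the beat's peak curvature: torsion
    diverges like 1/kappa at the near-inflection nodes where the bending
    plane flips, and a floor tied to the beat's own curvature scale keeps
    the kymograph comparable across parameter settings.
    """
    n = b.grid.n_nodes
    nt = len(b.times)
    if kappa_floor is None:
        kappa_floor = 0.1 * float(np.hypot(b.U1, b.U2).max())
        if kappa_floor == 0.0:
            kappa_floor = None  # fall back to the geometric default
    tau = np.zeros((nt, n))
    for k in range(nt):
        ct = curvature_torsion_from_bending(b.field_at(k), kappa_floor=kappa_floor)
        tau[k] = np.where(ct.valid_mask, ct.tau, 0.0)
    tau_max = np.abs(tau).max()
    tracks = []
    if tau_max > 0:
        thresh = peak_fraction * tau_max
        for sign in (+1, -1):
            positions = np.full(nt, np.nan)
            for k in range(nt):
                prof = sign * tau[k]
                peaks, props = find_peaks(prof, height=thresh)
                if len(peaks):
                    positions[k] = b.grid.s[peaks[np.argmax(props["peak_heights"])]]
            ok = np.isfinite(positions)
            if ok.sum() >= max(4, nt // 4):
                speed = _track_speed(b.times[ok], positions[ok], b.grid.L)
                tracks.append(
                    {"sign": sign, "positions": positions, "speed": speed}
                )
    return {"tau": tau, "s": b.grid.s, "t": b.times, "tracks": tracks}


def _track_speed(t: np.ndarray, pos: np.ndarray, L: float) -> float:
    """Mean propagation speed of a peak track, unwrapping tip-to-base resets."""
    p = pos.copy()
    offset = 0.0
    for i in range(1, len(p)):
        if p[i] + offset - p[i - 1] < -L / 2:
            offset += L
        elif p[i] + offset - p[i - 1] > L / 2:
            offset -= L
        p[i] += offset
    slope = np.polyfit(t, p, 1)[0]
    return float(slope)


def shapes_over_beat(
    b: BeatSolution,
    n_shapes: int = 10,
    base_point: np.ndarray | None = None,
    base_frame=None,
) -> list[FramedCurve]:
    """Flagellar shapes at evenly spaced phases of the beat.

    The base is clamped (fixed pose), matching the trapped-cell viewpoint in
    which the model is formulated.
    """
    idx = np.linspace(0, len(b.times) - 1, n_shapes, endpoint=False).astype(int)
    return [
        integrate_frame(b.field_at(k), base_point=base_point, base_frame=base_frame)
        for k in idx
    ]
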