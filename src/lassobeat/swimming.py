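"""Rigid-body swimming propelled by the computed beat.

The cell body is a prolate ellipsoid with the flagellum attached at its
anterior pole; hydrodynamics is resistive force theory for the flagellum
(local anisotropic drag) plus the classical ellipsoid resistance tensor for
the body.  At every beat phase the rigid translational and angular
velocities (V, Omega) solve the force-free, torque-free balance: the 6x6
grand resistance of body + flagellum, which is symmetric positive definite,
against the drag generated by the flagellum's shape change.  Because the
problem is linear and the beat periodic, the net motion per beat is a fixed
screw transformation; composing it yields a helical swimming path along
which the body completes exactly one rotation per helix turn.

The beat is computed once in the body frame and is not re-coupled to the
body motion (kinematic decoupling, consistent with the trapped-cell stance
of the beat model).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .dynamics import DragCoefficients
from .geometry import FramedCurve

__all__ = [
    "CellBody",
    "SwimPath",
    "ellipsoid_resistance",
    "rft_densities",
    "solve_rigid_velocities",
    "integrate_path",
    "helix_metrics",
]


def _skew(v: np.ndarray) -> np.ndarray:
    return np.array([
        [0.0, -v[2], v[1]],
        [v[2], 0.0, -v[0]],
        [-v[1], v[0], 0.0],
    ])


def ellipsoid_resistance(semi_axes: tuple[float, float, float], eta: float) -> np.ndarray:
    """6x6 resistance matrix of a prolate spheroid (a >= b = c) about its center.

    Uses the classical closed-form drag factors in terms of the eccentricity
    e = sqrt(1 - b^2/a^2); the sphere limit is handled by series.  Ordering is
    (force; torque) against (velocity; angular velocity), body axes with x
    along the major axis.
    """
    a, b, c = semi_axes
    if not (a > 0 and b > 0 and c > 0):
        raise ValueError("semi-axes must be positive")
    if abs(b - c) > 1e-12 * b:
        raise ValueError("only spheroids (b == c) are supported")
    if a < b:
        raise ValueError("expect prolate spheroid with a >= b")
    e = np.sqrt(max(1.0 - (b / a) ** 2, 0.0))
    if e < 1e-4:
        # sphere limit: all drag factors tend to 1
        trans = 6 * np.pi * eta * a * np.ones(3)
        rot = 8 * np.pi * eta * a**3 * np.ones(3)
    else:
        Le = np.log((1 + e) / (1 - e))
        XA = (8.0 / 3.0) * e**3 / (-2 * e + (1 + e**2) * Le)
        YA = (16.0 / 3.0) * e**3 / (2 * e + (3 * e**2 - 1) * Le)
        XC = (4.0 / 3.0) * e**3 * (1 - e**2) / (2 * e - (1 - e**2) * Le)
        YC = (4.0 / 3.0) * e**3 * (2 - e**2) / (-2 * e + (1 + e**2) * Le)
        trans = 6 * np.pi * eta * a * np.array([XA, YA, YA])
        rot = 8 * np.pi * eta * a**3 * np.array([XC, YC, YC])
    R = np.zeros((6, 6))
    R[:3, :3] = np.diag(trans)
    R[3:, 3:] = np.diag(rot)
    return R


@dataclass(frozen=True)
class CellBody:
    """Ellipsoidal cell body with the flagellum base on the anterior pole.

    Lengths are in the same (nondimensional) units as the beat; viscosity
    ``eta`` must be consistent with the flagellar drag coefficients.  The
    base frame of the flagellum is tilted by ``tilt`` about the body y axis.
    """

    semi_axes: tuple[float, float, float] = (1.0, 0.2, 0.2)
    eta: float = 0.46
    tilt: float = np.pi / 6
    attachment_point: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 0.0, 0.0])
    )

    @property
    def resistance(self) -> np.ndarray:
        return ellipsoid_resistance(self.semi_axes, self.eta)

    def base_pose(self) -> tuple[np.ndarray, np.ndarray]:
        """(point, frame matrix) of the flagellum base in body coordinates.

        The flagellum's tangent (its d3) leaves along the body +x axis tilted
        by ``tilt`` towards +z.
        """
        Rt = Rotation.from_euler("y", -self.tilt).as_matrix()
        d3 = Rt @ np.array([1.0, 0.0, 0.0])
        d1 = Rt @ np.array([0.0, 0.0, 1.0])
        d2 = np.cross(d3, d1)
        frame = np.column_stack([d1, d2, d3])
        return self.attachment_point, frame


@dataclass
class SwimPath:
    """Time series of rigid-body poses of the swimming cell."""

    times: np.ndarray
    positions: np.ndarray  # (nt, 3)
    quaternions: np.ndarray  # (nt, 4) scalar-last, unit norm
    per_beat_displacement: np.ndarray | None = None
    per_beat_rotation: np.ndarray | None = None  # rotation vector


# ---------------------------------------------------------------------------
# resistive force theory
# ---------------------------------------------------------------------------

def rft_densities(
    velocities: np.ndarray,
    spin_rates: np.ndarray,
    d3: np.ndarray,
    drag: DragCoefficients,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-node viscous force and torque densities.

    F = -mu_perp (Id - d3 x d3) v - mu_par (d3 x d3) v, and
    G = -mu_rot w3 d3 with w3 the spin rate about the tangent.
    """
    v_par = np.einsum("ij,ij->i", velocities, d3)[:, None] * d3
    v_perp = velocities - v_par
    F = -drag.mu_perp * v_perp - drag.mu_par * v_par
    G = -drag.mu_rot * spin_rates[:, None] * d3
    return F, G


def _flagellum_resistance(
    pts: np.ndarray, d3: np.ndarray, drag: DragCoefficients, h: float
) -> np.ndarray:
    """6x6 RFT resistance of a frozen flagellar shape about the body origin."""
    n = len(pts)
    w = np.full(n, h)
    w[0] = w[-1] = h / 2
    R = np.zeros((6, 6))
    for i in range(n):
        t = d3[i]
        M = drag.mu_perp * (np.eye(3) - np.outer(t, t)) + drag.mu_par * np.outer(t, t)
        S = _skew(pts[i])
        R[:3, :3] += w[i] * M
        R[:3, 3:] += -w[i] * M @ S
        R[3:, :3] += w[i] * S @ M
        R[3:, 3:] += -w[i] * S @ M @ S
        # rotational drag about the tangent
        R[3:, 3:] += w[i] * drag.mu_rot * np.outer(t, t)
    return R


def solve_rigid_velocities(
    shapes: list[FramedCurve],
    body: CellBody,
    drag: DragCoefficients,
    period: float,
) -> np.ndarray:
    """Rigid (V, Omega) per phase from the zero-net-force/torque balance.

    ``shapes`` are the flagellar configurations in body coordinates at
    evenly spaced phases over one period.  Shape-change velocities are
    centered differences in time (periodic); the 6x6 grand resistance of
    body plus flagellum is SPD, so each solve is unique.
    """
    n_ph = len(shapes)
    dt = period / n_ph
    h = shapes[0].grid.h
    Rb = body.resistance
    out = np.zeros((n_ph, 6))
    pts = np.array([sh.r for sh in shapes])
    d1s = np.array([sh.d1 for sh in shapes])
    d2s = np.array([sh.d2 for sh in shapes])
    d3s = np.array([sh.d3 for sh in shapes])
    for k in range(n_ph):
        kp, km = (k + 1) % n_ph, (k - 1) % n_ph
        v_shape = (pts[kp] - pts[km]) / (2 * dt)
        spin = np.einsum(
            "ij,ij->i", (d1s[kp] - d1s[km]) / (2 * dt), d2s[k]
        )
        F, G = rft_densities(v_shape, spin, d3s[k], drag)
        w = np.full(len(F), h)
        w[0] = w[-1] = h / 2
        force = (w[:, None] * F).sum(axis=0)
        torque = (w[:, None] * (np.cross(pts[k], F) + G)).sum(axis=0)
        A = Rb + _flagellum_resistance(pts[k], d3s[k], drag, h)
        rhs = np.concatenate([force, torque])
        sol = np.linalg.solve(A, rhs)
        out[k] = sol
    return out


def rigid_balance_residual(
    shapes: list[FramedCurve],
    rigid: np.ndarray,
    body: CellBody,
    drag: DragCoefficients,
    period: float,
) -> float:
    """Max residual total force/torque over the phases (should vanish)."""
    n_ph = len(shapes)
    dt = period / n_ph
    h = shapes[0].grid.h
    Rb = body.resistance
    pts = np.array([sh.r for sh in shapes])
    d1s = np.array([sh.d1 for sh in shapes])
    d2s = np.array([sh.d2 for sh in shapes])
    d3s = np.array([sh.d3 for sh in shapes])
    worst = 0.0
    for k in range(n_ph):
        kp, km = (k + 1) % n_ph, (k - 1) % n_ph
        V, Om = rigid[k, :3], rigid[k, 3:]
        v_tot = (pts[kp] - pts[km]) / (2 * dt) + V + np.cross(Om, pts[k])
        spin = (
            np.einsum("ij,ij->i", (d1s[kp] - d1s[km]) / (2 * dt), d2s[k])
            + d3s[k] @ Om
        )
        F, G = rft_densities(v_tot, spin, d3s[k], drag)
        w = np.full(len(F), h)
        w[0] = w[-1] = h / 2
        force = (w[:, None] * F).sum(axis=0) - Rb[:3, :3] @ V
        torque = (
            (w[:, None] * (np.cross(pts[k], F) + G)).sum(axis=0) - Rb[3:, 3:] @ Om
        )
        worst = max(worst, float(np.abs(np.r_[force, torque]).max()))
    return worst


# ---------------------------------------------------------------------------
# path integration and helix metrics
# ---------------------------------------------------------------------------

def beat_screw(rigid: np.ndarray, period: float) -> tuple[Rotation, np.ndarray]:
    """Net rigid transformation over one beat from body-frame velocities.

    Integrates pose with exact exponential steps per phase interval and
    returns (rotation, displacement) expressed in the starting body frame.
    """
    n_ph = len(rigid)
    dt = period / n_ph
    R = Rotation.identity()
    x = np.zeros(3)
    for k in range(n_ph):
        V, Om = rigid[k, :3], rigid[k, 3:]
        x = x + R.apply(V) * dt
        R = R * Rotation.from_rotvec(Om * dt)
    return R, x


def integrate_path(
    rigid: np.ndarray, period: float, n_beats: int
) -> SwimPath:
    """Compose the per-beat screw transformation over ``n_beats`` beats."""
    Rb, xb = beat_screw(rigid, period)
    times = np.arange(n_beats + 1) * period
    positions = np.zeros((n_beats + 1, 3))
    quats = np.zeros((n_beats + 1, 4))
    R = Rotation.identity()
    x = np.zeros(3)
    quats[0] = R.as_quat()
    for k in range(n_beats):
        x = x + R.apply(xb)
        R = R * Rb
        positions[k + 1] = x
        quats[k + 1] = R.as_quat()
    return SwimPath(
        times,
        positions,
        quats,
        per_beat_displacement=xb,
        per_beat_rotation=Rb.as_rotvec(),
    )


def helix_metrics(path: SwimPath) -> dict:
    """Helix geometry of a swimming path.

    The helix axis is the invariant axis of the per-beat screw; radius and
    pitch follow from the orbit of the body center; handedness is positive
    (right-handed) when the translation along the axis and the rotation about
    it share a sign.  ``body_rotations_per_turn`` compares the accumulated
    body rotation against the angular progress of the position about the
    axis, both measured from the integrated path.
    """
    rv = path.per_beat_rotation
    d = path.per_beat_displacement
    if rv is None or d is None:
        raise ValueError("path lacks per-beat screw data")
    theta = np.linalg.norm(rv)
    if theta < 1e-12:
        return {
            "radius": 0.0,
            "pitch": np.nan,
            "handedness": 0,
            "body_rotations_per_turn": np.nan,
            "axis": None,
            "degenerate": True,
        }
    axis = rv / theta
    d_par = float(d @ axis)
    d_perp = d - d_par * axis
    # center of the circular orbit: (I - R) c_perp = d_perp in the axis plane
    R = Rotation.from_rotvec(rv).as_matrix()
    A = np.eye(3) - R
    # solve in the plane orthogonal to axis
    b1 = _any_orthogonal(axis)
    b2 = np.cross(axis, b1)
    Ap = np.array([[b1 @ A @ b1, b1 @ A @ b2], [b2 @ A @ b1, b2 @ A @ b2]])
    cp = np.linalg.solve(Ap, np.array([b1 @ d_perp, b2 @ d_perp]))
    center = cp[0] * b1 + cp[1] * b2
    radius = float(np.linalg.norm(center))
    pitch = float(2 * np.pi * d_par / theta)
    handedness = int(np.sign(d_par))
    # independent measurement from the integrated poses: the screw axis
    # passes through `center`, and positions minus `center` rotate about it
    pos_rel = path.positions - center
    ang = _angular_progress(pos_rel, axis, b1, b2)
    body_angle = theta * (len(path.positions) - 1)
    ratio = body_angle / abs(ang) if abs(ang) > 0 else np.nan
    return {
        "radius": radius,
        "pitch": pitch,
        "handedness": handedness,
        "body_rotations_per_turn": float(ratio),
        "axis": axis,
        "degenerate": radius < 1e-12,
    }


def _any_orthogonal(v: np.ndarray) -> np.ndarray:
    a = np.array([1.0, 0.0, 0.0])
    if abs(v @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    out = a - (a @ v) * v
    return out / np.linalg.norm(out)


def _angular_progress(pos_rel, axis, b1, b2) -> float:
    x = pos_rel @ b1
    y = pos_rel @ b2
    ang = np.unwrap(np.arctan2(y, x))
    return float(ang[-1] - ang[0])
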