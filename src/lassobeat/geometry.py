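"""Discrete differential geometry of framed curves.

The flagellum's shape is encoded by the bending strains ``U1, U2`` and the
twist ``U3`` of an orthonormal material frame ``(d1, d2, d3)`` attached to the
axonemal centerline ``r(s)``:

    U1 = d2' . d3,   U2 = d3' . d1,   U3 = d1' . d2,

with the centerline slaved to the frame through ``r' = d3``.  Equivalently the
frame rotates along arc length with Darboux vector
``Omega = U1 d1 + U2 d2 + U3 d3``.  This module converts between the strain
representation and explicit framed curves, computes curvature/torsion both
from strains and from raw centerline samples (the route used for measured
waveforms), and builds the geometric test objects used throughout: the nine
microtubule centerlines on the axonemal surface, and the "torsion dipole"
idealization of the spinning-lasso outline.

Conventions: arc-length grids are uniform; a right-handed helix has positive
torsion; torsion is reported only where the curvature exceeds a floor, since
the bending-vector angle is undefined at inflections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.spatial.transform import Rotation
from shapely.geometry import LineString

__all__ = [
    "ArcGrid",
    "BendingTwistField",
    "FramedCurve",
    "ShearField",
    "CurvatureTorsion",
    "integrate_frame",
    "bending_twist_from_frame",
    "shear_from_bending",
    "curvature_torsion_from_bending",
    "curvature_torsion_from_centerline",
    "mt_centerlines",
    "MT_ANGLES",
    "torsion_dipole_curve",
    "project_outline",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArcGrid:
    """Uniform arc-length grid on [0, L] with ``n_nodes`` samples."""

    n_nodes: int
    L: float = 1.0

    def __post_init__(self) -> None:
        if self.n_nodes < 8:
            raise ValueError(f"need at least 8 nodes, got {self.n_nodes}")
        if self.L <= 0:
            raise ValueError("length must be positive")

    @property
    def h(self) -> float:
        return self.L / (self.n_nodes - 1)

    @property
    def s(self) -> np.ndarray:
        return np.linspace(0.0, self.L, self.n_nodes)


def _conform(grid: ArcGrid, *arrays: np.ndarray) -> tuple[np.ndarray, ...]:
    out = []
    for a in arrays:
        a = np.asarray(a, dtype=float)
        if a.shape[0] != grid.n_nodes:
            raise ValueError(
                f"array of length {a.shape[0]} does not conform to grid "
                f"with {grid.n_nodes} nodes"
            )
        if not np.all(np.isfinite(a)):
            raise ValueError("non-finite values in field")
        out.append(a)
    return tuple(out)


@dataclass
class BendingTwistField:
    """Bending strains U1, U2 and twist U3 sampled on an arc-length grid."""

    grid: ArcGrid
    U1: np.ndarray
    U2: np.ndarray
    U3: np.ndarray

    def __post_init__(self) -> None:
        self.U1, self.U2, self.U3 = _conform(self.grid, self.U1, self.U2, self.U3)

    @classmethod
    def constant(cls, grid: ArcGrid, u1: float, u2: float, u3: float) -> "BendingTwistField":
        n = grid.n_nodes
        return cls(grid, np.full(n, u1), np.full(n, u2), np.full(n, u3))

    def as_matrix(self) -> np.ndarray:
        """(n, 3) array of per-node strain vectors in the material frame."""
        return np.column_stack([self.U1, self.U2, self.U3])


@dataclass
class FramedCurve:
    """Centerline points with a right-handed orthonormal frame per node.

    ``r`` is (n, 3); ``d1, d2, d3`` are (n, 3) with ``d3`` the tangent.
    """

    grid: ArcGrid
    r: np.ndarray
    d1: np.ndarray
    d2: np.ndarray
    d3: np.ndarray

    ORTHO_TOL = 1e-10

    def __post_init__(self) -> None:
        self.r, self.d1, self.d2, self.d3 = _conform(
            self.grid, self.r, self.d1, self.d2, self.d3
        )

    def frame_defect(self) -> float:
        """Max deviation of the per-node frame from a right-handed rotation."""
        R = np.stack([self.d1, self.d2, self.d3], axis=-1)  # (n, 3, 3)
        eye = np.eye(3)
        gram = np.einsum("nij,nik->njk", R, R)
        defect = np.abs(gram - eye).max()
        det_defect = np.abs(np.linalg.det(R) - 1.0).max()
        return max(defect, det_defect)


@dataclass
class ShearField:
    """Collective microtubule sliding gamma1, gamma2; both vanish at the base."""

    grid: ArcGrid
    gamma1: np.ndarray
    gamma2: np.ndarray

    def __post_init__(self) -> None:
        self.gamma1, self.gamma2 = _conform(self.grid, self.gamma1, self.gamma2)


@dataclass
class CurvatureTorsion:
    """Curvature, torsion and a validity mask (torsion defined only where
    curvature exceeds the floor)."""

    grid: ArcGrid
    kappa: np.ndarray
    tau: np.ndarray
    valid_mask: np.ndarray
    psi: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.kappa, self.tau = _conform(self.grid, self.kappa, self.tau)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)

    def max_abs_tau(self) -> float:
        if not self.valid_mask.any():
            return 0.0
        return float(np.abs(self.tau[self.valid_mask]).max())


# ---------------------------------------------------------------------------
# frame integration and differentiation
# ---------------------------------------------------------------------------

def _check_base_frame(d1: np.ndarray, d2: np.ndarray, d3: np.ndarray) -> np.ndarray:
    R = np.column_stack([d1, d2, d3]).astype(float)
    if np.abs(R.T @ R - np.eye(3)).max() > 1e-8 or np.linalg.det(R) < 0:
        raise ValueError("base frame is not right-handed orthonormal")
    return R


def _rotvec_displacement(u: np.ndarray, h: float) -> np.ndarray:
    """Integral over one cell of exp(sigma [u]x) e3, for constant strain u.

    Closed form of the helix chord: with K = [u]x, theta = |u| h,

        int_0^h exp(sigma K) dsigma = h I + (1-cos th)/|u|^2 K
                                      + (h - sin th/|u|)/|u|^2 K^2.
    """
    norm = np.linalg.norm(u)
    K = np.array([
        [0.0, -u[2], u[1]],
        [u[2], 0.0, -u[0]],
        [-u[1], u[0], 0.0],
    ])
    if norm * h < 1e-8:
        # series: h I + h^2/2 K + h^3/6 K^2
        M = h * np.eye(3) + 0.5 * h**2 * K + (h**3 / 6.0) * (K @ K)
    else:
        th = norm * h
        M = (
            h * np.eye(3)
            + ((1.0 - np.cos(th)) / norm**2) * K
            + ((h - np.sin(th) / norm) / norm**2) * (K @ K)
        )
    return M @ np.array([0.0, 0.0, 1.0])


def integrate_frame(
    U: BendingTwistField,
    base_point: np.ndarray | None = None,
    base_frame: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> FramedCurve:
    """Reconstruct the framed curve from bending strains and twist.

    The frame is advanced cell by cell with the exact rotation generated by
    the cell-averaged strain vector (piecewise-constant Darboux vector), which
    preserves orthonormality to round-off; the centerline uses the matching
    exact helix chord.  Second-order accurate in the grid spacing for smooth
    strain fields.
    """
    grid = U.grid
    n, h = grid.n_nodes, grid.h
    if base_point is None:
        base_point = np.zeros(3)
    if base_frame is None:
        R0 = np.eye(3)
    else:
        R0 = _check_base_frame(*base_frame)

    u_nodes = U.as_matrix()
    u_mid = 0.5 * (u_nodes[:-1] + u_nodes[1:])

    R = np.empty((n, 3, 3))
    r = np.empty((n, 3))
    R[0] = R0
    r[0] = np.asarray(base_point, dtype=float)
    # per-cell rotation increments in the material frame: R_{k+1} = R_k exp(h [u]x)
    rots = Rotation.from_rotvec(u_mid * h).as_matrix()
    for k in range(n - 1):
        r[k + 1] = r[k] + R[k] @ _rotvec_displacement(u_mid[k], h)
        R[k + 1] = R[k] @ rots[k]
    return FramedCurve(grid, r, R[:, :, 0], R[:, :, 1], R[:, :, 2])


def _dds(a: np.ndarray, h: float) -> np.ndarray:
    """Second-order derivative along axis 0: centered interior, one-sided ends."""
    d = np.empty_like(a)
    d[1:-1] = (a[2:] - a[:-2]) / (2 * h)
    d[0] = (-3 * a[0] + 4 * a[1] - a[2]) / (2 * h)
    d[-1] = (3 * a[-1] - 4 * a[-2] + a[-3]) / (2 * h)
    return d


def bending_twist_from_frame(curve: FramedCurve) -> BendingTwistField:
    """Strains from a framed curve by centered finite differences."""
    h = curve.grid.h
    d1s, d2s, d3s = _dds(curve.d1, h), _dds(curve.d2, h), _dds(curve.d3, h)
    U1 = np.einsum("ij,ij->i", d2s, curve.d3)
    U2 = np.einsum("ij,ij->i", d3s, curve.d1)
    U3 = np.einsum("ij,ij->i", d1s, curve.d2)
    return BendingTwistField(curve.grid, U1, U2, U3)


def shear_from_bending(U: BendingTwistField) -> ShearField:
    """Sliding-bending coupling: gamma1 = int_0^s U2, gamma2 = -int_0^s U1."""
    g1 = cumulative_trapezoid(U.U2, dx=U.grid.h, initial=0.0)
    g2 = -cumulative_trapezoid(U.U1, dx=U.grid.h, initial=0.0)
    return ShearField(U.grid, g1, g2)


# ---------------------------------------------------------------------------
# curvature and torsion
# ---------------------------------------------------------------------------

def _unwrap_segments(psi: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """2-pi unwrap restarted on each contiguous run of valid nodes."""
    out = psi.copy()
    i = 0
    n = len(psi)
    while i < n:
        if not valid[i]:
            i += 1
            continue
        j = i
        while j < n and valid[j]:
            j += 1
        out[i:j] = np.unwrap(psi[i:j])
        i = j
    return out


def curvature_torsion_from_bending(
    U: BendingTwistField, kappa_floor: float | None = None
) -> CurvatureTorsion:
    """Curvature and torsion of the centerline implied by the strains.

    kappa = |(U1, U2)|, and tau = psi' + U3 where psi is the unwrapped angle
    of the bending vector.  Torsion is undefined (masked) below the curvature
    floor; the default floor is 1e-3 / L.
    """
    grid = U.grid
    if kappa_floor is None:
        kappa_floor = 1e-3 / grid.L
    kappa = np.hypot(U.U1, U.U2)
    valid = kappa >= kappa_floor
    # rate of rotation of the bending vector, in quotient form: the unwrapped
    # angle itself is kept only as a diagnostic, because a planar inflection
    # (U crossing zero along a line) makes psi jump by pi within one cell
    # while the quotient stays finite and exact.
    dU1, dU2 = _dds(U.U1, grid.h), _dds(U.U2, grid.h)
    with np.errstate(invalid="ignore", divide="ignore"):
        psi_rate = np.where(valid, (U.U1 * dU2 - U.U2 * dU1) / kappa**2, 0.0)
    tau = np.where(valid, psi_rate + U.U3, 0.0)
    psi = _unwrap_segments(np.arctan2(U.U2, U.U1), valid)
    return CurvatureTorsion(grid, kappa, tau, valid, psi=psi)


def curvature_torsion_from_centerline(
    points: np.ndarray, kappa_floor: float | None = None
) -> CurvatureTorsion:
    """Discrete Frenet curvature/torsion from ordered 3D centerline samples.

    The curve is reparametrized by cumulative chord length; derivatives use
    centered differences with one-sided stencils at the endpoints.  Curvature
    and torsion use the vector forms kappa = |r' x r''| / |r'|^3 and
    tau = det[r', r'', r'''] / |r' x r''|^2, which keep the Frenet sign
    convention (right-handed helix positive) while staying finite through
    planar inflections; torsion is masked where the curvature falls below
    the floor (collinear runs).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 5:
        raise ValueError("need at least 5 three-dimensional points")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(seg == 0.0):
        raise ValueError("repeated points in centerline")
    s = np.concatenate([[0.0], np.cumsum(seg)])
    Ltot = s[-1]
    # resample to a uniform grid to match the ArcGrid contract
    n = len(pts)
    grid = ArcGrid(n, Ltot)
    su = grid.s
    pu = np.column_stack([np.interp(su, s, pts[:, k]) for k in range(3)])
    h = grid.h

    def d(a):
        return _dds(a, h)

    r1 = d(pu)
    r2 = d(r1)
    r3 = d(r2)
    cross = np.cross(r1, r2)
    cross_norm = np.linalg.norm(cross, axis=1)
    speed = np.linalg.norm(r1, axis=1)
    kappa = cross_norm / speed**3
    if kappa_floor is None:
        kappa_floor = 1e-3 / Ltot
    valid = kappa >= kappa_floor
    with np.errstate(invalid="ignore", divide="ignore"):
        tau = np.where(
            valid,
            np.einsum("ij,ij->i", cross, r3) / np.where(valid, cross_norm**2, 1.0),
            0.0,
        )
    # third-derivative stencils touching the ends are low accuracy
    edge = np.zeros_like(valid)
    edge[:3] = edge[-3:] = True
    return CurvatureTorsion(grid, kappa, tau, valid & ~edge)


# ---------------------------------------------------------------------------
# axonemal surface and test curves
# ---------------------------------------------------------------------------

#: angular positions of the nine doublet microtubules, clockwise numbering
#: as seen from the distal end; MT 2 sits on the d1 axis.
MT_ANGLES = 2.0 * np.pi * (2 - np.arange(1, 10)) / 9.0


def mt_centerlines(
    U: BendingTwistField, gamma: ShearField, rho_a: float
) -> list[np.ndarray]:
    """Centerlines of the nine doublet MTs on the axonemal surface.

    MT j lies at C(s, phi_j) = r + rho_a (cos phi d1 + sin phi d2 +
    (cos phi gamma1 + sin phi gamma2) d3); the axial offset term is the
    collective-sliding displacement that accompanies bending.
    """
    curve = integrate_frame(U)
    out = []
    for phi in MT_ANGLES:
        axial = np.cos(phi) * gamma.gamma1 + np.sin(phi) * gamma.gamma2
        rj = curve.r + rho_a * (
            np.cos(phi) * curve.d1
            + np.sin(phi) * curve.d2
            + axial[:, None] * curve.d3
        )
        out.append(rj)
    return out


def torsion_dipole_curve(
    plane_rotation: float = np.pi / 2,
    segment_lengths: tuple[float, float, float] = (1.0, 1.0, 1.0),
    grid: ArcGrid | None = None,
    curvature: float | None = None,
    smear_cells: int = 8,
) -> FramedCurve:
    """Three planar arcs whose plane rotates by +angle then -angle.

    The plane rotations are concentrated torsion impulses of opposite sign
    (a torsion dipole): the angle of the bending vector ramps by
    +-plane_rotation across each joint while the curvature stays constant.
    Each impulse is smeared over ``smear_cells`` grid cells — wide enough
    that centered differences recover the impulse integral (a single-cell
    jump systematically loses ~8% of it), narrow against any sensible
    segment length.  The 2D outline of such a curve is a looping curve for
    generic views.
    """
    if not (0 <= plane_rotation < np.pi):
        raise ValueError("plane_rotation must lie in [0, pi)")
    lengths = np.asarray(segment_lengths, dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("segment lengths must be positive")
    Ltot = float(lengths.sum())
    if grid is None:
        grid = ArcGrid(601, Ltot)
    elif abs(grid.L - Ltot) > 1e-12 * Ltot:
        raise ValueError("grid length must equal the total segment length")
    if curvature is None:
        curvature = 3.4 * np.pi / Ltot  # each third bends by ~200 degrees
    s = grid.s
    width = smear_cells * grid.h
    s1, s2 = lengths[0], lengths[0] + lengths[1]
    ramp_up = np.clip((s - s1) / width + 0.5, 0.0, 1.0)
    ramp_dn = np.clip((s - s2) / width + 0.5, 0.0, 1.0)
    psi = plane_rotation * (ramp_up - ramp_dn)
    U1 = curvature * np.cos(psi)
    U2 = curvature * np.sin(psi)
    return integrate_frame(BendingTwistField(grid, U1, U2, np.zeros_like(s)))


def project_outline(
    curve: FramedCurve | np.ndarray, view_direction: np.ndarray
) -> tuple[np.ndarray, bool]:
    """Orthographic projection of the centerline and a self-crossing flag."""
    v = np.asarray(view_direction, dtype=float)
    if abs(np.linalg.norm(v) - 1.0) > 1e-8:
        raise ValueError("view direction must be a unit vector")
    pts = curve.r if isinstance(curve, FramedCurve) else np.asarray(curve, float)
    # orthonormal basis of the viewing plane
    a = np.array([1.0, 0.0, 0.0])
    if abs(v @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    e1 = a - (a @ v) * v
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(v, e1)
    plane = np.column_stack([pts @ e1, pts @ e2])
    self_intersects = not LineString(plane).is_simple
    return plane, self_intersects
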