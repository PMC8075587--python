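"""Energy functionals of the composite flagellum and the force/target maps.

The flagellum's internal energy is the sum of three terms:

* the axoneme's passive elastic energy,
  ``W_pas = 1/2 int Ba (U1^2 + U2^2) + Ca U3^2 ds``;
* the active energy, minus the dyneins' work through collective sliding,
  ``W_act = int (H1 g1 + H2 g2) ds + H1_tip g1(L) + H2_tip g2(L)`` (the sign
  convention of the shear forces is fixed by the balance equations; see
  ``axoneme_active_energy``);
* the paraflagellar rod's shear energy, with the rod slaved to the axonemal
  surface at angle ``phi_p`` and only the in-plane shear V2 retained,
  ``W_p = 1/2 int Dp (-sin(phi_p) g1 + cos(phi_p) g2)^2 ds``.

Completing the square in the bending strains identifies the *target bending*
``U* = (U1*, U2*)`` the dynein forces would impose on a rod-free axoneme:

    U1*(s) = (H2_tip + int_s^L H2)/Ba,   U2*(s) = -(H1_tip + int_s^L H1)/Ba.

Inverting that map (``H1 = Ba dU2*/ds``, ``H1_tip = -Ba U2*(L)``, and with
flipped signs for the 2-components) lets actuation be prescribed as a target
waveform.  Concentrated tip forces are kept as separate scalars and handled
analytically — they enter boundary terms and tail integrals, never as grid
deltas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .geometry import (
    ArcGrid,
    BendingTwistField,
    FramedCurve,
    ShearField,
    _conform,
    _dds,
    shear_from_bending,
)

__all__ = [
    "AxonemeParams",
    "PFRParams",
    "ForcePattern",
    "TargetBending",
    "PFRStrains",
    "axoneme_passive_energy",
    "axoneme_active_energy",
    "pfr_attachment",
    "pfr_strains_exact",
    "pfr_strain_linearized",
    "pfr_energy",
    "total_energy",
    "target_bending_from_forces",
    "forces_from_target_bending",
]


PHI_P_DEFAULT = -2.0 * np.pi / 9.0  # Euglena gracilis attachment angle


@dataclass(frozen=True)
class AxonemeParams:
    """Axonemal moduli and geometry.

    Ba, Ca: bending and twist moduli (energy * length).  rho_a: axoneme
    radius; L: length.  The slender-rod reduction assumes rho_a << L.
    """

    Ba: float = 1.0
    Ca: float = 1.0
    rho_a: float = 0.01
    L: float = 1.0

    def __post_init__(self) -> None:
        for name in ("Ba", "Ca", "rho_a", "L"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.rho_a / self.L >= 0.05:
            warnings.warn(
                "rho_a/L >= 0.05: slender-rod reduction is inaccurate",
                stacklevel=2,
            )

    @property
    def nu(self) -> None:
        raise AttributeError("nu is a property of the PFR/axoneme pair")


@dataclass(frozen=True)
class PFRParams:
    """Paraflagellar rod moduli and attachment geometry.

    Dp, Ep: shear and stretch moduli (energy / length); rho_p: rod radius;
    phi_p: angle between the axoneme-rod joining line and the spontaneous
    bending plane (about -2*pi/9 in Euglena gracilis).
    """

    Dp: float = 3.0
    Ep: float = 0.0
    rho_p: float = 0.01
    phi_p: float = PHI_P_DEFAULT

    def __post_init__(self) -> None:
        if self.Dp < 0 or self.Ep < 0:
            raise ValueError("moduli must be nonnegative")
        if self.rho_p <= 0:
            raise ValueError("rho_p must be positive")
        if not (-np.pi < self.phi_p <= np.pi):
            raise ValueError("phi_p must lie in (-pi, pi]")

    @property
    def e_p(self) -> np.ndarray:
        """Unit vector of the joining line in the bending plane."""
        return np.array([np.cos(self.phi_p), np.sin(self.phi_p)])

    def nu(self, ax: AxonemeParams) -> float:
        """Nondimensional rod-to-axoneme stiffness ratio Dp / (Ba L^-2)."""
        return self.Dp * ax.L**2 / ax.Ba


@dataclass
class ForcePattern:
    """Distributed shear forces H1, H2 plus concentrated tip forces."""

    grid: ArcGrid
    H1: np.ndarray
    H2: np.ndarray
    H1_tip: float = 0.0
    H2_tip: float = 0.0

    def __post_init__(self) -> None:
        self.H1, self.H2 = _conform(self.grid, self.H1, self.H2)
        if not np.isfinite([self.H1_tip, self.H2_tip]).all():
            raise ValueError("tip forces must be finite")

    @classmethod
    def zero(cls, grid: ArcGrid) -> "ForcePattern":
        z = np.zeros(grid.n_nodes)
        return cls(grid, z, z.copy())

    def is_planar(self, tol: float = 0.0) -> bool:
        """True when the pattern drives bending only in the d1-d3 plane."""
        return (
            float(np.abs(self.H2).max(initial=0.0)) <= tol
            and abs(self.H2_tip) <= tol
        )


@dataclass
class TargetBending:
    """Bending field the dyneins would impose on a rod-free axoneme."""

    grid: ArcGrid
    U1_star: np.ndarray
    U2_star: np.ndarray

    def __post_init__(self) -> None:
        self.U1_star, self.U2_star = _conform(self.grid, self.U1_star, self.U2_star)


@dataclass
class PFRStrains:
    """Exact rod strains: shears V1, V2 and stretch V3 (dimensionless)."""

    grid: ArcGrid
    V1: np.ndarray
    V2: np.ndarray
    V3: np.ndarray

    def __post_init__(self) -> None:
        self.V1, self.V2, self.V3 = _conform(self.grid, self.V1, self.V2, self.V3)


# ---------------------------------------------------------------------------
# energies
# ---------------------------------------------------------------------------

def _trapz(y: np.ndarray, h: float) -> float:
    return float(np.trapezoid(y, dx=h))


def axoneme_passive_energy(U: BendingTwistField, p: AxonemeParams) -> float:
    h = U.grid.h
    return 0.5 * _trapz(p.Ba * (U.U1**2 + U.U2**2) + p.Ca * U.U3**2, h)


def axoneme_active_energy(U: BendingTwistField, f: ForcePattern) -> float:
    """Active internal energy: minus the dyneins' work through sliding.

    Evaluates ``int (H1 g1 + H2 g2) ds + H1_tip g1(L) + H2_tip g2(L)``.
    The overall sign is fixed by variational consistency: with the sign
    conventions of the torque-balance equations (H_perp = (-H2, H1), tip
    condition Ba U(L) = -Hhat_perp), this expression equals
    ``-Ba int U . U* ds``, so that the total energy is stationary exactly at
    the equilibria of the balance equations and the arc-generating actuation
    (H1 = 0, H1_tip = -Ba K) lowers the energy of the arc it drives.
    """
    if f.grid.n_nodes != U.grid.n_nodes:
        raise ValueError("force pattern and strain field grids differ")
    g = shear_from_bending(U)
    h = U.grid.h
    distributed = _trapz(f.H1 * g.gamma1 + f.H2 * g.gamma2, h)
    tip = f.H1_tip * g.gamma1[-1] + f.H2_tip * g.gamma2[-1]
    return distributed + tip


def pfr_strain_linearized(gamma: ShearField, phi_p: float) -> np.ndarray:
    """Linearized rod shear V2 = -sin(phi_p) gamma1 + cos(phi_p) gamma2."""
    return -np.sin(phi_p) * gamma.gamma1 + np.cos(phi_p) * gamma.gamma2


def pfr_energy(gamma: ShearField, q: PFRParams) -> float:
    V2 = pfr_strain_linearized(gamma, q.phi_p)
    return 0.5 * q.Dp * _trapz(V2**2, gamma.grid.h)


def total_energy(
    U: BendingTwistField,
    f: ForcePattern,
    p: AxonemeParams,
    q: PFRParams,
) -> dict[str, float]:
    """Total flagellar energy and its components.

    Returns the three-way split (passive, active, rod) and, when the
    actuation is planar and the field twistless, the complete-the-square
    regrouping: ``axoneme_grouped`` is the pure square
    (Ba/2) int |U - U*|^2, and passive + active equals the pure square plus
    the U-independent ``grouping_constant`` -(Ba/2) int U*^2 (up to
    quadrature-route differences of order h^2).
    """
    if not (U.grid.n_nodes == f.grid.n_nodes and abs(U.grid.L - f.grid.L) < 1e-12):
        raise ValueError("strain field and force pattern grids are inconsistent")
    gamma = shear_from_bending(U)
    w_pas = axoneme_passive_energy(U, p)
    w_act = axoneme_active_energy(U, f)
    w_p = pfr_energy(gamma, q)
    out = {
        "total": w_pas + w_act + w_p,
        "axoneme_passive": w_pas,
        "axoneme_active": w_act,
        "pfr": w_p,
    }
    if f.is_planar() and float(np.abs(U.U3).max()) == 0.0:
        t = target_bending_from_forces(f, p.Ba)
        h = U.grid.h
        w_a = 0.5 * p.Ba * _trapz(
            (U.U1 - t.U1_star) ** 2 + (U.U2 - t.U2_star) ** 2, h
        )
        out["axoneme_grouped"] = w_a
        out["grouping_constant"] = -0.5 * p.Ba * _trapz(
            t.U1_star**2 + t.U2_star**2, h
        )
    return out


# ---------------------------------------------------------------------------
# force <-> target-bending correspondence
# ---------------------------------------------------------------------------

def _tail_integral(y: np.ndarray, h: float) -> np.ndarray:
    """int_s^L y dt: total minus the cumulative integral.

    Cumulative Simpson where available (the target-bending field feeds
    higher-derivative operators downstream, so quadrature order matters),
    trapezoid otherwise.
    """
    try:
        from scipy.integrate import cumulative_simpson
        cum = np.r_[0.0, cumulative_simpson(y, dx=h)]
    except ImportError:  # pragma: no cover
        cum = cumulative_trapezoid(y, dx=h, initial=0.0)
    return cum[-1] - cum


def target_bending_from_forces(f: ForcePattern, Ba: float) -> TargetBending:
    h = f.grid.h
    U1s = (f.H2_tip + _tail_integral(f.H2, h)) / Ba
    U2s = -(f.H1_tip + _tail_integral(f.H1, h)) / Ba
    return TargetBending(f.grid, U1s, U2s)


def forces_from_target_bending(t: TargetBending, Ba: float) -> ForcePattern:
    h = t.grid.h
    H1 = Ba * _dds(t.U2_star, h)
    H2 = -Ba * _dds(t.U1_star, h)
    return ForcePattern(
        t.grid,
        H1,
        H2,
        H1_tip=-Ba * t.U2_star[-1],
        H2_tip=Ba * t.U1_star[-1],
    )


# ---------------------------------------------------------------------------
# rod attachment kinematics (exact, for diagnostics)
# ---------------------------------------------------------------------------

def pfr_attachment(
    curve: FramedCurve,
    gamma: ShearField,
    q: PFRParams,
    rho_a: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Rod centerline and cross-section frame slaved to the axoneme.

    The rod touches the axonemal surface at angle phi_p: its centerline is
    ``r_p = C(s, phi_p) + rho_p N(s, phi_p)``; the first frame vector g1 is
    the outer surface normal, g2 follows the tangent to the material section
    (the curve connecting equal-arclength points of adjacent doublets), and
    g3 completes the frame.  The g2 condition is what couples microtubule
    sliding to the rod cross-section orientation.
    """
    phi = q.phi_p
    c, sn = np.cos(phi), np.sin(phi)
    N = c * curve.d1 + sn * curve.d2
    axial = (c * gamma.gamma1 + sn * gamma.gamma2)[:, None]
    r_surf = curve.r + rho_a * (N + axial * curve.d3)
    r_p = r_surf + q.rho_p * N
    # tangent to the material section at phi_p
    dphiC = rho_a * (
        -sn * curve.d1
        + c * curve.d2
        + (-sn * gamma.gamma1 + c * gamma.gamma2)[:, None] * curve.d3
    )
    g2 = dphiC / np.linalg.norm(dphiC, axis=1, keepdims=True)
    g1 = N
    # g1 is orthogonal to g2 exactly (no d3 component in g1)
    g3 = np.cross(g1, g2)
    return r_p, g1, g2, g3


def pfr_strains_exact(
    r_p: np.ndarray,
    g1: np.ndarray,
    g2: np.ndarray,
    grid: ArcGrid,
) -> PFRStrains:
    """Exact rod strains by finite differences of the attached centerline."""
    h = grid.h
    drp = _dds(r_p, h)
    V1 = np.einsum("ij,ij->i", drp, g1)
    V2 = np.einsum("ij,ij->i", drp, g2)
    V3 = np.linalg.norm(drp, axis=1) - 1.0
    return PFRStrains(grid, V1, V2, V3)
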