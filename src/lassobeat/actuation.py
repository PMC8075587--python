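"""Dynein actuation patterns.

The dynein forces are prescribed, not self-organized: the working hypothesis
is that sliding inhibition by the rod attachment triggers a dynein
organization that, on a rod-free axoneme, would produce an asymmetric planar
(Chlamydomonas-like) beat.  Such actuation is specified through its target
bending, U2*(s) = A0 + A1 sin(2 pi s / L) for the static case and the
traveling wave U2*(s, t) = A0 + A1 sin(2 pi (s/L - t/T) n_w) for the dynamic
one, then converted to shear forces by the exact inversion of the
force-to-target map.  Planar actuation means H2 = H2_tip = 0, i.e. U1* = 0.

Default nondimensional amplitudes A0 L = 2 and A1 L = 2.5 give a visibly
asymmetric, wave-bearing beat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .elastic import ForcePattern, TargetBending
from .geometry import ArcGrid

__all__ = [
    "ActuationSpec",
    "static_target",
    "static_forces",
    "traveling_wave_forces",
]


@dataclass(frozen=True)
class ActuationSpec:
    """Amplitudes, period and wave count of the prescribed actuation.

    A0: mean target curvature (1/length); A1: wave amplitude (1/length);
    period: beat period T (time units); wavelengths: number of waves along
    the length; planar: enforce H2 = H2_tip = 0.
    """

    A0: float = 2.0
    A1: float = 2.5
    period: float = 1.0
    wavelengths: int = 1
    planar: bool = True

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("period must be positive")
        if self.wavelengths < 1:
            raise ValueError("need at least one wavelength")


def static_target(spec: ActuationSpec, grid: ArcGrid) -> TargetBending:
    """Asymmetric static target: U1* = 0, U2* = A0 + A1 sin(2 pi s / L)."""
    s = grid.s
    U2s = spec.A0 + spec.A1 * np.sin(2 * np.pi * spec.wavelengths * s / grid.L)
    return TargetBending(grid, np.zeros_like(s), U2s)


def traveling_wave_forces(
    spec: ActuationSpec, grid: ArcGrid, Ba: float, t: float
) -> ForcePattern:
    """Quasi-static force pattern driving a traveling target wave.

    U2*(s, t) = A0 + A1 sin(2 pi (s/L - t/T) n_w) is inverted analytically:
    H1 = Ba dU2*/ds, H1_tip = -Ba U2*(L, t); H2 and its tip force vanish
    (planar actuation).  The pattern is T-periodic in t.
    """
    if not spec.planar:
        raise ValueError("traveling-wave pattern requires planar actuation")
    s = grid.s
    k = 2 * np.pi * spec.wavelengths / grid.L
    phase = k * s - 2 * np.pi * spec.wavelengths * t / spec.period
    H1 = Ba * spec.A1 * k * np.cos(phase)
    H1_tip = -Ba * (spec.A0 + spec.A1 * np.sin(phase[-1]))
    z = np.zeros_like(s)
    return ForcePattern(grid, H1, z, H1_tip=H1_tip, H2_tip=0.0)


def static_forces(spec: ActuationSpec, grid: ArcGrid, Ba: float) -> ForcePattern:
    """Force pattern of the static asymmetric target A0 + A1 sin(2 pi s/L).

    Evaluated analytically (the t = 0 snapshot of the traveling wave) rather
    than through ``forces_from_target_bending``: downstream operators take a
    third derivative of the nodal forces, which amplifies the finite-
    difference wiggle a numerical inversion would leave at the endpoints.
    """
    return traveling_wave_forces(spec, grid, Ba, 0.0)
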