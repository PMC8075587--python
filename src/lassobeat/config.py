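"""Run configuration: schema-validated YAML with nondimensional defaults.

Internally everything is nondimensional: lengths in units of the flagellar
length L, energies in Ba/L, distributed forces in Ba/L^2, tip forces in
Ba/L, time in units of mu_perp L^4 / Ba.  The rod stiffness enters through
nu = Dp / (Ba L^-2).  Configs may therefore simply set the nondimensional
groups; dimensional values can be used as long as they are mutually
consistent.  Angles accept either radians or strings like ``"-2pi/9"``.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

__all__ = ["RunConfig", "load_config", "parse_angle"]

_ANGLE_RE = re.compile(
    r"^\s*(-?)\s*(\d+(?:\.\d+)?)?\s*\*?\s*pi\s*(?:/\s*(\d+(?:\.\d+)?))?\s*$",
    re.IGNORECASE,
)


def parse_angle(value: float | str) -> float:
    """Parse an angle given in radians or as a pi-fraction string.

    Accepts e.g. ``-0.698``, ``"pi/2"``, ``"-2pi/9"``, ``"3*pi/4"``.
    """
    if isinstance(value, (int, float)):
        return float(value)
    m = _ANGLE_RE.match(value)
    if not m:
        raise ValueError(f"cannot parse angle {value!r}")
    sign = -1.0 if m.group(1) == "-" else 1.0
    num = float(m.group(2)) if m.group(2) else 1.0
    den = float(m.group(3)) if m.group(3) else 1.0
    return sign * num * np.pi / den


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_default=True)


class AxonemeConfig(_Block):
    Ba: float = Field(1.0, gt=0, description="bending modulus (energy*length)")
    Ca: float = Field(1.0, gt=0, description="twist modulus (energy*length)")
    rho_a: float = Field(0.01, gt=0, description="axoneme radius (L units)")
    L: float = Field(1.0, gt=0, description="flagellar length")


class PFRConfig(_Block):
    nu: float = Field(3.0, ge=0, description="Dp / (Ba L^-2), rod stiffness ratio")
    Ep: float = Field(0.0, ge=0, description="stretch modulus (diagnostic only)")
    rho_p: float = Field(0.01, gt=0, description="rod radius (L units)")
    phi_p: float | str = Field("-2pi/9", description="attachment angle")

    @field_validator("phi_p")
    @classmethod
    def _angle(cls, v):
        return parse_angle(v)


class DragConfig(_Block):
    mu_perp: float = Field(1.0, gt=0)
    mu_par: float = Field(0.5, gt=0)
    mu_rot: float = Field(1e-3, gt=0)


class ActuationConfig(_Block):
    A0: float = Field(2.0, description="mean target curvature (1/L units)")
    A1: float = Field(2.5, description="wave amplitude (1/L units)")
    sperm_number: float = Field(
        3.0, gt=0, description="(mu_perp * 2pi/T * L^4 / Ba)^(1/4)"
    )
    wavelengths: int = Field(1, ge=1)
    planar: bool = True

    @property
    def period(self) -> float:
        """Nondimensional beat period implied by the sperm-number group."""
        return 2 * np.pi / self.sperm_number**4


class BodyConfig(_Block):
    semi_axes: tuple[float, float, float] = (1.0, 0.2, 0.2)
    eta: float = Field(0.46, gt=0, description="fluid viscosity (nondim)")
    tilt: float | str = Field(np.pi / 6, description="base tilt from body axis")

    @field_validator("tilt")
    @classmethod
    def _angle(cls, v):
        return parse_angle(v)


class NumericsConfig(_Block):
    n_nodes: int = Field(256, ge=32)
    n_nodes_equilibrium: int = Field(400, ge=8)
    steps_per_period: int = Field(400, ge=16)
    n_periods: int = Field(8, ge=3)
    kappa_floor: float = Field(1e-3, gt=0, description="torsion mask floor (1/L)")
    bvp_tol: float = Field(1e-9, gt=0)
    seed: int = Field(0, ge=0, description="seed for randomized diagnostics")


class RunConfig(_Block):
    axoneme: AxonemeConfig = AxonemeConfig()
    pfr: PFRConfig = PFRConfig()
    drag: DragConfig = DragConfig()
    actuation: ActuationConfig = ActuationConfig()
    body: BodyConfig = BodyConfig()
    numerics: NumericsConfig = NumericsConfig()

    def axoneme_params(self):
        from .elastic import AxonemeParams

        a = self.axoneme
        return AxonemeParams(Ba=a.Ba, Ca=a.Ca, rho_a=a.rho_a, L=a.L)

    def pfr_params(self):
        from .elastic import PFRParams

        a, r = self.axoneme, self.pfr
        return PFRParams(
            Dp=r.nu * a.Ba / a.L**2, Ep=r.Ep, rho_p=r.rho_p, phi_p=r.phi_p
        )

    def drag_coefficients(self):
        from .dynamics import DragCoefficients

        d = self.drag
        return DragCoefficients(mu_perp=d.mu_perp, mu_par=d.mu_par, mu_rot=d.mu_rot)

    def actuation_spec(self):
        from .actuation import ActuationSpec

        a = self.actuation
        return ActuationSpec(
            A0=a.A0 / self.axoneme.L,
            A1=a.A1 / self.axoneme.L,
            period=a.period,
            wavelengths=a.wavelengths,
            planar=a.planar,
        )

    def cell_body(self):
        from .swimming import CellBody

        b = self.body
        return CellBody(semi_axes=tuple(b.semi_axes), eta=b.eta, tilt=b.tilt)

    def dump(self, path: str | Path) -> None:
        """Write the fully resolved config next to run outputs."""
        Path(path).write_text(
            json.dumps(self.model_dump(mode="json"), indent=2) + "\n"
        )


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML config; missing keys take defaults.

    An empty or absent file yields the full default configuration
    (phi_p = -2pi/9, nu = 3, n = 256).  Unknown keys are rejected with the
    offending names in the error message.
    """
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        return RunConfig()
    return RunConfig.model_validate(data)
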