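"""Shared fixtures: random smooth fields and the reference beats.

The heavy dynamic runs (the rod-bearing beat and its rod-free control) are
session-scoped so the dynamics, swimming and acceptance tests share them.
"""

from __future__ import annotations

import numpy as np
import pytest

from lassobeat import ArcGrid, BendingTwistField, ForcePattern, RunConfig
from lassobeat.pipelines import run_beat, run_swim


def smooth_profile(grid: ArcGrid, rng: np.random.Generator, amp: float = 3.0,
                   modes: int = 3) -> np.ndarray:
    """Random band-limited profile: a few Fourier modes, decaying spectrum."""
    s = grid.s
    out = np.zeros_like(s)
    for k in range(1, modes + 1):
        out += amp * rng.normal() / k * np.sin(2 * np.pi * k * s / grid.L)
        out += amp * rng.normal() / k * np.cos(2 * np.pi * k * s / grid.L)
    return out


def smooth_bending(grid: ArcGrid, rng: np.random.Generator, amp: float = 3.0,
                   twist: bool = False, offset: float = 0.0) -> BendingTwistField:
    U3 = smooth_profile(grid, rng, amp) if twist else np.zeros(grid.n_nodes)
    return BendingTwistField(
        grid,
        smooth_profile(grid, rng, amp) + offset,
        smooth_profile(grid, rng, amp) + offset,
        U3,
    )


def smooth_forces(grid: ArcGrid, rng: np.random.Generator, amp: float = 10.0,
                  planar: bool = False) -> ForcePattern:
    H1 = smooth_profile(grid, rng, amp)
    H2 = np.zeros(grid.n_nodes) if planar else smooth_profile(grid, rng, amp)
    return ForcePattern(
        grid,
        H1,
        H2,
        H1_tip=float(rng.normal() * amp / 5),
        H2_tip=0.0 if planar else float(rng.normal() * amp / 5),
    )


@pytest.fixture(scope="session")
def default_config() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def euglenid_beat(default_config):
    """Converged beat of the rod-bearing flagellum at the default settings
    (nu = 3, phi_p = -2pi/9, sperm-number group 3)."""
    return run_beat(default_config)


@pytest.fixture(scope="session")
def planar_control_beat(default_config):
    """Rod-free (Dp = 0) control beat under the same actuation."""
    return run_beat(default_config, pfr_free=True)


@pytest.fixture(scope="session")
def swim_result(default_config, euglenid_beat):
    return run_swim(default_config, euglenid_beat["steady"], n_beats=40)
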