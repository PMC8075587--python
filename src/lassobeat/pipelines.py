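"""High-level pipelines tying the modules together.

These are the operations behind the command-line interface and the example
scripts: solve a static equilibrium and characterize its trace, integrate a
beat to its periodic steady state, turn a beat into a swimming path, and run
the torsion analysis on a waveform file.
"""

from __future__ import annotations

import numpy as np

from .actuation import static_forces, traveling_wave_forces
from .config import RunConfig
from .dynamics import (
    BeatSolution,
    periodic_steady_state,
    shapes_over_beat,
    solve_dynamics,
    torsion_kymograph,
)
from .elastic import ForcePattern
from .equilibrium import (
    bending_trace_metrics,
    planarity_classification,
    solve_equilibrium,
)
from .geometry import (
    ArcGrid,
    curvature_torsion_from_bending,
    curvature_torsion_from_centerline,
    integrate_frame,
    shear_from_bending,
)
from .swimming import helix_metrics, integrate_path, solve_rigid_velocities
from .waveforms import read_waveforms

__all__ = [
    "run_equilibrium",
    "run_beat",
    "run_swim",
    "torsion_analysis",
]


def run_equilibrium(cfg: RunConfig) -> dict:
    """Static equilibrium under the configured actuation, with trace metrics."""
    p, q = cfg.axoneme_params(), cfg.pfr_params()
    grid = ArcGrid(cfg.numerics.n_nodes_equilibrium, p.L)
    f = static_forces(cfg.actuation_spec(), grid, p.Ba)
    sol = solve_equilibrium(f, p, q, tol=cfg.numerics.bvp_tol)
    ct = curvature_torsion_from_bending(
        sol.U, kappa_floor=cfg.numerics.kappa_floor / p.L
    )
    metrics = bending_trace_metrics(sol)
    planar = planarity_classification(q.phi_p, f)
    gamma = shear_from_bending(sol.U)
    return {
        "solution": sol,
        "curvature_torsion": ct,
        "shear": gamma,
        "metrics": metrics,
        "predicted_planar": planar,
        "summary": {
            "energy": sol.energy,
            "residual_norm": sol.residual_norm,
            "trace_area": sol.trace_area,
            "tau_min": metrics["tau_min"],
            "tau_max": metrics["tau_max"],
            "max_abs_tau": ct.max_abs_tau(),
            "predicted_planar": planar,
            "nu": cfg.pfr.nu,
            "phi_p": q.phi_p,
        },
    }


def run_beat(cfg: RunConfig, pfr_free: bool = False) -> dict:
    """Integrate the beat to periodic steady state; torsion kymograph included."""
    p, q = cfg.axoneme_params(), cfg.pfr_params()
    if pfr_free:
        q = type(q)(Dp=0.0, Ep=q.Ep, rho_p=q.rho_p, phi_p=q.phi_p)
    drag = cfg.drag_coefficients()
    grid = ArcGrid(cfg.numerics.n_nodes, p.L)
    spec = cfg.actuation_spec()

    def forces(t: float) -> ForcePattern:
        return traveling_wave_forces(spec, grid, p.Ba, t)

    beat = solve_dynamics(
        forces,
        p,
        q,
        drag,
        grid,
        period=spec.period,
        n_periods=cfg.numerics.n_periods,
        steps_per_period=cfg.numerics.steps_per_period,
    )
    steady = periodic_steady_state(beat)
    kymo = torsion_kymograph(steady)  # curvature-scaled floor
    return {
        "beat": beat,
        "steady": steady,
        "kymograph": kymo,
        "summary": {
            "period": spec.period,
            "period_mismatch": steady.period_mismatch,
            "converged_periodic": steady.converged_periodic,
            "max_abs_twist": float(np.abs(steady.U3).max()),
            "tau_extremes": [
                float(kymo["tau"].min()),
                float(kymo["tau"].max()),
            ],
            "n_tracks": len(kymo["tracks"]),
            "track_speeds": [tr["speed"] for tr in kymo["tracks"]],
        },
    }


def run_swim(cfg: RunConfig, steady: BeatSolution, n_beats: int = 40) -> dict:
    """Swimming path and helix metrics from a periodic beat."""
    body = cfg.cell_body()
    drag = cfg.drag_coefficients()
    base_point, base_frame = body.base_pose()
    n_shapes = min(steady.steps_per_period, 50)
    shapes = shapes_over_beat(
        steady,
        n_shapes=n_shapes,
        base_point=base_point,
        base_frame=(base_frame[:, 0], base_frame[:, 1], base_frame[:, 2]),
    )
    rigid = solve_rigid_velocities(shapes, body, drag, steady.period)
    path = integrate_path(rigid, steady.period, n_beats)
    metrics = helix_metrics(path)
    return {
        "shapes": shapes,
        "rigid_velocities": rigid,
        "path": path,
        "helix": metrics,
        "summary": {
            "n_beats": n_beats,
            "radius": metrics["radius"],
            "pitch": metrics["pitch"],
            "handedness": metrics["handedness"],
            "body_rotations_per_turn": metrics["body_rotations_per_turn"],
        },
    }


def torsion_analysis(waveform_csv, kappa_floor: float | None = None) -> list:
    """Per-phase curvature/torsion of a waveform file (measured-beat pipeline)."""
    blocks = read_waveforms(waveform_csv)
    return [
        curvature_torsion_from_centerline(pts, kappa_floor=kappa_floor)
        for pts in blocks
    ]
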