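"""Synthetic waveform fixtures with analytically known curvature and torsion.

Stand-ins for reconstructed flagellar waveforms: circles (kappa = 1/R,
tau = 0), right-handed helices (kappa = a/(a^2+b^2), tau = b/(a^2+b^2)),
torsion dipoles (two opposite concentrated torsion impulses, zero net), and
a planar sinusoidal beat (tau = 0 at every phase).  Each generator writes the
standard waveform CSV plus a sidecar JSON of ground-truth values.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .geometry import ArcGrid, FramedCurve, torsion_dipole_curve
from .waveforms import write_waveforms

__all__ = ["generate_fixture", "helix_points", "circle_points", "FIXTURE_KINDS"]

FIXTURE_KINDS = ("helix", "circle", "torsion_dipole", "planar_beat")


def helix_points(a: float, b: float, n: int, n_turns: float = 2.0) -> np.ndarray:
    """Right-handed circular helix of radius a and pitch 2*pi*b."""
    t = np.linspace(0.0, 2 * np.pi * n_turns, n)
    return np.column_stack([a * np.cos(t), a * np.sin(t), b * t])


def circle_points(R: float, n: int, arc: float = 1.75 * np.pi) -> np.ndarray:
    t = np.linspace(0.0, arc, n)
    return np.column_stack([R * np.cos(t), R * np.sin(t), np.zeros_like(t)])


def _as_curve(pts: np.ndarray) -> FramedCurve:
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    L = float(seg.sum())
    grid = ArcGrid(len(pts), L)
    t = np.gradient(pts, axis=0)
    t /= np.linalg.norm(t, axis=1, keepdims=True)
    ref = np.array([0.0, 0.0, 1.0])
    d1 = np.cross(ref, t)
    bad = np.linalg.norm(d1, axis=1) < 1e-8
    d1[bad] = np.array([1.0, 0.0, 0.0])
    d1 /= np.linalg.norm(d1, axis=1, keepdims=True)
    d2 = np.cross(t, d1)
    return FramedCurve(grid, pts, d1, d2, t)


def generate_fixture(
    kind: str,
    out_prefix: str | Path,
    n_points: int = 200,
    n_phases: int = 1,
    params: dict | None = None,
) -> dict:
    """Write a synthetic waveform CSV plus ground-truth JSON; returns the truth."""
    params = dict(params or {})
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
    out_prefix = Path(out_prefix)
    shapes: list[FramedCurve] = []

    if kind == "circle":
        R = params.setdefault("radius", 1.0)
        shapes = [_as_curve(circle_points(R, n_points))]
        truth = {"kappa": 1.0 / R, "tau": 0.0}
    elif kind == "helix":
        a = params.setdefault("a", 1.0)
        b = params.setdefault("b", 0.3)
        shapes = [_as_curve(helix_points(a, b, n_points))]
        truth = {"kappa": a / (a**2 + b**2), "tau": b / (a**2 + b**2)}
    elif kind == "torsion_dipole":
        ang = params.setdefault("plane_rotation", np.pi / 2)
        lengths = params.setdefault("segment_lengths", (1.0, 1.0, 1.0))
        grid = ArcGrid(n_points, float(np.sum(lengths)))
        shapes = [torsion_dipole_curve(ang, tuple(lengths), grid)]
        truth = {
            "impulse_magnitude": ang,
            "net_torsion_integral": 0.0,
            "n_peaks": 2,
        }
    elif kind == "planar_beat":
        n_phases = max(n_phases, 6)
        A = params.setdefault("amplitude", 0.2)
        for k in range(n_phases):
            s = np.linspace(0, 1, n_points)
            y = A * np.sin(2 * np.pi * (s - k / n_phases))
            pts = np.column_stack([s, y, np.zeros_like(s)])
            shapes.append(_as_curve(pts))
        truth = {"tau": 0.0, "planar": True}

    write_waveforms(out_prefix.with_suffix(".csv"), shapes)
    payload = {"kind": kind, "params": params, "truth": truth}
    out_prefix.with_suffix(".json").write_text(json.dumps(payload, indent=2) + "\n")
    return payload
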