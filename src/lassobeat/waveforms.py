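"""Waveform, torsion and trajectory CSV formats.

Waveform CSV: columns ``phase_index, s, x, y, z``, one block of rows per
phase, header mandatory.  Arc length ``s`` is optional on input (recomputed
from the points when absent or blank).  Torsion CSV: ``s, kappa, tau, valid``
per phase.  Trajectory CSV: ``t, x, y, z, qw, qx, qy, qz``.  Floats are
written with repr-level precision so finite values round-trip bit-exactly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import CurvatureTorsion, FramedCurve

__all__ = [
    "write_waveforms",
    "read_waveforms",
    "write_torsion",
    "read_torsion",
    "write_trajectory",
]

_FLOAT_FMT = "%.17g"


def write_waveforms(path: str | Path, shapes: list[FramedCurve]) -> None:
    frames = []
    for k, sh in enumerate(shapes):
        frames.append(
            pd.DataFrame(
                {
                    "phase_index": k,
                    "s": sh.grid.s,
                    "x": sh.r[:, 0],
                    "y": sh.r[:, 1],
                    "z": sh.r[:, 2],
                }
            )
        )
    pd.concat(frames).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_waveforms(path: str | Path) -> list[np.ndarray]:
    """Read per-phase centerline point blocks (s recomputed downstream)."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"phase_index", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"waveform CSV missing columns: {sorted(missing)}")
    out = []
    for _, block in df.groupby("phase_index", sort=True):
        out.append(block[["x", "y", "z"]].to_numpy(dtype=float))
    return out


def write_torsion(
    path: str | Path, results: list[CurvatureTorsion], normalize: bool = False
) -> None:
    """Write per-phase curvature/torsion; ``normalize`` rescales to the
    conventions used for measured beats (s/L and tau*L)."""
    frames = []
    for k, ct in enumerate(results):
        L = ct.grid.L
        s = ct.grid.s / L if normalize else ct.grid.s
        tau = ct.tau * L if normalize else ct.tau
        kap = ct.kappa * L if normalize else ct.kappa
        frames.append(
            pd.DataFrame(
                {
                    "phase_index": k,
                    "s": s,
                    "kappa": kap,
                    "tau": tau,
                    "valid": ct.valid_mask.astype(int),
                }
            )
        )
    pd.concat(frames).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_torsion(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def write_trajectory(path: str | Path, swim_path) -> None:
    q = swim_path.quaternions  # scalar-last internally; write scalar-first
    pd.DataFrame(
        {
            "t": swim_path.times,
            "x": swim_path.positions[:, 0],
            "y": swim_path.positions[:, 1],
            "z": swim_path.positions[:, 2],
            "qw": q[:, 3],
            "qx": q[:, 0],
            "qy": q[:, 1],
            "qz": q[:, 2],
        }
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)
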