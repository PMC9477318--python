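"""Decomposition of the six base loads into the mechanical signal set.

The transverse forces and bending moments are rewritten as magnitude and
direction:

    F_T = sqrt(Fy² + Fz²)        F_D = angle of (Fy, Fz)
    M_B = sqrt(My² + Mz²)        M_D = angle of (My, Mz)

Directions use the quadrant-aware two-argument arctangent mapped to [0, 2π):
the mapping grids span all deflection directions, so a half-circle arctangent
would fold distinct deflections onto each other. ``F_x`` (axial force) and
``M_x`` (twisting moment) pass through unchanged. When a magnitude falls below
the zero threshold the corresponding direction is flagged undefined rather
than left as numerical noise.

Because each bending moment lies in a plane perpendicular to its reaction
force, M_D sits ~90° from F_D; the offset is exactly +90° whenever the axial
force is zero (and the contact point has positive x).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .elastica import BaseLoads
from .errors import DomainError

__all__ = [
    "SignalSet",
    "decompose",
    "recompose",
    "append_signal_columns",
    "direction_offset",
    "direction_offset_deg",
    "circular_mean_deg",
    "unwrap_direction",
    "ZERO_THRESHOLD",
]

ZERO_THRESHOLD = 1.0e-9  # μN or μN·mm; below solver noise


@dataclass(frozen=True)
class SignalSet:
    """The six mechanical signals at the whisker base.

    Forces in μN, moments in μN·mm, directions in radians in [0, 2π).
    ``fd_defined`` / ``md_defined`` are False when the magnitude is below the
    zero threshold, in which case the direction is 0.0 by convention.
    """

    Fx: float
    FT: float
    FD: float
    Mx: float
    MB: float
    MD: float
    fd_defined: bool = True
    md_defined: bool = True


def _full_circle(y, x):
    return np.mod(np.arctan2(y, x), 2.0 * np.pi)


def decompose(loads: BaseLoads) -> SignalSet:
    """Base loads -> (Fx, FT, FD, Mx, MB, MD)."""
    FT = float(np.hypot(loads.Fy, loads.Fz))
    MB = float(np.hypot(loads.My, loads.Mz))
    fd_def = FT >= ZERO_THRESHOLD
    md_def = MB >= ZERO_THRESHOLD
    FD = float(_full_circle(loads.Fz, loads.Fy)) if fd_def else 0.0
    MD = float(_full_circle(loads.Mz, loads.My)) if md_def else 0.0
    return SignalSet(loads.Fx, FT, FD, loads.Mx, MB, MD, fd_def, md_def)


def recompose(sig: SignalSet) -> BaseLoads:
    """Inverse of :func:`decompose` on the magnitude/direction pairs."""
    return BaseLoads(
        Fx=sig.Fx,
        Fy=sig.FT * np.cos(sig.FD),
        Fz=sig.FT * np.sin(sig.FD),
        Mx=sig.Mx,
        My=sig.MB * np.cos(sig.MD),
        Mz=sig.MB * np.sin(sig.MD),
    )


def append_signal_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorized decomposition appended to a table of base-load columns."""
    out = df.copy()
    out["FT"] = np.hypot(df["Fy"], df["Fz"])
    out["MB"] = np.hypot(df["My"], df["Mz"])
    out["FD_rad"] = _full_circle(df["Fz"].to_numpy(), df["Fy"].to_numpy())
    out["MD_rad"] = _full_circle(df["Mz"].to_numpy(), df["My"].to_numpy())
    out["FD_defined"] = out["FT"] >= ZERO_THRESHOLD
    out["MD_defined"] = out["MB"] >= ZERO_THRESHOLD
    out.loc[~out["FD_defined"], "FD_rad"] = 0.0
    out.loc[~out["MD_defined"], "MD_rad"] = 0.0
    return out


def direction_offset(sig: SignalSet) -> float:
    """Circular difference M_D − F_D mapped to (−180°, 180°], in degrees."""
    if not (sig.fd_defined and sig.md_defined):
        raise DomainError("direction offset undefined: magnitude below threshold")
    return float(_wrap_half(np.degrees(sig.MD - sig.FD)))


def direction_offset_deg(fd_rad, md_rad):
    """Vectorized M_D − F_D offset in (−180°, 180°]."""
    return _wrap_half(np.degrees(np.asarray(md_rad) - np.asarray(fd_rad)))


def _wrap_half(deg):
    """Wrap degrees into (−180, 180]."""
    return -np.mod(-np.asarray(deg) + 180.0, 360.0) + 180.0


def circular_mean_deg(angles_deg) -> float:
    """Circular mean of angles in degrees, reduced to [0°, 360°)."""
    a = np.deg2rad(np.asarray(angles_deg, float))
    mean = np.mod(np.degrees(np.arctan2(np.mean(np.sin(a)),
                                        np.mean(np.cos(a)))), 360.0)
    return float(0.0 if mean >= 360.0 - 1e-9 else mean)


def unwrap_direction(series_rad) -> np.ndarray:
    """Unwrap a direction time series (optional post-processing only).

    Plotted direction traces can exceed 2π when a trajectory winds around the
    circle; this is purely presentational and never applied to tables.
    """
    return np.unwrap(np.asarray(series_rad, float))
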