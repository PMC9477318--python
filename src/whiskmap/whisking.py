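"""Synthetic whisking-against-a-peg trials and peg-contour reconstruction.

The generator emulates the structure of the behavioral demonstration: a
body-restrained rat whisks a single whisker against a vertical peg (default
diameter 2.7 mm) at 1 ms frame resolution. During the forward sweep the
whisker presses the back (caudal) surface of the peg until it slips past;
during the backward sweep it presses the front (rostral) surface. Basepoint
position and the angles of emergence carry tracking-like jitter and are
low-pass filtered at 85 Hz before use, mirroring how tracked pose data are
smoothed.

Contact geometry uses a tangency model: at each penetrating frame the whisker
is rotated back about the vertical axis by the azimuthal overshoot δ until it
just grazes the peg circle (top view); the grazing point, projected onto the
cylinder surface, is the ground-truth contact point, and δ is the deflection
the elastica solver later reproduces. A side state machine flips
caudal→rostral (and back) whenever δ exceeds a slip threshold, emulating the
whisker snapping past the peg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.signal import butter, filtfilt

from .errors import ParameterError, StateError
from .geometry import WhiskerShape, spherical_grid_to_cartesian
from .mapping import MappingTable, TripletSpec, small_deflection_mask, _COLUMN

__all__ = [
    "PegModel",
    "WhiskParams",
    "WhiskTrajectory",
    "ReconstructionResult",
    "synth_whisk_trial",
    "lowpass_basepose",
    "trial_to_signals",
    "reconstruct_peg",
    "pose_rotation",
]


@dataclass(frozen=True)
class PegModel:
    """A vertical cylindrical peg in the lab frame."""

    x_mm: float = 9.97
    y_mm: float = 4.65
    diameter_mm: float = 2.7
    z_extent_mm: tuple = (-30.0, 30.0)

    def __post_init__(self):
        if self.diameter_mm <= 0:
            raise ParameterError("peg diameter must be positive")

    @property
    def radius_mm(self) -> float:
        return 0.5 * self.diameter_mm

    @property
    def axis_xy(self) -> np.ndarray:
        return np.array([self.x_mm, self.y_mm])


@dataclass(frozen=True)
class WhiskParams:
    """Kinematics of the synthetic whisk.

    One whisk cycle at ``frequency_hz`` starting fully retracted; protraction
    is a raised cosine of amplitude ``amplitude_deg`` about ``mean_deg``.
    Elevation drifts slowly so successive contacts spread along the peg's
    vertical axis. Jitter defaults emulate single-pixel tracking noise
    (58 μm pixels) on the basepoint and half-degree noise on the angles.
    """

    amplitude_deg: float = 25.0
    mean_deg: float = 0.0
    frequency_hz: float = 6.0
    n_cycles: int = 3
    elevation_mean_deg: float = 0.0
    elevation_amp_deg: float = 6.0
    elevation_freq_hz: float = 1.5
    basepoint_jitter_mm: float = 0.06
    angle_jitter_deg: float = 0.5
    slip_max_deg: float = 12.0
    frame_rate_hz: float = 1000.0


@dataclass
class WhiskTrajectory:
    """Time series of whisker pose and whisker-peg contact events (1 kHz)."""

    t_ms: np.ndarray
    basepoint: np.ndarray          # (T,3) lab frame, mm
    protraction_deg: np.ndarray
    elevation_deg: np.ndarray
    torsion_deg: np.ndarray
    in_contact: np.ndarray         # (T,) bool
    contact_lab: np.ndarray        # (T,3) NaN outside contact
    contact_whisker: np.ndarray    # (T,3) spherical (r,θ,φ), NaN outside
    side: np.ndarray               # (T,) '', 'back', 'front'
    meta: dict = field(default_factory=dict)
    peg: PegModel | None = None
    whisker: WhiskerShape | None = None

    def __post_init__(self):
        if not np.all(np.diff(self.t_ms) > 0):
            raise ParameterError("time must be strictly increasing")
        defined = np.isfinite(self.contact_whisker[:, 0])
        if not np.array_equal(defined, self.in_contact.astype(bool)):
            raise ParameterError("contact_whisker defined iff in_contact")

    @property
    def n_frames(self) -> int:
        return len(self.t_ms)

    def rotations(self) -> np.ndarray:
        """(T,3,3) whisker-frame -> lab-frame rotation per frame."""
        return pose_rotation(self.protraction_deg, self.elevation_deg,
                             self.torsion_deg)

    def contact_episodes(self):
        """Contiguous runs of contact frames as (start, stop, side) tuples."""
        c = self.in_contact.astype(int)
        edges = np.flatnonzero(np.diff(np.concatenate([[0], c, [0]])))
        out = []
        for a, b in zip(edges[::2], edges[1::2]):
            out.append((int(a), int(b), str(self.side[a])))
        return out


def pose_rotation(protraction_deg, elevation_deg, torsion_deg) -> np.ndarray:
    """R = Rz(protraction) · Ry(−elevation) · Rx(torsion), vectorized."""
    ps = np.deg2rad(np.atleast_1d(protraction_deg))
    el = np.deg2rad(np.atleast_1d(elevation_deg))
    to = np.deg2rad(np.atleast_1d(torsion_deg))
    cz, sz = np.cos(ps), np.sin(ps)
    cy, sy = np.cos(-el), np.sin(-el)
    cx, sx = np.cos(to), np.sin(to)
    T = len(ps)
    R = np.empty((T, 3, 3))
    # Rz @ Ry @ Rx composed directly
    R[:, 0, 0] = cz * cy
    R[:, 0, 1] = cz * sy * sx - sz * cx
    R[:, 0, 2] = cz * sy * cx + sz * sx
    R[:, 1, 0] = sz * cy
    R[:, 1, 1] = sz * sy * sx + cz * cx
    R[:, 1, 2] = sz * sy * cx - cz * sx
    R[:, 2, 0] = -sy
    R[:, 2, 1] = cy * sx
    R[:, 2, 2] = cy * cx
    return R


def _min_clearance(nodes_w, R, b, peg: PegModel, extra_rot_deg: float) -> float:
    """Min distance of the posed whisker to the peg axis minus its radius.

    ``extra_rot_deg`` applies an additional rotation about the vertical axis
    through the basepoint (the tangency search variable).
    """
    a = np.deg2rad(extra_rot_deg)
    c, s = np.cos(a), np.sin(a)
    Rz = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    q = (Rz @ R @ nodes_w.T).T + b
    zlo, zhi = peg.z_extent_mm
    inz = (q[:, 2] >= zlo) & (q[:, 2] <= zhi)
    if not inz.any():
        return np.inf
    d = np.hypot(q[inz, 0] - peg.x_mm, q[inz, 1] - peg.y_mm)
    return float(d.min() - peg.radius_mm)


def _tangency_contact(nodes_w, R, b, peg: PegModel, sign: float,
                      slip_max_deg: float):
    """Overshoot angle and grazing contact point, or None past the slip cap.

    ``sign`` = −1 clears by retraction (pressing the back surface), +1 by
    protraction (pressing the front).
    """
    f0 = _min_clearance(nodes_w, R, b, peg, 0.0)
    if f0 >= 0.0:
        return None  # not penetrating
    hi = slip_max_deg * 1.5
    fhi = _min_clearance(nodes_w, R, b, peg, sign * hi)
    if fhi < 0.0:
        return "slip"
    delta = brentq(lambda d: _min_clearance(nodes_w, R, b, peg, sign * d),
                   0.0, hi, xtol=1e-10)
    if delta > slip_max_deg:
        return "slip"
    a = np.deg2rad(sign * delta)
    c, s = np.cos(a), np.sin(a)
    Rz = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    q = (Rz @ R @ nodes_w.T).T + b
    d = np.hypot(q[:, 0] - peg.x_mm, q[:, 1] - peg.y_mm)
    k = int(np.argmin(d))
    radial = (q[k, :2] - peg.axis_xy) / max(d[k], 1e-12)
    c_lab = np.array([*(peg.axis_xy + peg.radius_mm * radial), q[k, 2]])
    return float(delta), c_lab


def _detect_contacts(whisker: WhiskerShape, peg: PegModel, basepoint,
                     prot_deg, elev_deg, tors_deg, slip_max_deg: float):
    """Per-frame contact state from the posed rigid whisker geometry."""
    T = len(prot_deg)
    rotations = pose_rotation(prot_deg, elev_deg, tors_deg)
    in_contact = np.zeros(T, bool)
    contact_lab = np.full((T, 3), np.nan)
    contact_w = np.full((T, 3), np.nan)
    side_arr = np.array([""] * T, dtype=object)
    side = "caudal"
    slipping = False  # after a slip, no contact until the whisker clears once
    nodes = whisker.nodes
    for t in range(T):
        R = rotations[t]
        b = basepoint[t]
        sign = -1.0 if side == "caudal" else 1.0
        res = _tangency_contact(nodes, R, b, peg, sign, slip_max_deg)
        if res is None:
            slipping = False
            continue
        if slipping:
            continue
        if res == "slip":
            side = "rostral" if side == "caudal" else "caudal"
            slipping = True
            continue
        _delta, c_lab = res
        in_contact[t] = True
        contact_lab[t] = c_lab
        side_arr[t] = "back" if side == "caudal" else "front"
        cw = R.T @ (c_lab - b)
        r = np.linalg.norm(cw)
        contact_w[t] = [r, np.degrees(np.arctan2(cw[1], cw[0])),
                        np.degrees(np.arctan2(cw[2], np.hypot(cw[0], cw[1])))]
    return in_contact, contact_lab, contact_w, side_arr


def synth_whisk_trial(whisker: WhiskerShape, peg: PegModel | None = None,
                      params: WhiskParams | None = None,
                      seed: int = 0) -> WhiskTrajectory:
    """Generate a synthetic whisk against a peg.

    The default placement produces two contiguous contact episodes per cycle:
    the forward sweep presses the back of the peg, slips past, and the
    backward sweep presses the front. An out-of-reach peg yields a valid
    trajectory with zero contact frames (with a warning).
    """
    peg = peg or PegModel()
    p = params or WhiskParams()
    rng = np.random.default_rng(seed)
    dt_ms = 1000.0 / p.frame_rate_hz
    T = int(round(p.n_cycles * p.frame_rate_hz / p.frequency_hz))
    t_ms = dt_ms * np.arange(T)
    t_s = t_ms / 1000.0
    prot = p.mean_deg - p.amplitude_deg * np.cos(2 * np.pi * p.frequency_hz * t_s)
    elev = (p.elevation_mean_deg
            + p.elevation_amp_deg * np.sin(2 * np.pi * p.elevation_freq_hz * t_s))
    tors = np.zeros(T)
    base = np.zeros((T, 3))
    base += p.basepoint_jitter_mm * rng.standard_normal((T, 3))
    prot = prot + p.angle_jitter_deg * rng.standard_normal(T)
    elev = elev + p.angle_jitter_deg * rng.standard_normal(T)
    in_c, c_lab, c_w, side = _detect_contacts(whisker, peg, base, prot, elev,
                                              tors, p.slip_max_deg)
    if not in_c.any():
        warnings.warn("peg is out of reach: trajectory has no contact frames")
    return WhiskTrajectory(
        t_ms=t_ms, basepoint=base, protraction_deg=prot, elevation_deg=elev,
        torsion_deg=tors, in_contact=in_c, contact_lab=c_lab,
        contact_whisker=c_w, side=side,
        meta={"seed": int(seed), "frame_rate_hz": p.frame_rate_hz,
              "slip_max_deg": p.slip_max_deg,
              "peg": {"x_mm": peg.x_mm, "y_mm": peg.y_mm,
                      "diameter_mm": peg.diameter_mm},
              "whisker_fingerprint": whisker.fingerprint(),
              "filtered_hz": None},
        peg=peg, whisker=whisker)


def lowpass_basepose(traj: WhiskTrajectory, cutoff_hz: float = 85.0,
                     whisker: WhiskerShape | None = None,
                     peg: PegModel | None = None) -> WhiskTrajectory:
    """Zero-phase low-pass of basepoint and emergence angles; contacts redone.

    A 4th-order Butterworth at ``cutoff_hz`` is applied forward-backward
    (zero phase) to the basepoint and angle channels only; the contact
    geometry is then recomputed from the smoothed pose.
    """
    fs = traj.meta.get("frame_rate_hz", 1000.0)
    if cutoff_hz >= fs / 2.0:
        raise ParameterError("cutoff must be below the Nyquist frequency")
    if cutoff_hz <= 0:
        raise ParameterError("cutoff must be positive")
    whisker = whisker or traj.whisker
    peg = peg or traj.peg
    if whisker is None or peg is None:
        raise StateError("need the whisker and peg to recompute contacts")
    b, a = butter(4, cutoff_hz, fs=fs)

    def lp(x):
        return filtfilt(b, a, x, axis=0)

    base = lp(traj.basepoint)
    prot = lp(traj.protraction_deg)
    elev = lp(traj.elevation_deg)
    tors = lp(traj.torsion_deg)
    slip_max = traj.meta.get("slip_max_deg", WhiskParams().slip_max_deg)
    in_c, c_lab, c_w, side = _detect_contacts(whisker, peg, base, prot, elev,
                                              tors, slip_max)
    meta = dict(traj.meta)
    meta["filtered_hz"] = cutoff_hz
    return WhiskTrajectory(traj.t_ms.copy(), base, prot, elev, tors, in_c,
                           c_lab, c_w, side, meta, peg, whisker)


def trial_to_signals(traj: WhiskTrajectory, whisker: WhiskerShape,
                     solver_opts=None, cone_deg: float = 2.0) -> pd.DataFrame:
    """Run the forward mechanics on every contact frame of a trial.

    Non-contact frames carry all-zero loads; frames where the contact solve
    does not converge are flagged and excluded downstream. Consecutive frames
    warm-start each other.
    """
    from .elastica import RodModel
    from .signals import append_signal_columns

    rod = RodModel(whisker, solver_opts)
    T = traj.n_frames
    cols = {k: np.zeros(T) for k in ("Fx", "Fy", "Fz", "Mx", "My", "Mz")}
    converged = np.ones(T, bool)
    contact_s = np.full(T, np.nan)
    tangent_x = np.full(T, np.nan)
    warm = None
    for t in range(T):
        if not traj.in_contact[t]:
            warm = None
            continue
        r, th, ph = traj.contact_whisker[t]
        target = spherical_grid_to_cartesian([r], [th], [ph])[0]
        res = rod.deflect(target, warm=warm)
        if not res.converged and warm is not None:
            res = rod.deflect(target)
        if res.converged:
            F, M = res.base_loads.as_arrays()
            cols["Fx"][t], cols["Fy"][t], cols["Fz"][t] = F
            cols["Mx"][t], cols["My"][t], cols["Mz"][t] = M
            contact_s[t] = res.contact_arc_length
            tangent_x[t] = res.contact_tangent[0]
            warm = rod.last_state
        else:
            converged[t] = False
            warm = None
    df = pd.DataFrame({"t_ms": traj.t_ms, "in_contact": traj.in_contact,
                       "converged": converged, **cols,
                       "contact_s_mm": contact_s, "tangent_x": tangent_x})
    df = append_signal_columns(df)
    excl = np.zeros(T, bool)
    if traj.in_contact.any():
        pts = spherical_grid_to_cartesian(traj.contact_whisker[traj.in_contact, 0],
                                          traj.contact_whisker[traj.in_contact, 1],
                                          traj.contact_whisker[traj.in_contact, 2])
        excl[traj.in_contact] = small_deflection_mask(pts, whisker, cone_deg)
    df["excluded_small_deflection"] = excl
    return df


@dataclass
class ReconstructionResult:
    """Estimated vs ground-truth lab-frame contact points for one trial."""

    frames: pd.DataFrame  # one row per retained contact frame
    triplet: TripletSpec

    @property
    def median_radial_error_mm(self) -> float:
        return float(self.frames["err_radial_mm"].abs().median())

    @property
    def median_angular_error_mm(self) -> float:
        return float(self.frames["err_angular_mm"].median())

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def reconstruct_peg(signals: pd.DataFrame, traj: WhiskTrajectory,
                    table: MappingTable,
                    spec: TripletSpec = TripletSpec(("Fx", "MB", "MD")),
                    k: int = 8) -> ReconstructionResult:
    """Invert per-frame signals and place the contact estimates in the lab.

    Retained frames are contact frames whose forward solve converged and that
    fall outside the small-deflection exclusion cone. The whisker-frame
    estimate from the lookup table is transformed by that frame's basepoint
    and orientation into the lab frame and compared against the ground-truth
    contact point. Errors are split into a radial component (along the true
    contact direction from the whisker base) and an angular component
    (perpendicular to it), both in mm.
    """
    from .mapping import invert_many

    keep = (traj.in_contact & signals["converged"].to_numpy(bool)
            & ~signals["excluded_small_deflection"].to_numpy(bool))
    idx = np.flatnonzero(keep)
    if len(idx) == 0:
        raise StateError("all frames excluded; nothing to reconstruct")
    q = np.column_stack([signals.loc[idx, _COLUMN[name]].to_numpy(float)
                         for name in spec])
    est = invert_many(q, table, spec, k=k)
    est_w = spherical_grid_to_cartesian(est["r_mm"], est["theta_deg"],
                                        est["phi_deg"])
    R = traj.rotations()[idx]
    b = traj.basepoint[idx]
    est_lab = np.einsum("tij,tj->ti", R, est_w) + b
    true_lab = traj.contact_lab[idx]
    true_w = np.einsum("tij,ti->tj", R, true_lab - b)  # R^T (c - b)
    err_w = est_w - true_w
    rhat = true_w / np.linalg.norm(true_w, axis=1, keepdims=True)
    err_rad = np.einsum("ti,ti->t", err_w, rhat)
    err_ang = np.linalg.norm(err_w - err_rad[:, None] * rhat, axis=1)
    frames = pd.DataFrame({
        "t_ms": traj.t_ms[idx],
        "side": traj.side[idx],
        "est_x": est_lab[:, 0], "est_y": est_lab[:, 1], "est_z": est_lab[:, 2],
        "true_x": true_lab[:, 0], "true_y": true_lab[:, 1],
        "true_z": true_lab[:, 2],
        "r_true_mm": traj.contact_whisker[idx, 0],
        "r_est_mm": est["r_mm"].to_numpy(),
        "theta_true_deg": traj.contact_whisker[idx, 1],
        "theta_est_deg": est["theta_deg"].to_numpy(),
        "phi_true_deg": traj.contact_whisker[idx, 2],
        "phi_est_deg": est["phi_deg"].to_numpy(),
        "err_radial_mm": err_rad,
        "err_angular_mm": err_ang,
        "err_total_mm": np.linalg.norm(est_lab - true_lab, axis=1),
        "extrapolated": est["extrapolated"].to_numpy(),
    })
    return ReconstructionResult(frames, spec)
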