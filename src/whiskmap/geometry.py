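"""Whisker geometry: shapes, frame alignment, and contact-point coordinates.

Whisker-centered coordinates place the origin at the whisker base with the
x-axis collinear with the proximal region of the whisker. The proximal 70% of
the whisker (close to planar for real vibrissae) lies as close as possible to
the x-y plane and the intrinsic curvature points the tip toward +y. A contact
point is given in spherical coordinates (r_wobj, θ_wobj, φ_wobj): the linear
distance from the origin, the azimuth of the contact point from the x-axis and
the elevation from the x-y plane.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import GeometryError, InputError, ParameterError, DomainError

__all__ = [
    "MaterialParams",
    "WhiskerShape",
    "ContactPoint",
    "build_gamma_like_whisker",
    "load_whisker_points",
    "save_whisker_points",
    "align_to_whisker_frame",
    "to_whisker_frame",
    "spherical_to_cartesian",
    "cartesian_to_spherical",
    "resample_polyline",
]


@dataclass(frozen=True)
class MaterialParams:
    """Material and taper parameters of a whisker.

    Young's modulus defaults to 3 GPa and Poisson's ratio to 0.38, typical
    values for rat vibrissae; the base radius is 100 μm with a base-to-tip
    radius ratio of 15 (linear taper).
    """

    youngs_modulus_gpa: float = 3.0
    poisson_ratio: float = 0.38
    base_radius_um: float = 100.0
    taper_ratio: float = 15.0

    def __post_init__(self):
        if self.youngs_modulus_gpa <= 0 or self.base_radius_um <= 0 or self.taper_ratio <= 0:
            raise ParameterError("material parameters must be positive")
        if not (0.0 < self.poisson_ratio < 0.5):
            raise ParameterError("poisson_ratio must lie in (0, 0.5)")
        if self.taper_ratio < 1.0:
            raise ParameterError("taper_ratio (base/tip) must be >= 1")

    @property
    def tip_radius_um(self) -> float:
        return self.base_radius_um / self.taper_ratio

    def to_dict(self) -> dict:
        return {
            "youngs_modulus_gpa": self.youngs_modulus_gpa,
            "poisson_ratio": self.poisson_ratio,
            "base_radius_um": self.base_radius_um,
            "taper_ratio": self.taper_ratio,
        }


@dataclass(frozen=True)
class ContactPoint:
    """Whisker-object contact point in whisker-centered spherical coordinates."""

    r_mm: float
    theta_deg: float
    phi_deg: float

    def __post_init__(self):
        if not np.isfinite([self.r_mm, self.theta_deg, self.phi_deg]).all():
            raise DomainError("contact point coordinates must be finite")
        if self.r_mm <= 0:
            raise DomainError("r_wobj must be positive")
        if not (-90.0 < self.phi_deg < 90.0):
            raise DomainError("phi_wobj must lie in (-90°, 90°)")


def spherical_to_cartesian(cp: ContactPoint) -> np.ndarray:
    """(r, θ, φ) in mm/degrees -> Cartesian position in mm."""
    th = np.deg2rad(cp.theta_deg)
    ph = np.deg2rad(cp.phi_deg)
    return np.array([
        cp.r_mm * np.cos(ph) * np.cos(th),
        cp.r_mm * np.cos(ph) * np.sin(th),
        cp.r_mm * np.sin(ph),
    ])


def cartesian_to_spherical(p) -> ContactPoint:
    """Cartesian mm -> ContactPoint; raises DomainError for the zero vector."""
    p = np.asarray(p, dtype=float)
    r = float(np.linalg.norm(p))
    if r <= 0.0:
        raise DomainError("cannot convert zero-length vector to spherical coordinates")
    theta = np.degrees(np.arctan2(p[1], p[0]))
    phi = np.degrees(np.arctan2(p[2], np.hypot(p[0], p[1])))
    return ContactPoint(r, float(theta), float(phi))


def spherical_grid_to_cartesian(r_mm, theta_deg, phi_deg):
    """Vectorized spherical -> Cartesian for arrays of coordinates."""
    th = np.deg2rad(np.asarray(theta_deg, float))
    ph = np.deg2rad(np.asarray(phi_deg, float))
    r = np.asarray(r_mm, float)
    return np.column_stack([
        r * np.cos(ph) * np.cos(th),
        r * np.cos(ph) * np.sin(th),
        r * np.sin(ph),
    ])


@dataclass(frozen=True)
class WhiskerShape:
    """Discretized undeflected whisker in the whisker-centered frame.

    nodes: (N,3) positions in mm, base at the origin, uniform arc spacing.
    arc_lengths: (N,) cumulative arc length per node, mm.
    radii_um: (N,) cross-section radius per node, μm (linear taper).
    """

    nodes: np.ndarray
    arc_lengths: np.ndarray
    radii_um: np.ndarray
    material: MaterialParams = field(default_factory=MaterialParams)

    def __post_init__(self):
        nodes = np.ascontiguousarray(np.asarray(self.nodes, float))
        arcs = np.asarray(self.arc_lengths, float)
        radii = np.asarray(self.radii_um, float)
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "arc_lengths", arcs)
        object.__setattr__(self, "radii_um", radii)
        if nodes.ndim != 2 or nodes.shape[1] != 3 or len(nodes) < 2:
            raise GeometryError("nodes must be an (N,3) array with N >= 2")
        if len(arcs) != len(nodes) or len(radii) != len(nodes):
            raise GeometryError("arc_lengths and radii must match the node count")
        if np.linalg.norm(nodes[0]) > 1e-9:
            raise GeometryError("first node must sit at the origin")
        if not np.all(np.diff(arcs) > 0):
            raise GeometryError("arc lengths must be strictly increasing")
        dif = np.diff(radii)
        if self.material.taper_ratio > 1.0 and not np.all(dif < 0):
            raise GeometryError("radii must strictly decrease under linear taper")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def total_arc_length(self) -> float:
        return float(self.arc_lengths[-1])

    def radius_at(self, s) -> np.ndarray:
        """Linear-taper radius (μm) at arc length s (mm)."""
        rb = self.material.base_radius_um
        rt = self.material.tip_radius_um
        return rb - (rb - rt) * np.asarray(s, float) / self.total_arc_length

    def nearest_point(self, p):
        """Nearest point on the node polyline to p.

        Returns (distance_mm, s_closest_mm, point_xyz).
        """
        d, s, q = nearest_on_polyline(np.asarray(p, float)[None, :], self.nodes,
                                      self.arc_lengths)
        return float(d[0]), float(s[0]), q[0]

    def fingerprint(self) -> str:
        """Stable hash of shape + material, used to pair tables with whiskers."""
        h = hashlib.sha256()
        h.update(np.round(self.nodes, 9).tobytes())
        h.update(np.round(self.radii_um, 6).tobytes())
        h.update(json.dumps(self.material.to_dict(), sort_keys=True).encode())
        return h.hexdigest()[:16]

    def with_material(self, material: MaterialParams) -> "WhiskerShape":
        rb, rt = material.base_radius_um, material.tip_radius_um
        radii = rb - (rb - rt) * self.arc_lengths / self.total_arc_length
        return WhiskerShape(self.nodes, self.arc_lengths, radii, material)


def _cumulative_arc(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_polyline(points: np.ndarray, n: int) -> np.ndarray:
    """Resample an ordered polyline to n nodes at uniform arc-length spacing."""
    arcs = _cumulative_arc(points)
    if arcs[-1] <= 0:
        raise GeometryError("polyline has zero length")
    s_new = np.linspace(0.0, arcs[-1], n)
    return np.column_stack([np.interp(s_new, arcs, points[:, c]) for c in range(3)])


def nearest_on_polyline(queries: np.ndarray, nodes: np.ndarray, arcs: np.ndarray):
    """Nearest point on a polyline for each query point (vectorized).

    Returns (distances, s_closest, points): the Euclidean distance, the arc
    length of the closest material point, and its position.
    """
    a = nodes[:-1]                       # (S,3)
    b = nodes[1:]
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    denom = np.where(denom <= 0, 1.0, denom)
    # (Q,S,3) differences
    qa = queries[:, None, :] - a[None, :, :]
    t = np.clip(np.einsum("qsj,sj->qs", qa, ab) / denom[None, :], 0.0, 1.0)
    proj = a[None, :, :] + t[:, :, None] * ab[None, :, :]
    d2 = np.sum((queries[:, None, :] - proj) ** 2, axis=2)
    k = np.argmin(d2, axis=1)
    rows = np.arange(len(queries))
    seg_len = arcs[1:] - arcs[:-1]
    s = arcs[:-1][k] + t[rows, k] * seg_len[k]
    return np.sqrt(d2[rows, k]), s, proj[rows, k]


def _rot_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix taking unit vector a to unit vector b."""
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if c < -1.0 + 1e-12:
        # antiparallel: rotate by pi about any axis orthogonal to a
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-8:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        K = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        return np.eye(3) + 2.0 * K @ K
    K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + K + K @ K / (1.0 + c)


def _rot_x(beta: float) -> np.ndarray:
    c, s = np.cos(beta), np.sin(beta)
    return np.array([[1.0, 0, 0], [0, c, -s], [0, s, c]])


def align_to_whisker_frame(points) -> np.ndarray:
    """Rigidly move an ordered 3D polyline into the whisker-centered frame.

    Steps: translate the base to the origin; rotate the base-to-10%-arc chord
    onto +x; rotate about x so the best-fit plane of the proximal 70% of the
    arc becomes the x-y plane; flip about x if needed so the tip has y > 0.
    The output is idempotent and invariant to rigid motions of the input.
    """
    p = np.asarray(points, dtype=float)
    if p.ndim != 2 or p.shape[1] != 3:
        raise InputError("points must be an (N,3) array")
    if len(p) < 10:
        raise InputError("need at least 10 points")
    p = p - p[0]
    arcs = _cumulative_arc(p)
    L = arcs[-1]
    if L <= 0:
        raise GeometryError("all points are coincident")
    s10 = 0.1 * L
    chord = np.array([np.interp(s10, arcs, p[:, c]) for c in range(3)])
    nc = np.linalg.norm(chord)
    if nc < 1e-12:
        raise GeometryError("degenerate proximal direction")
    R1 = _rot_between(chord / nc, np.array([1.0, 0.0, 0.0]))
    p = p @ R1.T
    # best-fit plane of the proximal 70% (by arc length)
    prox = p[arcs <= 0.7 * L]
    if len(prox) < 3:
        prox = p[: max(3, len(p) // 2)]
    centered = prox - prox.mean(axis=0)
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    normal = vt[-1]
    if svals[0] < 1e-12:
        raise GeometryError("degenerate proximal geometry")
    ny, nz = normal[1], normal[2]
    if np.hypot(ny, nz) > 1e-12:
        beta = np.arctan2(ny, nz)
        p = p @ _rot_x(beta).T
    if p[-1, 1] < 0:
        p = p @ _rot_x(np.pi).T
    return p


def to_whisker_frame(shape: WhiskerShape) -> WhiskerShape:
    """Frame-align an existing WhiskerShape (material preserved)."""
    aligned = align_to_whisker_frame(shape.nodes)
    return replace(shape, nodes=aligned)


def _shape_from_polyline(points: np.ndarray, material: MaterialParams,
                         n_nodes: int, align: bool) -> WhiskerShape:
    nodes = resample_polyline(points, n_nodes)
    # iterate to the fixed point where nodes are uniform in their own chord
    # metric, so resampling an already-uniform polyline is the identity
    for _ in range(3):
        nodes = resample_polyline(nodes, n_nodes)
    if align:
        nodes = align_to_whisker_frame(nodes)
    nodes = nodes - nodes[0]
    arcs = _cumulative_arc(nodes)
    rb, rt = material.base_radius_um, material.tip_radius_um
    radii = rb - (rb - rt) * arcs / arcs[-1]
    return WhiskerShape(nodes, arcs, radii, material)


def build_gamma_like_whisker(arc_length_mm: float = 20.0,
                             taper_ratio: float = 15.0,
                             base_radius_um: float = 100.0,
                             quad_coeff: float = 0.02,
                             oop_cubic_coeff: float = 0.12,
                             n_nodes: int = 100,
                             youngs_modulus_gpa: float = 3.0,
                             poisson_ratio: float = 0.38) -> WhiskerShape:
    """Synthetic whisker emulating a rat γ whisker.

    The in-plane shape is quadratic (``y = quad_coeff · x²``, curvature toward
    +y) and the distal ~30% of the arc leaves the plane with a cubic
    out-of-plane displacement reaching ``oop_cubic_coeff · L`` at the tip, so
    the proximal 70% is near-planar while the distal segment has significant
    out-of-plane curvature. A linear taper runs from the base radius to
    ``base_radius / taper_ratio`` at the tip.
    """
    if arc_length_mm <= 0:
        raise ParameterError("arc length must be positive")
    if taper_ratio <= 1.0:
        raise ParameterError("taper_ratio must exceed 1")
    if n_nodes < 20:
        raise ParameterError("need at least 20 nodes")
    material = MaterialParams(youngs_modulus_gpa, poisson_ratio,
                              base_radius_um, taper_ratio)
    t = np.linspace(0.0, 1.0, 4000)
    x = t * arc_length_mm
    y = quad_coeff * x ** 2
    z = oop_cubic_coeff * arc_length_mm * np.clip((t - 0.7) / 0.3, 0.0, None) ** 3
    pts = np.column_stack([x, y, z])
    # rescale so the arc length equals the requested value exactly
    pts *= arc_length_mm / _cumulative_arc(pts)[-1]
    return _shape_from_polyline(pts, material, n_nodes, align=True)


def load_whisker_points(path, material: MaterialParams | None = None,
                        n_nodes: int = 100) -> WhiskerShape:
    """Load an ordered 3D point file (CSV ``s_mm,x_mm,y_mm,z_mm`` or JSON).

    Points are resampled to uniform arc-length spacing; taper and material are
    attached from ``material`` (package defaults when omitted). The input frame
    is preserved apart from moving the base to the origin.
    """
    path = Path(path)
    if material is None:
        material = MaterialParams()
    try:
        if path.suffix.lower() == ".json":
            payload = json.loads(path.read_text())
            pts = np.asarray(payload["points"], dtype=float)
        else:
            df = pd.read_csv(path, comment="#")
            cols = [c for c in ("x_mm", "y_mm", "z_mm") if c in df.columns]
            if len(cols) != 3:
                raise InputError(f"{path}: expected columns x_mm,y_mm,z_mm")
            pts = df[cols].to_numpy(dtype=float)
    except (OSError, ValueError, KeyError) as exc:
        raise InputError(f"could not read whisker points from {path}: {exc}") from exc
    if len(pts) < 10:
        raise InputError("need at least 10 points")
    if not np.isfinite(pts).all():
        raise InputError("whisker points contain non-finite coordinates")
    if np.any(np.linalg.norm(np.diff(pts, axis=0), axis=1) <= 0):
        raise InputError("duplicate consecutive points")
    return _shape_from_polyline(pts, material, n_nodes, align=False)


def save_whisker_points(shape: WhiskerShape, path) -> None:
    """Write whisker nodes as CSV ``s_mm,x_mm,y_mm,z_mm`` (units in header)."""
    path = Path(path)
    df = pd.DataFrame({
        "s_mm": shape.arc_lengths,
        "x_mm": shape.nodes[:, 0],
        "y_mm": shape.nodes[:, 1],
        "z_mm": shape.nodes[:, 2],
    })
    with open(path, "w") as fh:
        fh.write("# whiskmap whisker points v1; units: mm\n")
        df.to_csv(fh, index=False)
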