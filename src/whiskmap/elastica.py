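"""Quasistatic, frictionless deflection of a tapered, curved whisker.

The solver deflects the whisker so that a material point reaches a prescribed
contact point while the applied point load stays orthogonal to the local
deflected tangent (a frictionless point contact). The six base loads are the
loads transmitted through the base cross-section — the force and moment the
whisker exerts on the follicle: ``F_base = F_applied`` and
``M_base = p_contact × F_applied``. With this convention the axial force
``F_x`` is positive when the contact pulls the whisker out of the follicle
(tension), which happens for distal, concave-forward contacts that straighten
the intrinsic curvature.

Internal unit system: mm, μN, μN·mm; Young's modulus is converted from GPa to
μN/mm² so load magnitudes stay near unity for typical whisker deflections.

Failure of the contact iteration to converge is interpreted as slip — the
whisker would slide off the contact point — and the target is discarded,
mirroring how non-convergence is treated when sweeping the reachable space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _rodcore
from .errors import ParameterError
from .geometry import ContactPoint, WhiskerShape, spherical_grid_to_cartesian

__all__ = [
    "BaseLoads",
    "DeflectionResult",
    "SolverOptions",
    "RodModel",
    "base_reactions",
    "deflect_to_point",
    "reachable_space",
]

GPA_TO_UN_PER_MM2 = 1.0e9  # 1 GPa = 1e9 μN/mm²


@dataclass(frozen=True)
class BaseLoads:
    """Loads transmitted through the base cross-section (whisker frame).

    Forces in μN, moments in μN·mm. ``Fx`` positive = the whisker is pulled
    out of the follicle. All six are zero when there is no contact.
    """

    Fx: float = 0.0
    Fy: float = 0.0
    Fz: float = 0.0
    Mx: float = 0.0
    My: float = 0.0
    Mz: float = 0.0

    def as_arrays(self):
        return (np.array([self.Fx, self.Fy, self.Fz]),
                np.array([self.Mx, self.My, self.Mz]))


def base_reactions(applied_force, contact_location) -> BaseLoads:
    """Base loads for a point load at a contact location (static equilibrium).

    The transmitted force equals the applied force and the transmitted moment
    is the moment of the applied force about the base,
    ``M = p_contact × F_applied``, both in the whisker-centered frame.
    """
    F = np.asarray(applied_force, float)
    p = np.asarray(contact_location, float)
    M = np.cross(p, F)
    return BaseLoads(float(F[0]), float(F[1]), float(F[2]),
                     float(M[0]), float(M[1]), float(M[2]))


@dataclass(frozen=True)
class DeflectionResult:
    deflected_nodes: np.ndarray
    applied_force: np.ndarray
    contact_location: np.ndarray
    contact_arc_length: float
    contact_tangent: np.ndarray
    base_loads: BaseLoads
    converged: bool
    iterations: int
    residual_mm: float
    reason: str = ""


@dataclass(frozen=True)
class SolverOptions:
    """Tolerances and iteration budgets of the contact solver."""

    tol_pos_mm: float = 1.0e-6       # target-reach tolerance
    tol_tangent: float = 1.0e-8      # |F·t|/|F| frictionless tolerance
    max_newton: int = 200
    max_equilibrium: int = 500
    eq_tol: float = 1.0e-10          # joint-angle fixed-point tolerance (rad)
    fmax_un: float = 1.0e6           # force cap before declaring slip
    on_whisker_tol_mm: float = 1.0e-8

    def __post_init__(self):
        if min(self.tol_pos_mm, self.tol_tangent, self.eq_tol) <= 0:
            raise ParameterError("solver tolerances must be positive")
        if self.max_newton < 1 or self.max_equilibrium < 1:
            raise ParameterError("iteration budgets must be positive")


def _parallel_transport_frames(nodes: np.ndarray):
    """Reference segment frames (e1, e2, tangent) with zero intrinsic twist."""
    seg = np.diff(nodes, axis=0)
    t = seg / np.linalg.norm(seg, axis=1)[:, None]
    n = len(t)
    frames = np.empty((n, 3, 3))
    # deterministic first normal: the world axis least aligned with t0
    trial = np.eye(3)[np.argmin(np.abs(t[0]))]
    e1 = trial - np.dot(trial, t[0]) * t[0]
    e1 /= np.linalg.norm(e1)
    for i in range(n):
        if i > 0:
            e1 = e1 - np.dot(e1, t[i]) * t[i]
            nrm = np.linalg.norm(e1)
            if nrm < 1e-12:  # right-angle kink; fall back to any normal
                trial = np.eye(3)[np.argmin(np.abs(t[i]))]
                e1 = trial - np.dot(trial, t[i]) * t[i]
                nrm = np.linalg.norm(e1)
            e1 = e1 / nrm
        e2 = np.cross(t[i], e1)
        frames[i] = np.column_stack([e1, e2, t[i]])
    return frames


def _rotvec_from_matrix(R: np.ndarray) -> np.ndarray:
    tr = np.trace(R)
    c = np.clip((tr - 1.0) / 2.0, -1.0, 1.0)
    angle = np.arccos(c)
    w = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    if angle < 1e-12:
        return 0.5 * w
    return angle / (2.0 * np.sin(angle)) * w


class RodModel:
    """Precomputed discrete-elastica arrays for one whisker.

    Holds the reference joint rotations, the joint compliances (bending
    ``EI(s)`` with ``I = π r⁴/4`` and torsion ``GJ`` with ``G = E/(2(1+ν))``,
    ``J = 2I``) and warm-start state used when sweeping grids.
    """

    def __init__(self, whisker: WhiskerShape, opts: SolverOptions | None = None):
        self.whisker = whisker
        self.opts = opts or SolverOptions()
        nodes = whisker.nodes
        arcs = whisker.arc_lengths
        ds = float(arcs[-1]) / (len(nodes) - 1)
        if not np.allclose(np.diff(arcs), ds, rtol=1e-4):
            raise ParameterError("RodModel requires uniform arc-length spacing")
        self.ds = ds
        self.L = float(arcs[-1])
        self.pos0 = np.ascontiguousarray(nodes, float)
        frames = _parallel_transport_frames(nodes)
        nj = len(frames)
        theta_ref = np.zeros((nj, 3))
        for i in range(1, nj):
            theta_ref[i] = _rotvec_from_matrix(frames[i - 1].T @ frames[i])
        self.theta_ref = np.ascontiguousarray(theta_ref)
        self.R0 = np.ascontiguousarray(frames[0])
        E = whisker.material.youngs_modulus_gpa * GPA_TO_UN_PER_MM2
        nu = whisker.material.poisson_ratio
        r_mm = whisker.radius_at(arcs[:nj]) * 1e-3
        I = np.pi * r_mm ** 4 / 4.0
        w = np.full(nj, ds)
        w[0] = 0.5 * ds
        self.comp_b = np.ascontiguousarray(w / (E * I))
        self.comp_t = np.ascontiguousarray(self.comp_b * (1.0 + nu))
        self._EI0 = E * I[0]

    # -- helpers -------------------------------------------------------------

    def _initial_guess(self, target: np.ndarray):
        from .geometry import nearest_on_polyline

        d, s, q = nearest_on_polyline(target[None, :], self.pos0,
                                      self.whisker.arc_lengths)
        s0 = float(np.clip(s[0], 2 * self.ds, self.L))
        k = min(int(s0 / self.ds), len(self.pos0) - 2)
        tangent = self.pos0[k + 1] - self.pos0[k]
        tangent /= np.linalg.norm(tangent)
        delta = target - q[0]
        dn = delta - np.dot(delta, tangent) * tangent
        # linearized cantilever stiffness at the contact arc
        E = self.whisker.material.youngs_modulus_gpa * GPA_TO_UN_PER_MM2
        r_mid = self.whisker.radius_at(0.4 * s0) * 1e-3
        k_lin = 3.0 * E * (np.pi * r_mid ** 4 / 4.0) / s0 ** 3
        F0 = k_lin * dn
        nrm = np.linalg.norm(F0)
        if nrm > 1e4:
            F0 *= 1e4 / nrm
        return F0, s0, float(d[0])

    def deflect_under_force(self, force, s_c: float,
                            theta_init=None) -> DeflectionResult:
        """Equilibrium shape under a prescribed point load at arc ``s_c``.

        No contact constraint is enforced; this is the forward problem used
        for validation against beam-theory oracles.
        """
        F = np.ascontiguousarray(force, float)
        s_c = float(np.clip(s_c, 1.5 * self.ds, self.L))
        theta = np.ascontiguousarray(self.theta_ref.copy()
                                     if theta_init is None else theta_init)
        n = len(self.pos0)
        pos = np.empty((n, 3))
        Rseg = np.empty((n - 1, 3, 3))
        iters, ok = _rodcore._equilibrium(
            theta, self.theta_ref, self.comp_b, self.comp_t, self.ds, self.R0,
            F, s_c, pos, Rseg, self.opts.max_equilibrium, self.opts.eq_tol)
        k = min(int(s_c / self.ds), len(Rseg) - 1)
        pc = self._point_at(pos, s_c)
        return DeflectionResult(pos.copy(), F.copy(), pc, s_c,
                                Rseg[k, :, 2].copy(), base_reactions(F, pc),
                                bool(ok), int(iters), 0.0,
                                "" if ok else "no-equilibrium")

    def deflect(self, target, warm=None) -> DeflectionResult:
        """Deflect the whisker so a material point reaches ``target`` (mm)."""
        target = np.ascontiguousarray(target, float)
        opts = self.opts
        F0, s0, dist = self._initial_guess(target)
        if dist < opts.on_whisker_tol_mm:
            # target already on the undeflected whisker: null deflection
            k = min(int(s0 / self.ds), len(self.pos0) - 2)
            tangent = self.pos0[k + 1] - self.pos0[k]
            tangent = tangent / np.linalg.norm(tangent)
            return DeflectionResult(self.pos0.copy(), np.zeros(3), target, s0,
                                    tangent, BaseLoads(), True, 0, 0.0)
        if np.linalg.norm(target) > self.L * (1.0 + 1e-9):
            return self._failure(target, "unreachable")
        theta_init = self.theta_ref
        if warm is not None:
            F0 = np.asarray(warm[0], float)
            s0 = float(warm[1])
            theta_init = warm[2]
        u, ok, iters, theta, pos, Rseg = _rodcore.solve_contact(
            self.theta_ref, self.comp_b, self.comp_t, self.ds, self.R0,
            target, np.ascontiguousarray(F0), s0,
            np.ascontiguousarray(theta_init),
            opts.max_newton, opts.tol_pos_mm, opts.tol_tangent, opts.fmax_un,
            opts.max_equilibrium, opts.eq_tol)
        if not ok:
            return self._failure(target, "slip", iters)
        F = u[:3].copy()
        s_c = float(u[3])
        k = min(int(s_c / self.ds), len(Rseg) - 1)
        tangent = Rseg[k, :, 2].copy()
        pc = self._point_at(pos, s_c)
        res = float(np.linalg.norm(pc - target))
        result = DeflectionResult(pos.copy(), F, pc, s_c, tangent,
                                  base_reactions(F, pc), True, int(iters), res)
        self._last_state = (F, s_c, theta.copy())
        return result

    def _point_at(self, pos, s):
        k = min(int(s / self.ds), len(pos) - 2)
        f = s / self.ds - k
        return (1.0 - f) * pos[k] + f * pos[k + 1]

    def _failure(self, target, reason, iters=0):
        return DeflectionResult(self.pos0.copy(), np.zeros(3), target, np.nan,
                                np.full(3, np.nan), BaseLoads(), False,
                                int(iters), np.nan, reason)

    @property
    def last_state(self):
        """Warm-start tuple (F, s_c, theta) from the last converged solve."""
        return getattr(self, "_last_state", None)


_ROD_CACHE: dict[tuple, RodModel] = {}


def _rod_for(whisker: WhiskerShape, opts: SolverOptions | None) -> RodModel:
    key = (whisker.fingerprint(), opts or SolverOptions())
    if key not in _ROD_CACHE:
        if len(_ROD_CACHE) > 16:
            _ROD_CACHE.clear()
        _ROD_CACHE[key] = RodModel(whisker, opts)
    return _ROD_CACHE[key]


def deflect_to_point(whisker: WhiskerShape, target: ContactPoint | np.ndarray,
                     solver_opts: SolverOptions | None = None,
                     warm=None) -> DeflectionResult:
    """Deflect ``whisker`` to a contact point; slip returns converged=False."""
    if isinstance(target, ContactPoint):
        from .geometry import spherical_to_cartesian

        target = spherical_to_cartesian(target)
    return _rod_for(whisker, solver_opts).deflect(target, warm=warm)


def reachable_space(whisker: WhiskerShape, grid, solver_opts=None,
                    cone_deg: float = 2.0, rim_patience: int = 2,
                    progress: bool = False):
    """Sweep a contact-point grid and build the forward mapping table.

    Targets are visited with warm-start continuation: for each (r, φ) the
    azimuth runs outward from the whisker's own azimuth at that arc length, so
    each solve starts from the neighbouring converged deflection. Grid points
    for which the solver cannot converge are recorded as discarded ("slip"),
    matching how slipping contacts are dropped when the reachable space is
    generated. The small-deflection exclusion cone (distance to the whisker
    below ``s_closest·tan(cone_deg)``) is flagged but not dropped.
    """
    from .mapping import MappingTable, small_deflection_mask
    from .signals import append_signal_columns

    rod = RodModel(whisker, solver_opts)
    rows = _grid_frame(grid)
    xyz = spherical_grid_to_cartesian(rows["r_mm"], rows["theta_deg"],
                                      rows["phi_deg"])
    n = len(rows["r_mm"])
    out = {
        "converged": np.zeros(n, bool),
        "Fx": np.full(n, np.nan), "Fy": np.full(n, np.nan), "Fz": np.full(n, np.nan),
        "Mx": np.full(n, np.nan), "My": np.full(n, np.nan), "Mz": np.full(n, np.nan),
        "contact_s_mm": np.full(n, np.nan),
        "tangent_x": np.full(n, np.nan),
        "discard_reason": np.array([""] * n, dtype=object),
    }

    # whisker azimuth/elevation per arc length, for continuation ordering
    def whisker_direction(r):
        idx = np.argmin(np.abs(whisker.arc_lengths - r))
        p = whisker.nodes[idx]
        return (np.degrees(np.arctan2(p[1], p[0])),
                np.degrees(np.arctan2(p[2], np.hypot(p[0], p[1]))))

    def record(i, res):
        out["converged"][i] = True
        F, M = res.base_loads.as_arrays()
        out["Fx"][i], out["Fy"][i], out["Fz"][i] = F
        out["Mx"][i], out["My"][i], out["Mz"][i] = M
        out["contact_s_mm"][i] = res.contact_arc_length
        out["tangent_x"][i] = res.contact_tangent[0]

    by_r = {}
    for i, (r, th, ph) in enumerate(zip(rows["r_mm"], rows["theta_deg"],
                                        rows["phi_deg"])):
        by_r.setdefault(r, {}).setdefault(ph, []).append((th, i))

    for r, phi_rows in sorted(by_r.items()):
        th0, ph0 = whisker_direction(r)
        phis = sorted(phi_rows)
        # two passes in elevation, each moving away from the whisker's own
        # elevation so every row can warm-start from its inward neighbour
        up = [p for p in phis if p >= ph0]
        down = [p for p in phis if p < ph0][::-1]
        for phi_pass in (up, down):
            prev_row: dict = {}
            for i_pass, ph in enumerate(phi_pass):
                items = sorted(phi_rows[ph])
                this_row: dict = {}
                ups = [(th, i) for th, i in items if th >= th0]
                downs = [(th, i) for th, i in items if th < th0][::-1]
                for branch in (ups, downs):
                    warm = None
                    misses = 0
                    for th, i in branch:
                        if misses >= rim_patience:
                            # past the slip rim of this branch; stop probing
                            out["discard_reason"][i] = "slip"
                            continue
                        cands = [g for g in (warm, prev_row.get(th))
                                 if g is not None]
                        if not cands:
                            cands = [None]  # cold start only at branch heads
                        for guess in cands:
                            res = rod.deflect(xyz[i], warm=guess)
                            if res.converged:
                                break
                        if res.converged:
                            record(i, res)
                            warm = rod.last_state
                            this_row[th] = warm
                            misses = 0
                        else:
                            out["discard_reason"][i] = res.reason or "slip"
                            warm = None
                            misses += 1
                prev_row = this_row
                if not this_row:
                    # entire elevation row unreachable; outward rows are too
                    for ph2 in phi_pass[i_pass + 1:]:
                        for _th, j in phi_rows[ph2]:
                            out["discard_reason"][j] = "slip"
                    break
        if progress:
            print(f"reachable_space: r={r} done "
                  f"({int(out['converged'].sum())} converged)")

    import pandas as pd

    df = pd.DataFrame({**rows, **out})
    df["excluded_small_deflection"] = small_deflection_mask(xyz, whisker, cone_deg)
    df = append_signal_columns(df)
    from .mapping import classify_region_frame

    df["region"] = classify_region_frame(df)
    meta = {
        "schema_version": 1,
        "whisker_fingerprint": whisker.fingerprint(),
        "cone_deg": cone_deg,
        "n_grid": n,
        "n_converged": int(df["converged"].sum()),
    }
    return MappingTable(df, meta)


def _grid_frame(grid):
    """Normalize a grid (list of ContactPoint or DataFrame) to plain arrays."""
    import pandas as pd

    if isinstance(grid, pd.DataFrame):
        return {c: grid[c].to_numpy(float) for c in ("r_mm", "theta_deg", "phi_deg")}
    r = np.array([cp.r_mm for cp in grid], float)
    th = np.array([cp.theta_deg for cp in grid], float)
    ph = np.array([cp.phi_deg for cp in grid], float)
    return {"r_mm": r, "theta_deg": th, "phi_deg": ph}
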