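"""Numerical kernels for the discrete elastica.

The whisker is modelled as a chain of rigid links of uniform length ``ds``
connected by elastic joints. Joint ``i`` sits at node ``i`` (``i = 0 .. N-2``;
joint 0 is at the clamp) and carries the rotation from the previous link frame
to the next. The undeflected shape defines reference joint rotations built by
parallel transport (zero intrinsic twist). Under a point load ``F`` applied at
arc length ``s_c``, equilibrium requires each joint rotation to equal its
reference plus the elastic strain ``C_i · m_i`` where ``m_i`` is the internal
moment at the joint expressed in the local frame and ``C_i`` the bending /
torsion compliance. That fixed point is solved by damped successive
substitution; the applied force and the contact arc length are then found by a
damped Newton iteration enforcing (a) the material point at ``s_c`` reaches the
target and (b) the force is orthogonal to the local tangent (frictionless
contact).

Joint compliances carry trapezoidal quadrature weights (half weight at the
clamp) so the small-deflection limit reproduces Euler–Bernoulli beam integrals
to second order in ``ds``.

All kernels operate on plain float64 arrays and are compiled with numba when
available; a pure-Python fallback keeps the module importable without it.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(func):
            return func

        return wrap


@njit(cache=True)
def _rodrigues(v0, v1, v2, R):
    """Rotation matrix of rotation vector (v0,v1,v2), written into R."""
    th2 = v0 * v0 + v1 * v1 + v2 * v2
    if th2 < 1e-24:
        a = 1.0
        b = 0.5
    else:
        th = np.sqrt(th2)
        a = np.sin(th) / th
        b = (1.0 - np.cos(th)) / th2
    # R = I + a*K + b*K^2 with K = skew(v)
    R[0, 0] = 1.0 + b * (-v2 * v2 - v1 * v1)
    R[0, 1] = -a * v2 + b * (v0 * v1)
    R[0, 2] = a * v1 + b * (v0 * v2)
    R[1, 0] = a * v2 + b * (v0 * v1)
    R[1, 1] = 1.0 + b * (-v2 * v2 - v0 * v0)
    R[1, 2] = -a * v0 + b * (v1 * v2)
    R[2, 0] = -a * v1 + b * (v0 * v2)
    R[2, 1] = a * v0 + b * (v1 * v2)
    R[2, 2] = 1.0 + b * (-v1 * v1 - v0 * v0)


@njit(cache=True)
def _reconstruct(theta, R0, ds, pos, Rseg):
    """Rebuild node positions and segment frames from joint rotation vectors."""
    nj = theta.shape[0]
    Rp = np.empty((3, 3))
    Rj = np.empty((3, 3))
    for r in range(3):
        for c in range(3):
            Rp[r, c] = R0[r, c]
    pos[0, 0] = 0.0
    pos[0, 1] = 0.0
    pos[0, 2] = 0.0
    for i in range(nj):
        _rodrigues(theta[i, 0], theta[i, 1], theta[i, 2], Rj)
        for r in range(3):
            a = Rp[r, 0] * Rj[0, 0] + Rp[r, 1] * Rj[1, 0] + Rp[r, 2] * Rj[2, 0]
            b = Rp[r, 0] * Rj[0, 1] + Rp[r, 1] * Rj[1, 1] + Rp[r, 2] * Rj[2, 1]
            c = Rp[r, 0] * Rj[0, 2] + Rp[r, 1] * Rj[1, 2] + Rp[r, 2] * Rj[2, 2]
            Rseg[i, r, 0] = a
            Rseg[i, r, 1] = b
            Rseg[i, r, 2] = c
        for r in range(3):
            Rp[r, 0] = Rseg[i, r, 0]
            Rp[r, 1] = Rseg[i, r, 1]
            Rp[r, 2] = Rseg[i, r, 2]
        pos[i + 1, 0] = pos[i, 0] + ds * Rseg[i, 0, 2]
        pos[i + 1, 1] = pos[i, 1] + ds * Rseg[i, 1, 2]
        pos[i + 1, 2] = pos[i, 2] + ds * Rseg[i, 2, 2]


@njit(cache=True)
def _point_at(pos, ds, s, out):
    """Linear interpolation of the polyline position at arc length s."""
    nseg = pos.shape[0] - 1
    k = int(s / ds)
    if k < 0:
        k = 0
    if k > nseg - 1:
        k = nseg - 1
    f = s / ds - k
    if f < 0.0:
        f = 0.0
    if f > 1.0:
        f = 1.0
    for c in range(3):
        out[c] = (1.0 - f) * pos[k, c] + f * pos[k + 1, c]
    return k


@njit(cache=True)
def _equilibrium(theta, theta_ref, comp_b, comp_t, ds, R0, F, s_c,
                 pos, Rseg, maxit, tol):
    """Relax joint rotations to equilibrium under point load F at arc s_c.

    Returns (iterations, converged).
    """
    nj = theta.shape[0]
    pc = np.empty(3)
    mix = 1.0
    prev_delta = 1.0e300
    for it in range(maxit):
        _reconstruct(theta, R0, ds, pos, Rseg)
        _point_at(pos, ds, s_c, pc)
        delta = 0.0
        for i in range(nj):
            s_i = i * ds
            if s_i < s_c - 1e-12:
                rx = pc[0] - pos[i, 0]
                ry = pc[1] - pos[i, 1]
                rz = pc[2] - pos[i, 2]
                Mx = ry * F[2] - rz * F[1]
                My = rz * F[0] - rx * F[2]
                Mz = rx * F[1] - ry * F[0]
            else:
                Mx = 0.0
                My = 0.0
                Mz = 0.0
            # local components in the pre-joint frame (clamp frame for i=0)
            if i == 0:
                m0 = R0[0, 0] * Mx + R0[1, 0] * My + R0[2, 0] * Mz
                m1 = R0[0, 1] * Mx + R0[1, 1] * My + R0[2, 1] * Mz
                m2 = R0[0, 2] * Mx + R0[1, 2] * My + R0[2, 2] * Mz
            else:
                m0 = Rseg[i - 1, 0, 0] * Mx + Rseg[i - 1, 1, 0] * My + Rseg[i - 1, 2, 0] * Mz
                m1 = Rseg[i - 1, 0, 1] * Mx + Rseg[i - 1, 1, 1] * My + Rseg[i - 1, 2, 1] * Mz
                m2 = Rseg[i - 1, 0, 2] * Mx + Rseg[i - 1, 1, 2] * My + Rseg[i - 1, 2, 2] * Mz
            t0 = theta_ref[i, 0] + comp_b[i] * m0
            t1 = theta_ref[i, 1] + comp_b[i] * m1
            t2 = theta_ref[i, 2] + comp_t[i] * m2
            d0 = t0 - theta[i, 0]
            d1 = t1 - theta[i, 1]
            d2 = t2 - theta[i, 2]
            ad = abs(d0)
            if abs(d1) > ad:
                ad = abs(d1)
            if abs(d2) > ad:
                ad = abs(d2)
            if ad > delta:
                delta = ad
            theta[i, 0] += mix * d0
            theta[i, 1] += mix * d1
            theta[i, 2] += mix * d2
        if delta < tol:
            _reconstruct(theta, R0, ds, pos, Rseg)
            return it + 1, True
        if delta > prev_delta * 1.2:
            mix *= 0.5
            if mix < 0.01:
                return it + 1, False
        elif delta < 0.5 * prev_delta and mix < 1.0:
            mix = min(1.0, mix * 1.25)
        prev_delta = delta
    return maxit, False


@njit(cache=True)
def _residual(theta, theta_ref, comp_b, comp_t, ds, R0, F, s_c, target,
              pos, Rseg, r, eq_maxit, eq_tol):
    """Position + frictionless-tangency residual; returns inner convergence."""
    it, ok = _equilibrium(theta, theta_ref, comp_b, comp_t, ds, R0, F, s_c,
                          pos, Rseg, eq_maxit, eq_tol)
    pc = np.empty(3)
    k = _point_at(pos, ds, s_c, pc)
    r[0] = pc[0] - target[0]
    r[1] = pc[1] - target[1]
    r[2] = pc[2] - target[2]
    fn = np.sqrt(F[0] * F[0] + F[1] * F[1] + F[2] * F[2])
    if fn > 1e-12:
        ft = (F[0] * Rseg[k, 0, 2] + F[1] * Rseg[k, 1, 2] + F[2] * Rseg[k, 2, 2]) / fn
    else:
        ft = 0.0
    r[3] = ft
    return ok


@njit(cache=True)
def _norm4(r, wt):
    return np.sqrt(r[0] * r[0] + r[1] * r[1] + r[2] * r[2] + wt * wt * r[3] * r[3])


@njit(cache=True)
def solve_contact(theta_ref, comp_b, comp_t, ds, R0, target, F0, s0, theta_init,
                  max_newton, tol_pos, tol_tan, fmax, eq_maxit, eq_tol):
    """Find the frictionless point load deflecting the rod to ``target``.

    Unknowns are the force vector and the contact arc length. Returns
    ``(u, converged, iterations, theta, pos, Rseg)`` where ``u[:3]`` is the
    applied force (μN) and ``u[3]`` the contact arc length (mm).
    """
    nj = theta_ref.shape[0]
    n = nj + 1
    L = nj * ds
    s_lo = 1.5 * ds
    wt = 5.0  # mm-equivalent weight of the tangency residual in the merit norm

    theta = theta_init.copy()
    pos = np.empty((n, 3))
    Rseg = np.empty((nj, 3, 3))
    r = np.empty(4)
    u = np.empty(4)
    u[0] = F0[0]
    u[1] = F0[1]
    u[2] = F0[2]
    u[3] = min(max(s0, s_lo), L)

    okin = _residual(theta, theta_ref, comp_b, comp_t, ds, R0, u[:3], u[3],
                     target, pos, Rseg, r, eq_maxit, eq_tol)
    J = np.empty((4, 4))
    rp = np.empty(4)
    for it in range(max_newton):
        rmax = max(abs(r[0]), max(abs(r[1]), abs(r[2])))
        if okin and rmax < tol_pos and abs(r[3]) < tol_tan:
            return u, True, it, theta, pos, Rseg
        fn = np.sqrt(u[0] * u[0] + u[1] * u[1] + u[2] * u[2])
        if fn > fmax:
            return u, False, it, theta, pos, Rseg
        # finite-difference Jacobian
        hF = 1e-6 * max(10.0, fn)
        for j in range(4):
            th_s = theta.copy()
            uj = u[j]
            if j < 3:
                h = hF
                u[j] = uj + h
            else:
                h = 1e-4
                if uj + h > L:
                    h = -1e-4
                u[j] = uj + h
            _residual(th_s, theta_ref, comp_b, comp_t, ds, R0, u[:3], u[3],
                      target, pos, Rseg, rp, eq_maxit, eq_tol)
            for q in range(4):
                J[q, j] = (rp[q] - r[q]) / h
            u[j] = uj
        # weight the tangency row to match the merit norm
        for c in range(4):
            J[3, c] *= wt
        rw = np.empty(4)
        rw[0] = r[0]
        rw[1] = r[1]
        rw[2] = r[2]
        rw[3] = wt * r[3]
        # Tikhonov-guarded solve
        lam = 1e-12
        for q in range(4):
            J[q, q] += lam
        step = np.linalg.solve(J, rw)
        base = _norm4(r, wt)
        alpha = 1.0
        accepted = False
        for _ls in range(9):
            ut = u.copy()
            for q in range(4):
                ut[q] = u[q] - alpha * step[q]
            if ut[3] < s_lo:
                ut[3] = s_lo
            if ut[3] > L:
                ut[3] = L
            th_t = theta.copy()
            okt = _residual(th_t, theta_ref, comp_b, comp_t, ds, R0, ut[:3],
                            ut[3], target, pos, Rseg, rp, eq_maxit, eq_tol)
            if okt and _norm4(rp, wt) < base * (1.0 - 1e-4 * alpha):
                for q in range(4):
                    u[q] = ut[q]
                    r[q] = rp[q]
                theta = th_t
                okin = True
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            return u, False, it, theta, pos, Rseg
    return u, False, max_newton, theta, pos, Rseg
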