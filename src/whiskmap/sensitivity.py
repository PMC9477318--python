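"""Numerical Jacobian of the contact point with respect to (M_D, M_B, F_x).

There is no analytic inverse mapping, so each element of the 3×3 Jacobian

    [∂r/∂M_D   ∂r/∂M_B   ∂r/∂F_x ]
    [∂θ/∂M_D   ∂θ/∂M_B   ∂θ/∂F_x ]
    [∂φ/∂M_D   ∂φ/∂M_B   ∂φ/∂F_x ]

is evaluated by central differences of a scattered-data interpolant of the
mapping table, holding the other two mechanical variables constant. The step
for each variable is 0.05% of that variable's own range over the analysis
envelope (by default the range spanned by a behavioral trial rather than the
full simulation space). Each probe point therefore needs 18 interpolations —
six per contact-point coordinate.

Interpolation is linear over a Delaunay triangulation of the signal points;
probes whose ± step leaves the convex hull are flagged invalid rather than
extrapolated. For presentation the per-element samples are trimmed to their
central 99% interval and binned 50×50 over (mechanical variable × element
value); bins holding fewer than 5% of the maximum bin count get the floor
display weight 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientDataError, ParameterError
from .mapping import MappingTable

__all__ = [
    "JACOBIAN_VARIABLES",
    "JacobianField",
    "BinnedSensitivity",
    "step_from_range",
    "signal_envelope",
    "jacobian_field",
    "trim_and_bin",
    "spread_by_quartile",
]

JACOBIAN_VARIABLES = ("MD", "MB", "Fx")          # column order
CONTACT_COORDS = ("r_mm", "theta_deg", "phi_deg")  # row order
_COLS = {"MD": "MD_rad", "MB": "MB", "Fx": "Fx"}
STEP_FRACTION = 5.0e-4  # 0.05% of each variable's range


def step_from_range(envelope) -> np.ndarray:
    """Central-difference steps: 0.05% of each variable's envelope range.

    ``envelope`` maps variable name -> (min, max), or is a (3,2) array in
    (MD, MB, Fx) order.
    """
    if isinstance(envelope, dict):
        env = np.array([envelope[v] for v in JACOBIAN_VARIABLES], float)
    else:
        env = np.asarray(envelope, float)
    if env.shape != (3, 2):
        raise ParameterError("envelope must give (min, max) per variable")
    span = env[:, 1] - env[:, 0]
    if np.any(span <= 0):
        raise ParameterError("degenerate envelope range")
    return STEP_FRACTION * span


def _unwrap_md(md: np.ndarray, center: float | None = None):
    """Shift M_D onto a continuous branch around its circular mean."""
    md = np.asarray(md, float)
    if center is None:
        center = np.arctan2(np.mean(np.sin(md)), np.mean(np.cos(md)))
    return center + np.angle(np.exp(1j * (md - center))), float(center)


def signal_envelope(source, pad: float = 0.0) -> dict:
    """(min, max) of MD, MB, Fx from a table or a signal DataFrame.

    ``pad`` expands each range by that fraction on both sides.
    """
    df = source.retained() if isinstance(source, MappingTable) else source
    md, _ = _unwrap_md(df["MD_rad"].to_numpy(float))
    vals = {"MD": md, "MB": df["MB"].to_numpy(float), "Fx": df["Fx"].to_numpy(float)}
    env = {}
    for name, v in vals.items():
        lo, hi = float(np.min(v)), float(np.max(v))
        w = (hi - lo) * pad
        env[name] = (lo - w, hi + w)
    return env


@dataclass
class JacobianField:
    """Central-difference Jacobian samples over the probe points.

    ``locations`` is (P,3) in (MD, MB, Fx); ``matrix`` is (P,3,3) with rows
    (r, θ, φ) and columns (MD, MB, Fx); ``valid`` flags interpolation success
    per element. Units: mm or degrees per (μN·mm or μN or radian).
    """

    locations: np.ndarray
    matrix: np.ndarray
    valid: np.ndarray
    steps: np.ndarray
    envelope: dict
    metadata: dict = field(default_factory=dict)

    @property
    def n_probes(self) -> int:
        return len(self.locations)


def jacobian_field(table: MappingTable, envelope: dict | None = None,
                   steps=None) -> JacobianField:
    """Evaluate the Jacobian at every retained table sample in the envelope.

    Probe points are the retained records themselves (no new grid), so each
    probe costs 18 interpolations of the scattered mapping.
    """
    from scipy.interpolate import LinearNDInterpolator

    sub = table.retained().reset_index(drop=True)
    if len(sub) < 10:
        raise InsufficientDataError("too few retained records for a Jacobian")
    md, center = _unwrap_md(sub["MD_rad"].to_numpy(float))
    pts = np.column_stack([md, sub["MB"].to_numpy(float), sub["Fx"].to_numpy(float)])
    coords = sub[list(CONTACT_COORDS)].to_numpy(float)
    if envelope is None:
        envelope = signal_envelope(table)
    env = np.array([envelope[v] for v in JACOBIAN_VARIABLES], float)
    if steps is None:
        steps = step_from_range(envelope)
    steps = np.asarray(steps, float)

    inside = np.all((pts >= env[:, 0]) & (pts <= env[:, 1]), axis=1)
    probes = pts[inside]
    if len(probes) == 0:
        raise InsufficientDataError("no table samples inside the envelope")

    interp = LinearNDInterpolator(pts, coords)
    matrix = np.empty((len(probes), 3, 3))
    valid = np.zeros((len(probes), 3, 3), bool)
    for j in range(3):
        e = np.zeros(3)
        e[j] = steps[j]
        up = interp(probes + e)      # (P,3) coordinate values
        dn = interp(probes - e)
        ok = np.isfinite(up).all(axis=1) & np.isfinite(dn).all(axis=1)
        deriv = (up - dn) / (2.0 * steps[j])
        matrix[:, :, j] = deriv
        valid[:, :, j] = ok[:, None]
    matrix[~valid] = np.nan
    return JacobianField(
        locations=probes, matrix=matrix, valid=valid, steps=steps,
        envelope=envelope,
        metadata={
            "interpolation": "linear simplex (Delaunay); "
                             "natural-neighbour unavailable in this stack",
            "md_branch_center_rad": center,
            "n_table_records": int(len(sub)),
            "n_probes": int(len(probes)),
        },
    )


@dataclass
class BinnedSensitivity:
    """50×50 binned summaries per Jacobian element, after 99% trimming.

    ``elements`` maps "d<coord>_d<var>" -> dict with bin edges, per-bin mean
    element value, count and display weight (count / max count, floored at
    0.05 for sparse bins). Bookkeeping per element: valid + invalid + trimmed
    = total probes.
    """

    elements: dict
    n_probes: int
    n_bins: int
    trim: float

    def to_dict(self) -> dict:
        def arr(a):
            return np.asarray(a).tolist()

        return {
            "n_probes": self.n_probes,
            "n_bins": self.n_bins,
            "trim": self.trim,
            "elements": {
                k: {kk: (arr(vv) if isinstance(vv, np.ndarray) else vv)
                    for kk, vv in e.items()}
                for k, e in self.elements.items()
            },
        }


def trim_and_bin(field: JacobianField, n_bins: int = 50, trim: float = 0.99,
                 alpha_floor: float = 0.05, min_samples: int = 100) -> BinnedSensitivity:
    """Trim each element to its central 99% interval and bin 50×50."""
    elements = {}
    n_probes = field.n_probes
    for i, coord in enumerate(("r", "theta", "phi")):
        for j, var in enumerate(JACOBIAN_VARIABLES):
            v = field.matrix[:, i, j]
            x = field.locations[:, j]
            ok = field.valid[:, i, j] & np.isfinite(v)
            n_valid = int(ok.sum())
            if n_valid < min_samples:
                raise InsufficientDataError(
                    f"element d{coord}/d{var}: {n_valid} valid samples")
            vv, xx = v[ok], x[ok]
            q = 0.5 * (1.0 - trim)
            lo, hi = np.quantile(vv, [q, 1.0 - q])
            keep = (vv >= lo) & (vv <= hi)
            n_trimmed = int((~keep).sum())
            vv, xx = vv[keep], xx[keep]
            counts, xe, ve = np.histogram2d(xx, vv, bins=n_bins)
            sums, _, _ = np.histogram2d(xx, vv, bins=[xe, ve], weights=vv)
            with np.errstate(invalid="ignore"):
                means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
            cmax = counts.max()
            alpha = counts / cmax if cmax > 0 else counts
            alpha[(counts > 0) & (counts < alpha_floor * cmax)] = alpha_floor
            elements[f"d{coord}_d{var}"] = {
                "x_edges": xe, "value_edges": ve,
                "mean": means, "count": counts.astype(int),
                "display_weight": alpha,
                "n_valid": n_valid,
                "n_invalid": int(n_probes - n_valid),
                "n_trimmed": n_trimmed,
                "n_binned": int(counts.sum()),
                "trim_interval": [float(lo), float(hi)],
            }
    return BinnedSensitivity(elements, n_probes, n_bins, trim)


def spread_by_quartile(field: JacobianField, by: str = "MB"):
    """IQR of each Jacobian element in the bottom vs top quartile of |by|.

    Returns (iqr_bottom, iqr_top), each (3,3). The mapping is better
    conditioned at large signal magnitudes, so the spread contracts in the
    top quartile.
    """
    j = JACOBIAN_VARIABLES.index(by)
    mag = np.abs(field.locations[:, j])
    q1, q3 = np.quantile(mag, [0.25, 0.75])
    lo_mask = mag <= q1
    hi_mask = mag >= q3
    iqr_lo = np.empty((3, 3))
    iqr_hi = np.empty((3, 3))
    for i in range(3):
        for jj in range(3):
            v = field.matrix[:, i, jj]
            ok = field.valid[:, i, jj] & np.isfinite(v)
            for mask, out in ((lo_mask, iqr_lo), (hi_mask, iqr_hi)):
                vv = v[ok & mask]
                out[i, jj] = (np.subtract(*np.quantile(vv, [0.75, 0.25]))
                              if len(vv) >= 8 else np.nan)
    return iqr_lo, iqr_hi


def plot_binned(binned: BinnedSensitivity, path) -> None:
    """3×3 panel figure of the binned sensitivity (diagnostic quality)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(3, 3, figsize=(11, 9))
    for i, coord in enumerate(("r", "theta", "phi")):
        for j, var in enumerate(JACOBIAN_VARIABLES):
            e = binned.elements[f"d{coord}_d{var}"]
            ax = axes[i, j]
            xc = 0.5 * (np.asarray(e["x_edges"])[:-1] + np.asarray(e["x_edges"])[1:])
            vc = 0.5 * (np.asarray(e["value_edges"])[:-1] + np.asarray(e["value_edges"])[1:])
            X, V = np.meshgrid(xc, vc, indexing="ij")
            w = np.asarray(e["display_weight"])
            m = w > 0
            ax.scatter(X[m], V[m], s=4, alpha=np.clip(w[m], 0.05, 1.0))
            ax.set_xlabel(var)
            ax.set_ylabel(f"d{coord}/d{var}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
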