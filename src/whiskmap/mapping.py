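"""Forward mapping tables and their inversion back to contact points.

A MappingTable pairs each grid contact point (r, θ, φ) with the signal set it
generates, plus convergence, exclusion and region flags. Inversion treats the
retained records as a lookup table in the space of a signal triplet: the query
is embedded (magnitudes z-scored over the table, directions as (cos, sin) to
avoid the 0/2π seam), and the contact point is read off by inverse-distance
weighting over the k nearest samples.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError, StateError
from .geometry import (ContactPoint, WhiskerShape, nearest_on_polyline,
                       spherical_grid_to_cartesian)

__all__ = [
    "SIGNAL_NAMES",
    "CIRCULAR_SIGNALS",
    "TripletSpec",
    "MappingTable",
    "build_grid",
    "flag_small_deflection",
    "small_deflection_mask",
    "invert",
    "invert_many",
    "classify_region",
    "classify_region_frame",
]

SIGNAL_NAMES = ("Fx", "FT", "FD", "Mx", "MB", "MD")
CIRCULAR_SIGNALS = frozenset({"FD", "MD"})
_COLUMN = {"Fx": "Fx", "FT": "FT", "FD": "FD_rad",
           "Mx": "Mx", "MB": "MB", "MD": "MD_rad"}

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class TripletSpec:
    """An unordered choice of three distinct signals out of the six."""

    names: tuple

    def __post_init__(self):
        names = tuple(self.names)
        if len(names) != 3 or len(set(names)) != 3:
            raise ParameterError("a triplet needs exactly 3 distinct signals")
        for n in names:
            if n not in SIGNAL_NAMES:
                raise ParameterError(f"unknown signal {n!r}")
        object.__setattr__(self, "names", names)

    def __iter__(self):
        return iter(self.names)

    def __str__(self):
        return "(" + ", ".join(self.names) + ")"

    @property
    def key(self) -> str:
        return "-".join(self.names)


def enumerate_triplets():
    """All 20 unordered 3-subsets of the six base signals, canonical order."""
    return [TripletSpec(c) for c in itertools.combinations(SIGNAL_NAMES, 3)]


def build_grid(r_range=(6.0, 20.0), r_step=1.0,
               theta_range=(-65.0, 65.0), theta_step=1.0,
               phi_range=(-60.0, 60.0), phi_step=1.0) -> pd.DataFrame:
    """Cartesian product grid of contact points with inclusive endpoints.

    Defaults reproduce the full sweep: radial distance 6–20 mm in millimeter
    increments, azimuth −65°..65° and elevation −60°..60° in single-degree
    increments (237,765 candidate points).
    """
    axes = []
    for (lo, hi), step, name in (((r_range), r_step, "r"),
                                 ((theta_range), theta_step, "theta"),
                                 ((phi_range), phi_step, "phi")):
        if step <= 0:
            raise ParameterError(f"{name} step must be positive")
        if hi < lo:
            raise ParameterError(f"{name} range is empty")
        n = int(np.floor((hi - lo) / step + 1e-9)) + 1
        axes.append(lo + step * np.arange(n))
    r, th, ph = axes
    rr, tt, pp = np.meshgrid(r, th, ph, indexing="ij")
    return pd.DataFrame({"r_mm": rr.ravel(), "theta_deg": tt.ravel(),
                         "phi_deg": pp.ravel()})


def reduced_grid() -> pd.DataFrame:
    """Desk-scale default grid (steps 2 mm / 3° / 3°)."""
    return build_grid(r_step=2.0, theta_step=3.0, phi_step=3.0)


# -- small-deflection exclusion cone ----------------------------------------

def small_deflection_mask(points_xyz: np.ndarray, whisker: WhiskerShape,
                          cone_deg: float = 2.0) -> np.ndarray:
    """True where a point lies inside the small-deflection cone.

    A point is excluded when its distance to the whisker is below
    ``s_closest · tan(cone_deg)`` where ``s_closest`` is the arc length of the
    nearest point on the undeflected whisker. Lookup resolution is too coarse
    there: tiny signal changes move the radial estimate by a lot.
    """
    d, s, _ = nearest_on_polyline(np.atleast_2d(points_xyz), whisker.nodes,
                                  whisker.arc_lengths)
    return d < s * np.tan(np.deg2rad(cone_deg))


def flag_small_deflection(target: ContactPoint, whisker: WhiskerShape,
                          cone_deg: float = 2.0) -> bool:
    from .geometry import spherical_to_cartesian

    p = spherical_to_cartesian(target)
    return bool(small_deflection_mask(p[None, :], whisker, cone_deg)[0])


# -- region classification ---------------------------------------------------

def classify_region_frame(df: pd.DataFrame) -> np.ndarray:
    """Vectorized CF / CB / large-deflection labels for converged records.

    Large deflection: the whisker segment at the contact has rotated past the
    orientation parallel to the y-z plane (deflected tangent x-component < 0);
    contacts beyond that tube flip F_D by ~180° and F_T passes through zero.
    Otherwise the azimuth sign relative to the intrinsic-curvature direction
    (+y) splits concave-forward (θ ≤ 0, deflection against the curvature)
    from concave-backward (θ > 0).
    """
    region = np.array([""] * len(df), dtype=object)
    conv = df["converged"].to_numpy(bool)
    tx = df["tangent_x"].to_numpy(float)
    th = df["theta_deg"].to_numpy(float)
    region[conv & (tx < 0)] = "ld"
    region[conv & (tx >= 0) & (th <= 0)] = "cf"
    region[conv & (tx >= 0) & (th > 0)] = "cb"
    return region


def classify_region(record) -> str:
    """Region of a single converged record (mapping-table row)."""
    tx = record["tangent_x"]
    if not record.get("converged", True) or not np.isfinite(tx):
        raise StateError("record lacks deflection metadata")
    if tx < 0:
        return "ld"
    return "cf" if record["theta_deg"] <= 0 else "cb"


# -- the table ----------------------------------------------------------------

class MappingTable:
    """Gridded forward mapping with convergence/exclusion flags.

    ``df`` holds one row per grid point; ``meta`` carries the schema version,
    the whisker fingerprint and grid provenance. Only converged rows carry
    loads/signals; ``retained()`` additionally drops the small-deflection
    exclusion cone.
    """

    def __init__(self, df: pd.DataFrame, meta: dict | None = None):
        self.df = df.reset_index(drop=True)
        self.meta = dict(meta or {})
        self.meta.setdefault("schema_version", SCHEMA_VERSION)
        key = self.df[["r_mm", "theta_deg", "phi_deg"]].round(9)
        if key.duplicated().any():
            raise ParameterError("duplicate grid coordinates in mapping table")
        self._indices = {}

    def __len__(self):
        return len(self.df)

    def converged(self) -> pd.DataFrame:
        return self.df[self.df["converged"]]

    def retained(self) -> pd.DataFrame:
        d = self.df
        return d[d["converged"] & ~d["excluded_small_deflection"]]

    # -- persistence (delegated) --
    def save_csv(self, path):
        from .io import save_table_csv

        save_table_csv(self, path)

    def save_hdf5(self, path):
        from .io import save_table_hdf5

        save_table_hdf5(self, path)

    @staticmethod
    def load(path):
        from .io import load_table

        return load_table(path)

    # -- triplet feature embedding --
    def _embedding(self, spec: TripletSpec, df: pd.DataFrame | None = None):
        """Feature matrix for a triplet: z-scored magnitudes, (cos,sin) angles."""
        base = self.retained() if df is None else df
        cols, stats = [], []
        for name in spec:
            v = base[_COLUMN[name]].to_numpy(float)
            if name in CIRCULAR_SIGNALS:
                cols += [np.cos(v), np.sin(v)]
                stats.append((name, None, None))
            else:
                mu, sd = float(v.mean()), float(v.std())
                sd = sd if sd > 1e-12 else 1.0
                cols.append((v - mu) / sd)
                stats.append((name, mu, sd))
        return np.column_stack(cols), stats

    def _embed_query(self, spec: TripletSpec, stats, values: np.ndarray):
        cols = []
        j = 0
        for name, mu, sd in stats:
            v = np.asarray(values[:, j], float)
            if name in CIRCULAR_SIGNALS:
                cols += [np.cos(v), np.sin(v)]
            else:
                cols.append((v - mu) / sd)
            j += 1
        return np.column_stack(cols)

    def triplet_index(self, spec: TripletSpec):
        """Cached nearest-neighbour index over the retained records."""
        key = spec.key
        if key not in self._indices:
            from sklearn.neighbors import NearestNeighbors

            sub = self.retained().reset_index(drop=True)
            if len(sub) == 0:
                raise StateError("mapping table has no retained records")
            X, stats = self._embedding(spec, sub)
            nn = NearestNeighbors(n_neighbors=min(8, len(sub))).fit(X)
            d_nn, _ = nn.kneighbors(X, n_neighbors=min(2, len(sub)))
            med_spacing = float(np.median(d_nn[:, -1])) if len(sub) > 1 else 1.0
            self._indices[key] = (nn, stats, sub, med_spacing)
        return self._indices[key]


def invert_many(queries: np.ndarray, table: MappingTable, spec: TripletSpec,
                k: int = 8):
    """Vectorized lookup of contact points for triplet queries.

    ``queries`` is (Q,3) in the order of ``spec`` (directions in radians).
    Returns a DataFrame with the interpolated (r, θ, φ), the distance to the
    nearest table sample, and an ``extrapolated`` flag when the query lies
    farther from the sample cloud than 3× the table's median nearest-neighbour
    spacing. Queries matching a retained record exactly return that record's
    coordinates (ties broken by the smallest r).
    """
    if "whisker_fingerprint" not in table.meta:
        raise StateError("mapping table lacks a whisker fingerprint")
    nn, stats, sub, spacing = table.triplet_index(spec)
    queries = np.atleast_2d(np.asarray(queries, float))
    Xq = table._embed_query(spec, stats, queries)
    k = min(k, len(sub))
    dist, idx = nn.kneighbors(Xq, n_neighbors=k)
    coords = sub[["r_mm", "theta_deg", "phi_deg"]].to_numpy(float)
    r_neighbors = coords[idx, 0]

    exact = dist[:, 0] < 1e-12
    with np.errstate(divide="ignore"):
        w = 1.0 / np.maximum(dist, 1e-300)
    w /= w.sum(axis=1, keepdims=True)
    est = np.einsum("qk,qkc->qc", w, coords[idx])
    if exact.any():
        # exact hits: return that record; among exact duplicates pick min r
        for q in np.where(exact)[0]:
            dup = dist[q] < 1e-12
            cand = idx[q][dup]
            best = cand[np.argmin(r_neighbors[q][dup])]
            est[q] = coords[best]
    return pd.DataFrame({
        "r_mm": est[:, 0], "theta_deg": est[:, 1], "phi_deg": est[:, 2],
        "nearest_distance": dist[:, 0],
        "extrapolated": dist[:, 0] > 3.0 * spacing,
    })


def invert(query, table: MappingTable, spec: TripletSpec, k: int = 8):
    """Single-query lookup; returns (ContactPoint, diagnostics dict)."""
    res = invert_many(np.asarray(query, float)[None, :], table, spec, k=k)
    row = res.iloc[0]
    cp = ContactPoint(float(row["r_mm"]), float(row["theta_deg"]),
                      float(row["phi_deg"]))
    return cp, {"nearest_distance": float(row["nearest_distance"]),
                "extrapolated": bool(row["extrapolated"])}


def contact_xyz(df: pd.DataFrame) -> np.ndarray:
    """Cartesian contact locations of table rows (mm)."""
    return spherical_grid_to_cartesian(df["r_mm"].to_numpy(),
                                       df["theta_deg"].to_numpy(),
                                       df["phi_deg"].to_numpy())
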