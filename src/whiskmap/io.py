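"""Readers and writers for mapping tables, trajectories and reports.

Every file carries a schema version and unit annotations. CSV files start
with ``# whiskmap-<kind> v<version>`` followed by a ``# meta: <json>`` line;
the HDF5 container mirrors the same columns as datasets with the metadata in
root attributes. Unknown (future) schema versions raise VersionError rather
than misparsing silently.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError, VersionError

TABLE_KIND = "whiskmap-mapping-table"
TRAJ_KIND = "whiskmap-trajectory"
SUPPORTED_VERSION = 1

_TABLE_UNITS = ("r_mm,theta_deg,phi_deg in mm/deg; forces uN; moments uN*mm; "
                "directions rad in [0,2pi)")


def _write_csv(df: pd.DataFrame, path, kind: str, meta: dict, units: str):
    with open(path, "w") as fh:
        fh.write(f"# {kind} v{SUPPORTED_VERSION}\n")
        fh.write(f"# units: {units}\n")
        fh.write(f"# meta: {json.dumps(meta, sort_keys=True)}\n")
        df.to_csv(fh, index=False)


def _read_header(path, kind: str) -> dict:
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith(f"# {kind} v"):
            raise InputError(f"{path}: not a {kind} file")
        version = int(first.rsplit("v", 1)[1])
        if version > SUPPORTED_VERSION:
            raise VersionError(
                f"{path}: schema v{version} is newer than supported "
                f"v{SUPPORTED_VERSION}")
        meta = {}
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("# meta:"):
                meta = json.loads(line.split(":", 1)[1])
    meta["schema_version"] = version
    return meta


def save_table_csv(table, path) -> None:
    _write_csv(table.df, path, TABLE_KIND, table.meta, _TABLE_UNITS)


def load_table_csv(path):
    from .mapping import MappingTable

    meta = _read_header(path, TABLE_KIND)
    df = pd.read_csv(path, comment="#")
    df["discard_reason"] = df.get("discard_reason", "").fillna("")
    df["region"] = df.get("region", "").fillna("")
    return MappingTable(df, meta)


def save_table_hdf5(table, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["kind"] = TABLE_KIND
        f.attrs["schema_version"] = table.meta.get("schema_version",
                                                   SUPPORTED_VERSION)
        f.attrs["meta"] = json.dumps(table.meta, sort_keys=True)
        f.attrs["units"] = _TABLE_UNITS
        for col in table.df.columns:
            v = table.df[col].to_numpy()
            if v.dtype == object:
                v = v.astype("S32")
            f.create_dataset(col, data=v)


def load_table_hdf5(path):
    import h5py

    from .mapping import MappingTable

    with h5py.File(path, "r") as f:
        if f.attrs.get("kind") != TABLE_KIND:
            raise InputError(f"{path}: not a {TABLE_KIND} container")
        version = int(f.attrs["schema_version"])
        if version > SUPPORTED_VERSION:
            raise VersionError(f"{path}: schema v{version} unsupported")
        meta = json.loads(f.attrs["meta"])
        meta["schema_version"] = version
        data = {}
        for col in f.keys():
            v = f[col][...]
            if v.dtype.kind == "S":
                v = v.astype(str)
            data[col] = v
    return MappingTable(pd.DataFrame(data), meta)


def load_table(path):
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        return load_table_hdf5(path)
    return load_table_csv(path)


def save_trajectory_csv(traj, path) -> None:
    df = pd.DataFrame({
        "t_ms": traj.t_ms,
        "bx": traj.basepoint[:, 0], "by": traj.basepoint[:, 1],
        "bz": traj.basepoint[:, 2],
        "protraction_deg": traj.protraction_deg,
        "elevation_deg": traj.elevation_deg,
        "torsion_deg": traj.torsion_deg,
        "in_contact": traj.in_contact.astype(int),
        "cx": traj.contact_lab[:, 0], "cy": traj.contact_lab[:, 1],
        "cz": traj.contact_lab[:, 2],
        "side": traj.side,
    })
    _write_csv(df, path, TRAJ_KIND, traj.meta,
               "positions mm; angles deg; t ms (1 kHz)")


def load_trajectory_csv(path):
    from .whisking import WhiskTrajectory

    meta = _read_header(path, TRAJ_KIND)
    df = pd.read_csv(path, comment="#")
    in_c = df["in_contact"].to_numpy(bool)
    c_lab = df[["cx", "cy", "cz"]].to_numpy(float)
    base = df[["bx", "by", "bz"]].to_numpy(float)
    # whisker-frame contacts are derived data; rebuild from pose
    from .whisking import pose_rotation

    R = pose_rotation(df["protraction_deg"], df["elevation_deg"],
                      df["torsion_deg"])
    c_w = np.full((len(df), 3), np.nan)
    for t in np.flatnonzero(in_c):
        cw = R[t].T @ (c_lab[t] - base[t])
        c_w[t] = [np.linalg.norm(cw),
                  np.degrees(np.arctan2(cw[1], cw[0])),
                  np.degrees(np.arctan2(cw[2], np.hypot(cw[0], cw[1])))]
    side = df.get("side")
    side = (side.fillna("").to_numpy(dtype=object) if side is not None
            else np.array([""] * len(df), dtype=object))
    return WhiskTrajectory(
        t_ms=df["t_ms"].to_numpy(float), basepoint=base,
        protraction_deg=df["protraction_deg"].to_numpy(float),
        elevation_deg=df["elevation_deg"].to_numpy(float),
        torsion_deg=df["torsion_deg"].to_numpy(float),
        in_contact=in_c, contact_lab=c_lab, contact_whisker=c_w,
        side=side, meta=meta)


def save_reports_json(reports, path) -> None:
    """Uniqueness reports as JSON mirroring the All/ELD/CF/CB vocabulary."""
    payload = {"kind": "whiskmap-uniqueness-report",
               "schema_version": SUPPORTED_VERSION,
               "reports": [r.to_dict() for r in reports]}
    Path(path).write_text(json.dumps(payload, indent=2))


def save_sensitivity_json(binned, path) -> None:
    payload = {"kind": "whiskmap-sensitivity", "schema_version": SUPPORTED_VERSION}
    payload.update(binned.to_dict())
    Path(path).write_text(json.dumps(payload, indent=2))
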