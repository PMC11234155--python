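"""Readers and writers for wall meshes, WSS fields and regime specs.

Two interchangeable on-disk forms are supported for a (mesh, field) pair:

* VTK legacy polydata (ASCII): one ``VECTORS wss_<k>`` array per time step
  plus a ``region_id`` scalar; readable by ParaView and by any CFD
  post-processing stack.
* a CSV pair: ``<prefix>_nodes.csv`` (node schema) and ``<prefix>_wss.csv``
  in long format (node_id, t, tau_x, tau_y, tau_z).

Regime specs round-trip through YAML.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fields import WallMesh, WSSField
from .geometry import REGIMES
from .synthwss import RegimeSpec

_REGION_IDS = {name: i for i, name in enumerate(("",) + REGIMES)}
_ID_REGIONS = {i: name for name, i in _REGION_IDS.items()}


def write_vtk(path: str | Path, mesh: WallMesh, field: WSSField) -> None:
    """Write mesh + field as VTK legacy ASCII polydata (points only)."""
    path = Path(path)
    pos = mesh.positions_mm()
    n = mesh.n_nodes
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"bypassflow wss field period={field.period} "
                 f"n_steps={field.n_steps}\n")
        fh.write("ASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {n} float\n")
        np.savetxt(fh, pos, fmt="%.8g")
        fh.write(f"POINT_DATA {n}\n")
        fh.write("SCALARS region_id int 1\nLOOKUP_TABLE default\n")
        ids = np.array([_REGION_IDS.get(r, 0) for r in mesh.region])
        np.savetxt(fh, ids[:, None], fmt="%d")
        fh.write("NORMALS normals float\n")
        np.savetxt(fh, mesh.normals, fmt="%.8g")
        for k in range(field.n_steps):
            fh.write(f"VECTORS wss_{k:04d} float\n")
            np.savetxt(fh, field.values[:, k, :], fmt="%.8g")


def read_vtk(path: str | Path) -> tuple[WallMesh, WSSField]:
    """Read a (mesh, field) pair written by :func:`write_vtk`."""
    tokens: list[str] = []
    period, n_steps = 1.0, None
    with open(path) as fh:
        lines = fh.readlines()
    for part in lines[1].split():
        if part.startswith("period="):
            period = float(part.split("=")[1])
        if part.startswith("n_steps="):
            n_steps = int(part.split("=")[1])
    i = 0
    pos = normals = ids = None
    vectors: list[np.ndarray] = []
    n = 0

    def grab(start: int, count: int) -> tuple[np.ndarray, int]:
        vals: list[float] = []
        j = start
        while len(vals) < count:
            vals.extend(float(v) for v in lines[j].split())
            j += 1
        return np.array(vals), j

    while i < len(lines):
        line = lines[i]
        if line.startswith("POINTS"):
            n = int(line.split()[1])
            flat, i = grab(i + 1, 3 * n)
            pos = flat.reshape(n, 3)
            continue
        if line.startswith("SCALARS region_id"):
            flat, i = grab(i + 2, n)
            ids = flat.astype(int)
            continue
        if line.startswith("NORMALS"):
            flat, i = grab(i + 1, 3 * n)
            normals = flat.reshape(n, 3)
            continue
        if line.startswith("VECTORS"):
            flat, i = grab(i + 1, 3 * n)
            vectors.append(flat.reshape(n, 3))
            continue
        i += 1
    if pos is None or not vectors:
        raise ValueError(f"{path} is not a bypassflow VTK field file")
    if n_steps is not None and n_steps != len(vectors):
        raise ValueError("header n_steps does not match stored arrays")
    axial = pos[:, 0]
    azimuth = np.arctan2(pos[:, 2], pos[:, 1]) % (2 * np.pi)
    radius = float(np.median(np.hypot(pos[:, 1], pos[:, 2])))
    region = np.array([_ID_REGIONS.get(int(k), "") for k in ids])
    mesh = WallMesh(axial, azimuth, normals, region, radius)
    values = np.stack(vectors, axis=1)
    return mesh, WSSField(values, period=period)


def write_csv(prefix: str | Path, mesh: WallMesh, field: WSSField) -> None:
    """Write ``<prefix>_nodes.csv`` and long-format ``<prefix>_wss.csv``."""
    prefix = Path(prefix)
    nodes = pd.DataFrame({
        "node_id": np.arange(mesh.n_nodes),
        "axial_mm": mesh.axial_mm,
        "azimuth_rad": mesh.azimuth_rad,
        "nx": mesh.normals[:, 0],
        "ny": mesh.normals[:, 1],
        "nz": mesh.normals[:, 2],
        "region": mesh.region,
        "radius_mm": mesh.radius_mm,
        "period_s": field.period,
    })
    nodes.to_csv(f"{prefix}_nodes.csv", index=False)
    n, s, _ = field.values.shape
    long = pd.DataFrame({
        "node_id": np.repeat(np.arange(n), s),
        "t": np.tile(field.times, n),
        "tau_x": field.values[:, :, 0].ravel(),
        "tau_y": field.values[:, :, 1].ravel(),
        "tau_z": field.values[:, :, 2].ravel(),
    })
    long.to_csv(f"{prefix}_wss.csv", index=False)


def read_csv(prefix: str | Path) -> tuple[WallMesh, WSSField]:
    nodes = pd.read_csv(f"{prefix}_nodes.csv")
    long = pd.read_csv(f"{prefix}_wss.csv")
    mesh = WallMesh(
        nodes["axial_mm"].to_numpy(),
        nodes["azimuth_rad"].to_numpy(),
        nodes[["nx", "ny", "nz"]].to_numpy(),
        nodes["region"].fillna("").to_numpy(),
        float(nodes["radius_mm"].iloc[0]),
    )
    n = mesh.n_nodes
    long = long.sort_values(["node_id", "t"], kind="stable")
    s = long["t"].nunique()
    values = long[["tau_x", "tau_y", "tau_z"]].to_numpy().reshape(n, s, 3)
    return mesh, WSSField(values, period=float(nodes["period_s"].iloc[0]))


def specs_to_yaml(specs: dict[str, RegimeSpec], path: str | Path) -> None:
    data = {r: {"target_tawss": s.target_tawss, "target_osi": s.target_osi,
                "target_transwss": s.target_transwss, "seed": s.seed,
                "jitter": s.jitter}
            for r, s in specs.items()}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def specs_from_yaml(path: str | Path) -> dict[str, RegimeSpec]:
    data = yaml.safe_load(Path(path).read_text())
    return {r: RegimeSpec(regime=r, **kw) for r, kw in data.items()}
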