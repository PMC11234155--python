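"""Wall meshes and time-resolved wall-shear-stress fields.

A :class:`WallMesh` is a set of points on the (cylindrical) channel wall,
each with an axial position, azimuth and outward unit normal.  A
:class:`WSSField` stores one pump cycle of 3-component WSS vectors
(dyne/cm^2) per node on a uniform time grid; the last sample wraps to the
first, so cycle integrals use the trapezoidal rule with periodic closure,
which on a uniform grid reduces to the plain sample mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import ChannelGeometry, RegionWindows


@dataclass
class WallMesh:
    """Nodes on the channel wall.

    ``axial_mm`` uses the channel axis (origin under the branch
    intersection, positive toward the right Luer); ``azimuth_rad`` runs
    around the lumen; ``normals`` are outward radial unit 3-vectors in the
    global frame (x = axial, y/z = cross-section).
    """

    axial_mm: np.ndarray
    azimuth_rad: np.ndarray
    normals: np.ndarray
    region: np.ndarray
    radius_mm: float = 1.25

    def __post_init__(self) -> None:
        self.axial_mm = np.asarray(self.axial_mm, dtype=float)
        self.azimuth_rad = np.asarray(self.azimuth_rad, dtype=float)
        self.normals = np.asarray(self.normals, dtype=float)
        self.region = np.asarray(self.region)
        n = self.axial_mm.size
        if not (self.azimuth_rad.size == n and self.normals.shape == (n, 3)
                and self.region.size == n):
            raise ValueError("mesh arrays have inconsistent sizes")
        norms = np.linalg.norm(self.normals, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("normals must be unit vectors")

    @property
    def n_nodes(self) -> int:
        return self.axial_mm.size

    def positions_mm(self) -> np.ndarray:
        """Node coordinates (x axial, y/z cross-section) in mm."""
        x = self.axial_mm
        y = self.radius_mm * np.cos(self.azimuth_rad)
        z = self.radius_mm * np.sin(self.azimuth_rad)
        return np.column_stack([x, y, z])

    def axial_unit(self) -> np.ndarray:
        e = np.zeros((self.n_nodes, 3))
        e[:, 0] = 1.0
        return e

    def azimuthal_unit(self) -> np.ndarray:
        """In-plane tangent perpendicular to the axis at each node."""
        t = np.zeros((self.n_nodes, 3))
        t[:, 1] = -np.sin(self.azimuth_rad)
        t[:, 2] = np.cos(self.azimuth_rad)
        return t


def make_wall_mesh(windows: RegionWindows,
                   nodes_per_mm: float = 8.0,
                   n_circ: int = 8,
                   geometry: ChannelGeometry | None = None) -> WallMesh:
    """Sample wall nodes inside the four region windows.

    Axial samples are placed at cell centres (half-step inset from the
    half-open window edges) so DS and HS nodes never coincide at the shared
    boundary; each axial station carries ``n_circ`` azimuthal nodes.
    """
    geometry = geometry or ChannelGeometry()
    lo, hi = geometry.axial_extent
    ax_list, phi_list, reg_list = [], [], []
    phis = 2.0 * np.pi * np.arange(n_circ) / n_circ
    for name, (a, b) in windows.as_dict().items():
        if a < lo - 1e-9 or b > hi + 1e-9:
            raise ValueError(f"window {name} exceeds the channel extent")
        n_ax = max(2, int(round((b - a) * nodes_per_mm)))
        step = (b - a) / n_ax
        xs = a + step * (np.arange(n_ax) + 0.5)
        ax_list.append(np.repeat(xs, n_circ))
        phi_list.append(np.tile(phis, n_ax))
        reg_list.append(np.full(n_ax * n_circ, name, dtype="<U2"))
    axial = np.concatenate(ax_list)
    phi = np.concatenate(phi_list)
    region = np.concatenate(reg_list)
    normals = np.column_stack(
        [np.zeros_like(phi), np.cos(phi), np.sin(phi)])
    return WallMesh(axial, phi, normals, region, geometry.lumen_radius)


@dataclass
class WSSField:
    """One pump cycle of WSS vectors per node.

    ``values`` has shape (n_nodes, n_steps, 3) in dyne/cm^2 on a uniform
    time grid ``t_k = k * period / n_steps`` (the sample at ``t = period``
    equals the one at ``t = 0`` and is not stored).
    """

    values: np.ndarray
    period: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[2] != 3:
            raise ValueError("values must have shape (n_nodes, n_steps, 3)")
        if self.period <= 0:
            raise ValueError("period must be > 0")
        if not np.all(np.isfinite(self.values)):
            bad = np.unique(np.nonzero(~np.isfinite(self.values))[0])
            raise ValueError(f"non-finite WSS samples at nodes {bad[:10]}")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_steps(self) -> int:
        return self.values.shape[1]

    @property
    def time_step(self) -> float:
        return self.period / self.n_steps

    @property
    def times(self) -> np.ndarray:
        return self.time_step * np.arange(self.n_steps)
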