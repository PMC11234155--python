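"""Channel geometry, fluid constants and the axial sampling windows.

The culture channel is a straight 50 mm lumen (radius 1.25 mm) fed by a
branch meeting the cover at 60 deg.  The axial coordinate has its origin at
the *origin point* directly below the branch/cover intersection and runs
positive toward the right Luer.  Four 2-mm sampling windows partition the
wall into the hemodynamic regimes:

* ``ST`` - stagnation zone between the (plugged) left Luer and the branch,
* ``DS`` - disturbed-flow zone immediately left of the origin,
* ``HS`` - high-shear zone immediately right of the origin,
* ``PF`` - physiological (uniform pulsatile) flow further downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

REGIMES = ("ST", "DS", "HS", "PF")

#: dyne/cm^2 per Pa
DYNE_PER_CM2_PER_PA = 10.0


class GeometryError(ValueError):
    """Raised for invalid geometry or infeasible window layouts."""


@dataclass(frozen=True)
class ChannelGeometry:
    """Lumen geometry in millimetres.

    ``left_length``/``right_length`` are the channel lengths on either side
    of the axial origin (the point below the branch intersection); their sum
    is the 50 mm main channel by default.
    """

    lumen_radius: float = 1.25
    plate_radius: float = 2.25
    collagen_thickness: float = 1.0
    left_length: float = 29.45
    right_length: float = 20.55
    branch_angle: float = 60.0

    def __post_init__(self) -> None:
        for name in ("lumen_radius", "plate_radius", "collagen_thickness",
                     "left_length", "right_length"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be > 0")
        if not (0.0 < self.branch_angle <= 90.0):
            raise GeometryError("branch_angle must lie in (0, 90] degrees")

    @property
    def lumen_diameter_mm(self) -> float:
        return 2.0 * self.lumen_radius

    @property
    def total_length(self) -> float:
        return self.left_length + self.right_length

    @property
    def axial_extent(self) -> tuple[float, float]:
        """(min, max) axial coordinate in mm, origin at the origin point."""
        return (-self.left_length, self.right_length)


@dataclass(frozen=True)
class FlowParams:
    """Perfusion fluid and pump-cycle constants.

    Density and viscosity are those of culture medium thickened with
    xanthan gum; the pump cycle is 1 s.  Velocities are mean lumen speeds
    in cm/s at the two pump settings (pulsatile peak and the conditioning
    flow used to establish the monolayer).
    """

    density: float = 1020.0        # kg/m^3
    viscosity: float = 0.0035      # Pa*s
    period: float = 1.0            # s
    peak_velocity: float = 5.1     # cm/s
    conditioning_velocity: float = 0.17  # cm/s

    def __post_init__(self) -> None:
        if self.density <= 0 or self.viscosity <= 0 or self.period <= 0:
            raise GeometryError("density, viscosity and period must be > 0")


@dataclass(frozen=True)
class RegionWindows:
    """Half-open axial windows [start, end) in mm, one per regime."""

    ST: tuple[float, float]
    DS: tuple[float, float] = (-2.0, 0.0)
    HS: tuple[float, float] = (0.0, 2.0)
    PF: tuple[float, float] = (10.0, 12.0)

    def __post_init__(self) -> None:
        items = self.as_dict()
        for name, (a, b) in items.items():
            if not b > a:
                raise GeometryError(f"window {name} is empty or reversed")
        names = list(items)
        for i, ni in enumerate(names):
            for nj in names[i + 1:]:
                a0, a1 = items[ni]
                b0, b1 = items[nj]
                if max(a0, b0) < min(a1, b1):
                    raise GeometryError(f"windows {ni} and {nj} overlap")

    def as_dict(self) -> dict[str, tuple[float, float]]:
        return {r: getattr(self, r) for r in REGIMES}

    def label(self, axial_mm: np.ndarray) -> np.ndarray:
        """Region label per axial position; '' where no window covers it."""
        axial_mm = np.asarray(axial_mm, dtype=float)
        out = np.full(axial_mm.shape, "", dtype="<U2")
        for name, (a, b) in self.as_dict().items():
            out[(axial_mm >= a) & (axial_mm < b)] = name
        return out

    def width(self, name: str) -> float:
        a, b = getattr(self, name)
        return b - a


def mean_velocity(flow_rate_ml_min: float, radius_mm: float) -> float:
    """Mean lumen velocity in cm/s for a volumetric flow through a circular
    lumen.

    Parameters
    ----------
    flow_rate_ml_min : volumetric flow in mL/min (>= 0).
    radius_mm : lumen radius in mm (> 0).

    Returns
    -------
    Mean velocity ``Q / (pi r^2)`` in cm/s, unrounded.
    """
    if radius_mm <= 0:
        raise GeometryError("radius must be > 0")
    if flow_rate_ml_min < 0:
        raise GeometryError("flow_rate must be >= 0")
    q_cm3_s = flow_rate_ml_min / 60.0          # 1 mL = 1 cm^3
    area_cm2 = np.pi * (radius_mm / 10.0) ** 2
    return q_cm3_s / area_cm2


def reynolds_number(velocity_cm_s: float, diameter_mm: float,
                    params: FlowParams | None = None) -> float:
    """Reynolds number ``rho v D / mu`` for a lumen of the given diameter.

    Velocity in cm/s and diameter in mm are converted to SI internally.
    """
    params = params or FlowParams()
    if params.viscosity <= 0:
        raise GeometryError("viscosity must be > 0")
    if velocity_cm_s < 0 or diameter_mm <= 0:
        raise GeometryError("velocity must be >= 0 and diameter > 0")
    v = velocity_cm_s / 100.0
    d = diameter_mm / 1000.0
    return params.density * v * d / params.viscosity


def default_windows(geometry: ChannelGeometry | None = None,
                    st_offset_from_left_luer: float = 15.0,
                    pf_offset_from_origin: float = 10.0,
                    window_width: float = 2.0) -> RegionWindows:
    """The four default 2-mm sampling windows for a geometry.

    DS and HS flank the axial origin ([-2, 0) and [0, 2) mm).  The ST window
    starts ``st_offset_from_left_luer`` mm from the left Luer; the PF window
    starts ``pf_offset_from_origin`` mm downstream of the origin, in the
    middle of the physiological-flow zone.  Raises ``GeometryError`` when a
    window falls outside the channel or collides with DS/HS.
    """
    geometry = geometry or ChannelGeometry()
    w = window_width
    st_start = -geometry.left_length + st_offset_from_left_luer
    st = (st_start, st_start + w)
    pf = (pf_offset_from_origin, pf_offset_from_origin + w)
    ds = (-w, 0.0)
    hs = (0.0, w)
    if st[1] > ds[0]:
        raise GeometryError(
            "channel too short: ST window reaches the disturbed-flow zone")
    if st[0] < -geometry.left_length:
        raise GeometryError("ST window extends past the left Luer")
    if pf[1] > geometry.right_length:
        raise GeometryError("PF window extends past the right Luer")
    if pf[0] < hs[1]:
        raise GeometryError("PF window reaches the high-shear zone")
    return RegionWindows(ST=st, DS=ds, HS=hs, PF=pf)
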