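"""Hemodynamic wall metrics: TAWSS, OSI, RRT and TransWSS.

Definitions (tau = instantaneous WSS vector, T = cycle period, n = wall
normal):

* ``TAWSS  = (1/T) int_0^T |tau| dt``  (dyne/cm^2)
* ``OSI    = 0.5 (1 - |int tau dt| / int |tau| dt)``  in [0, 0.5]
* ``RRT    = 1 / ((1 - 2 OSI) TAWSS_Pa)``  (1/Pa; TAWSS converted to Pa)
* ``TransWSS = (1/T) int |tau . (n x e_mean)| dt`` where ``e_mean`` is the
  unit vector of the cycle-mean WSS (dyne/cm^2).

All cycle integrals use the trapezoidal rule with periodic closure, which
on the uniform grid of :class:`~bypassflow.fields.WSSField` is the plain
sample mean.  Degenerate nodes (zero cycle-mean direction, singular RRT)
are flagged rather than silently propagated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fields import WallMesh, WSSField
from .geometry import DYNE_PER_CM2_PER_PA, RegionWindows

#: |int tau dt| below this multiple of int |tau| dt leaves the mean
#: direction (and hence TransWSS) undefined.
MEAN_DIR_EPS = 1e-9
#: RRT denominator (Pa) below this is capped at RRT_CEILING and flagged.
RRT_EPS = 1e-12
RRT_CEILING = 1e12

METRIC_COLUMNS = ("tawss", "osi", "rrt", "log10_rrt", "transwss")


def _check_field(field: WSSField) -> None:
    if field.n_steps < 8:
        raise ValueError("need at least 8 time steps per cycle")


def _cycle_integrals(field: WSSField):
    """(int |tau| dt, int tau dt) per node, trapezoid with periodic wrap."""
    dt = field.time_step
    mag = np.linalg.norm(field.values, axis=2)
    return dt * mag.sum(axis=1), dt * field.values.sum(axis=1)


def tawss(field: WSSField, node: int | None = None) -> np.ndarray | float:
    """Time-averaged WSS magnitude per node (dyne/cm^2)."""
    _check_field(field)
    i_abs, _ = _cycle_integrals(field)
    out = i_abs / field.period
    return out if node is None else float(out[node])


def osi(field: WSSField, node: int | None = None) -> np.ndarray | float:
    """Oscillatory shear index per node; 0 for all-zero (degenerate) nodes."""
    _check_field(field)
    i_abs, i_vec = _cycle_integrals(field)
    mag_vec = np.linalg.norm(i_vec, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(i_abs > 0, mag_vec / np.where(i_abs > 0, i_abs, 1.0), 1.0)
    out = 0.5 * (1.0 - np.clip(ratio, 0.0, 1.0))
    return out if node is None else float(out[node])


def rrt(tawss_pa, osi_value, eps: float = RRT_EPS,
        ceiling: float = RRT_CEILING):
    """Relative residence time in 1/Pa from TAWSS (in Pa!) and OSI.

    Returns ``(rrt, capped)`` where ``capped`` marks nodes whose
    denominator fell below ``eps`` and were clipped to ``ceiling``.
    """
    tawss_pa = np.asarray(tawss_pa, dtype=float)
    osi_value = np.asarray(osi_value, dtype=float)
    if np.any(tawss_pa < 0) or np.any(osi_value < 0):
        raise ValueError("TAWSS and OSI must be nonnegative")
    denom = (1.0 - 2.0 * osi_value) * tawss_pa
    capped = denom < eps
    out = np.where(capped, ceiling, 1.0 / np.where(capped, 1.0, denom))
    if out.ndim == 0:
        return float(out), bool(capped)
    return out, capped


def transwss(field: WSSField, node: int | None = None,
             normals: np.ndarray | None = None,
             eps: float = MEAN_DIR_EPS):
    """Transverse WSS per node (dyne/cm^2).

    ``normals`` is (n_nodes, 3) of unit wall normals.  Returns
    ``(transwss, undefined)``; nodes whose cycle-mean WSS direction is
    degenerate (|int tau dt| < eps * max(1, int |tau| dt)) report 0 and are
    flagged ``undefined``.
    """
    _check_field(field)
    if normals is None:
        raise ValueError("transwss requires wall normals")
    normals = np.asarray(normals, dtype=float)
    if normals.ndim == 1:
        normals = np.broadcast_to(normals, (field.n_nodes, 3))
    if not np.allclose(np.linalg.norm(normals, axis=1), 1.0, atol=1e-6):
        raise ValueError("normals must be unit vectors")
    i_abs, i_vec = _cycle_integrals(field)
    mag_vec = np.linalg.norm(i_vec, axis=1)
    undefined = mag_vec < eps * np.maximum(1.0, i_abs)
    safe = np.where(undefined, 1.0, mag_vec)
    e_mean = i_vec / safe[:, None]
    p = np.cross(normals, e_mean)
    proj = np.abs(np.einsum("nts,ns->nt", field.values, p))
    out = proj.mean(axis=1)
    out[undefined] = 0.0
    if node is not None:
        return float(out[node]), bool(undefined[node])
    return out, undefined


@dataclass(frozen=True)
class RegimeThresholds:
    """Decision-list thresholds for the four-regime wall classification.

    Order of the decision list: stagnation (near-zero TAWSS), disturbed
    (oscillatory and below-median TAWSS), high-shear (top-percentile TAWSS
    with substantial transverse component), else physiological.
    """

    stagnant_tawss: float = 0.01       # dyne/cm^2
    disturbed_osi: float = 0.15
    high_shear_percentile: float = 75.0
    high_shear_transwss: float = 0.05  # dyne/cm^2

    def __post_init__(self) -> None:
        if not (0.0 < self.high_shear_percentile < 100.0):
            raise ValueError("high_shear_percentile must be in (0, 100)")
        if self.stagnant_tawss < 0 or self.high_shear_transwss < 0:
            raise ValueError("thresholds must be nonnegative")
        if not (0.0 <= self.disturbed_osi <= 0.5):
            raise ValueError("disturbed_osi must be in [0, 0.5]")


def compute_all(field: WSSField, mesh: WallMesh) -> pd.DataFrame:
    """Per-node metric table.

    Columns: node_id, axial_mm, azimuth, region, tawss, osi, rrt,
    log10_rrt, transwss, flag_mean_dir_undefined, flag_rrt_capped.
    TAWSS/TransWSS are in dyne/cm^2, RRT in 1/Pa.
    """
    if mesh.n_nodes != field.n_nodes:
        raise ValueError("mesh and field node counts differ")
    ta = tawss(field)
    os_ = osi(field)
    tw, undef = transwss(field, normals=mesh.normals)
    rr, capped = rrt(ta / DYNE_PER_CM2_PER_PA, os_)
    with np.errstate(divide="ignore"):
        log_rr = np.log10(rr)
    return pd.DataFrame({
        "node_id": np.arange(mesh.n_nodes),
        "axial_mm": mesh.axial_mm,
        "azimuth": mesh.azimuth_rad,
        "region": mesh.region,
        "tawss": ta,
        "osi": os_,
        "rrt": rr,
        "log10_rrt": log_rr,
        "transwss": tw,
        "flag_mean_dir_undefined": undef,
        "flag_rrt_capped": capped,
    })


def summarize_regions(metrics: pd.DataFrame,
                      windows: RegionWindows) -> pd.DataFrame:
    """Min/max/mean of each metric over the nodes of each region window.

    Mirrors the usual per-location hemodynamics table (rows = region x
    metric, columns = min, max, mean).
    """
    label = windows.label(metrics["axial_mm"].to_numpy())
    rows = []
    for name in windows.as_dict():
        sub = metrics.loc[label == name, list(METRIC_COLUMNS)]
        if sub.empty:
            raise ValueError(f"region {name} contains no nodes")
        for m in METRIC_COLUMNS:
            v = sub[m].to_numpy()
            rows.append({"region": name, "metric": m,
                         "min": v.min(), "max": v.max(), "mean": v.mean()})
    return pd.DataFrame(rows)


def classify_regimes(metrics: pd.DataFrame,
                     thresholds: RegimeThresholds | None = None) -> pd.Series:
    """Label every node ST / DS / HS / PF by a threshold decision list.

    ST: TAWSS below the stagnation threshold.  DS: OSI above the
    oscillatory threshold with TAWSS below the field median.  HS: TAWSS at
    or above the configured field percentile and TransWSS above the
    transverse threshold.  Everything else: PF.
    """
    th = thresholds or RegimeThresholds()
    ta = metrics["tawss"].to_numpy()
    os_ = metrics["osi"].to_numpy()
    tw = metrics["transwss"].to_numpy()
    median_ta = np.median(ta)
    high_ta = np.percentile(ta, th.high_shear_percentile)
    labels = np.full(ta.shape, "PF", dtype="<U2")
    is_st = ta < th.stagnant_tawss
    is_ds = ~is_st & (os_ > th.disturbed_osi) & (ta < median_ta)
    is_hs = (~is_st & ~is_ds & (ta >= high_ta)
             & (tw >= th.high_shear_transwss))
    labels[is_hs] = "HS"
    labels[is_ds] = "DS"
    labels[is_st] = "ST"
    return pd.Series(labels, index=metrics.index, name="regime")
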