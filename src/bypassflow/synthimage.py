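"""Synthetic endothelial-monolayer images with exact ground truth.

Confocal stand-in for a confluent HUVEC monolayer under flow.  Cells are
the regions of an anisotropic (Mahalanobis-metric) Voronoi tessellation of
Poisson-disk-sampled seed points: each cell carries its own orientation and
elongation, drawn from regime-specific distributions, so the tessellation
reproduces the per-regime morphology statistics (alignment spread,
axis-ratio / eccentricity medians) of endothelial monolayers exposed to
physiological, disturbed, high-shear or stagnant flow.

Three channels are rendered (order: nuclei, VE-cadherin, F-actin):

* nuclei - a filled ellipse per cell, scaled from the cell's own ellipse;
* VE-cadherin - the tessellation edges as ridges; stable adherens-junction
  (AJ) edges are continuous, focal adherens-junction (FAJ) edges are
  rendered discontinuous (0.5-1.5 um gaps);
* F-actin - AJ edges get parallel bands offset ~1 um to each side (no
  overlap with VE-cadherin); FAJ edges get short (2-4 um) perpendicular
  stubs crossing - and therefore overlapping - the VE-cadherin signal.

Poisson-Gaussian noise is added at a configurable peak SNR.  The ground
truth (per-cell ellipse parameters measured from the exact label map, and
per-junction-segment class and length) makes every downstream imaging
stage testable without real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi
from skimage import filters, measure

from .geometry import REGIMES
from .morphometry import alignment_angle, props_orientation_deg

CHANNEL_NAMES = ("nuclei", "vecadherin", "factin")

#: folded-normal sigma (deg) matching a target median alignment angle:
#: median |N(0, s)| = 0.6745 s
_MEDIAN_TO_SIGMA = 1.0 / 0.6745


class MonolayerError(ValueError):
    """Raised for infeasible monolayer specifications."""


@dataclass(frozen=True)
class MonolayerSpec:
    """Generative parameters for one synthetic monolayer image.

    ``alignment_spread`` is the folded-normal sigma (deg) of cell-axis
    deviations from the flow when ``orientation_distribution='aligned'``;
    with ``'uniform'`` orientations are uniform on [-90, 90) and the
    spread is ignored.  ``ratio_median``/``ratio_log_sigma`` parameterize
    the log-normal major/minor axis-ratio distribution.  ``snr`` is the
    peak signal-to-noise ratio of the Poisson-Gaussian noise model.
    """

    n_cells: int = 100
    image_size: tuple[int, int] | None = None
    pixel_size: float = 0.3            # um/px
    flow_direction: float = 0.0        # deg, axis of the x (column) direction
    orientation_distribution: str = "aligned"
    alignment_spread: float = 11.0     # deg
    ratio_median: float = 2.0
    ratio_log_sigma: float = 0.35
    faj_fraction: float = 0.2
    snr: float = 8.0
    seed: int = 0
    target_cell_area_um2: float = 1200.0
    nucleus_scale: float = 0.35

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise MonolayerError("n_cells must be >= 1")
        if not (0.0 <= self.faj_fraction <= 1.0):
            raise MonolayerError("faj_fraction must lie in [0, 1]")
        if self.pixel_size <= 0 or self.snr <= 0:
            raise MonolayerError("pixel_size and snr must be > 0")
        if self.orientation_distribution not in ("aligned", "uniform"):
            raise MonolayerError("orientation_distribution must be "
                                 "'aligned' or 'uniform'")


#: per-regime morphology calibration: (orientation distribution,
#: median alignment angle deg, axis-ratio median, axis-ratio log-sigma,
#: FAJ length fraction).  Medians follow the per-location monolayer
#: statistics of the bypass-flow channel.
_PRESETS = {
    "PF": ("aligned", 7.43, 2.46, 0.40, 0.10),
    "DS": ("uniform", 45.0, 1.50, 0.21, 0.35),
    "HS": ("aligned", 23.93, 1.66, 0.31, 0.30),
    "ST": ("aligned", 22.36, 2.27, 0.42, 0.10),
}


def regime_preset(regime: str, **overrides) -> MonolayerSpec:
    """Monolayer spec whose ground-truth population emulates a regime."""
    if regime not in REGIMES:
        raise MonolayerError(f"unknown regime {regime!r}")
    dist, med_align, ratio_med, ratio_sig, faj = _PRESETS[regime]
    spread = med_align * _MEDIAN_TO_SIGMA if dist == "aligned" else 45.0
    spec = MonolayerSpec(
        orientation_distribution=dist, alignment_spread=spread,
        ratio_median=ratio_med, ratio_log_sigma=ratio_sig,
        faj_fraction=faj)
    return replace(spec, **overrides) if overrides else spec


@dataclass
class GroundTruth:
    """Exact per-cell and per-junction-segment truth for one image."""

    cells: pd.DataFrame
    junctions: pd.DataFrame
    label_map: np.ndarray
    segment_pixels: dict[int, np.ndarray] = field(repr=False, default_factory=dict)
    spec: MonolayerSpec | None = None

    def faj_length_fraction(self) -> float:
        j = self.junctions
        total = j["length_um"].sum()
        if total == 0:
            return float("nan")
        return float(j.loc[j["cls"] == "FAJ", "length_um"].sum() / total)


# ---------------------------------------------------------------------------
# seed placement and tessellation
# ---------------------------------------------------------------------------

def _sample_centers(rng, n, shape, r0, units, ratios):
    """Anisotropic Poisson-disk dart throwing.

    A candidate is accepted when, for every placed point, the mean of the
    two cells' Mahalanobis distances (unit = own ellipse) exceeds ``c``.
    ``c`` relaxes deterministically if the target count cannot be placed.
    """
    h, w = shape
    a_all = r0 * np.sqrt(ratios)
    b_all = r0 / np.sqrt(ratios)
    c = 1.3
    while c >= 0.55:
        centers = np.empty((n, 2))
        attempts = 0
        i = 0
        while i < n and attempts < 60 * n:
            attempts += 1
            cand = rng.uniform((0, 0), (w, h))
            if i:
                delta = cand - centers[:i]                  # (m, 2) in (x, y)
                u = units[i]
                du = delta @ u
                dv = delta @ np.array([-u[1], u[0]])
                d_cand = np.hypot(du / a_all[i], dv / b_all[i])
                up = units[:i]
                dup = (delta * up).sum(axis=1)
                dvp = delta[:, 1] * up[:, 0] - delta[:, 0] * up[:, 1]
                d_place = np.hypot(dup / a_all[:i], dvp / b_all[:i])
                if np.min(0.5 * (d_cand + d_place)) < c:
                    continue
            centers[i] = cand
            i += 1
        if i == n:
            return centers
        c *= 0.93
    raise MonolayerError(
        f"cannot place {n} cells on a {shape} image at this density")


def _label_map(shape, centers, units, ratios, r0):
    """Anisotropic-Voronoi labels: argmin per-cell Mahalanobis distance."""
    h, w = shape
    n = centers.shape[0]
    a = (r0 * np.sqrt(ratios)).astype(np.float32)
    b = (r0 / np.sqrt(ratios)).astype(np.float32)
    ux = units[:, 0].astype(np.float32)
    uy = units[:, 1].astype(np.float32)
    cx = centers[:, 0].astype(np.float32)
    cy = centers[:, 1].astype(np.float32)
    labels = np.empty((h, w), dtype=np.int32)
    xs = np.arange(w, dtype=np.float32)
    chunk = max(1, int(4e6 // max(1, n * w)) or 1)
    for r_start in range(0, h, chunk):
        r_end = min(h, r_start + chunk)
        ys = np.arange(r_start, r_end, dtype=np.float32)
        dx = xs[None, :, None] - cx[None, None, :]
        dy = ys[:, None, None] - cy[None, None, :]
        du = dx * ux[None, None, :] + dy * uy[None, None, :]
        dv = -dx * uy[None, None, :] + dy * ux[None, None, :]
        d2 = (du / a[None, None, :]) ** 2 + (dv / b[None, None, :]) ** 2
        labels[r_start:r_end] = np.argmin(d2, axis=2) + 1
    return labels


def _junction_truth(labels, pixel_size, faj_fraction, rng,
                    min_px: int = 6):
    """Per-cell-pair boundary segments with class labels and lengths."""
    pair_pixels: dict[tuple[int, int], list[tuple[int, int]]] = {}

    def add(a_arr, b_arr, rr_a, cc_a, rr_b, cc_b):
        diff = a_arr != b_arr
        la, lb = a_arr[diff], b_arr[diff]
        ra, ca = rr_a[diff], cc_a[diff]
        rb, cb = rr_b[diff], cc_b[diff]
        lo = np.minimum(la, lb)
        hi = np.maximum(la, lb)
        for k in range(lo.size):
            key = (int(lo[k]), int(hi[k]))
            pair_pixels.setdefault(key, []).append((int(ra[k]), int(ca[k])))
            pair_pixels.setdefault(key, []).append((int(rb[k]), int(cb[k])))

    h, w = labels.shape
    rr, cc = np.mgrid[0:h, 0:w]
    add(labels[:, :-1], labels[:, 1:], rr[:, :-1], cc[:, :-1],
        rr[:, 1:], cc[:, 1:])
    add(labels[:-1, :], labels[1:, :], rr[:-1, :], cc[:-1, :],
        rr[1:, :], cc[1:, :])

    rows = []
    seg_pixels: dict[int, np.ndarray] = {}
    seg_id = 0
    for (a, b), pix in sorted(pair_pixels.items()):
        coords = np.unique(np.array(pix), axis=0)
        if coords.shape[0] < min_px:
            continue
        xy = coords[:, ::-1].astype(float)          # (x, y)
        center = xy.mean(axis=0)
        d = xy - center
        cov = d.T @ d / d.shape[0]
        evals, evecs = np.linalg.eigh(cov)
        axis = evecs[:, -1]
        tangent = np.degrees(np.arctan2(axis[1], axis[0]))
        tangent = ((tangent + 90.0) % 180.0) - 90.0
        proj = d @ axis
        length_um = (proj.max() - proj.min() + 1.0) * pixel_size
        rows.append({"segment_id": seg_id, "cell_a": a, "cell_b": b,
                     "cls": "AJ", "length_um": length_um,
                     "tangent_deg": tangent, "n_px": coords.shape[0]})
        seg_pixels[seg_id] = coords
        seg_id += 1
    table = pd.DataFrame(rows)
    if len(table):
        # randomized length-stratified class assignment: a shuffled prefix
        # of segments is marked FAJ until the FAJ length fraction matches
        # the target, so the realized ground-truth fraction tracks
        # faj_fraction to within about one segment length
        total = table["length_um"].sum()
        target = faj_fraction * total
        acc = 0.0
        for idx in rng.permutation(len(table)):
            length = table.at[idx, "length_um"]
            if target - acc > 0.5 * length:
                table.at[idx, "cls"] = "FAJ"
                acc += length
    return table, seg_pixels


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _segment_frames(truth_junctions, seg_pixels):
    for row in truth_junctions.itertuples():
        coords = seg_pixels[row.segment_id]
        th = np.radians(row.tangent_deg)
        axis = np.array([np.cos(th), np.sin(th)])       # (x, y)
        normal = np.array([-axis[1], axis[0]])
        xy = coords[:, ::-1].astype(float)
        proj = (xy - xy.mean(axis=0)) @ axis
        yield row, coords, xy, axis, normal, proj


def _put(img, rr, cc, value=1.0):
    h, w = img.shape
    keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
    img[rr[keep], cc[keep]] = np.maximum(img[rr[keep], cc[keep]], value)


def _render_channels(shape, truth_cells, truth_junctions, seg_pixels,
                     spec, rng):
    px = spec.pixel_size
    vecad = np.zeros(shape, dtype=float)
    actin = np.zeros(shape, dtype=float)
    nuclei = np.zeros(shape, dtype=float)

    dash_px = 2.5 / px
    gap_px = 1.0 / px
    stub_step_px = 1.2 / px
    off_px = int(round(1.0 / px))

    for row, coords, xy, axis, normal, proj in _segment_frames(
            truth_junctions, seg_pixels):
        rr_, cc_ = coords[:, 0], coords[:, 1]
        if row.cls == "AJ":
            _put(vecad, rr_, cc_)
            for sgn in (-1, 1):
                _put(actin, rr_ + sgn * int(round(off_px * normal[1])),
                     cc_ + sgn * int(round(off_px * normal[0])), 0.8)
        else:
            s = proj - proj.min()
            keep = (s % (dash_px + gap_px)) < dash_px
            _put(vecad, rr_[keep], cc_[keep])
            # perpendicular stubs crossing the junction
            n_stubs = max(1, int((proj.max() - proj.min()) / stub_step_px))
            anchors = np.linspace(proj.min(), proj.max(), n_stubs + 2)[1:-1]
            for anc in anchors:
                k = np.argmin(np.abs(proj - anc))
                half = 0.5 * rng.uniform(2.0, 4.0) / px
                ts = np.arange(-half, half, 0.5)
                sx = xy[k, 0] + ts * normal[0]
                sy = xy[k, 1] + ts * normal[1]
                _put(actin, np.round(sy).astype(int),
                     np.round(sx).astype(int), 1.0)

    h, w = shape
    rr_grid, cc_grid = np.mgrid[0:h, 0:w]
    for cell in truth_cells.itertuples():
        a = 0.5 * cell.major_um / px * spec.nucleus_scale
        b = 0.5 * cell.minor_um / px * spec.nucleus_scale
        a, b = max(a, 2.0), max(b, 1.5)
        th = np.radians(cell.orientation_deg)
        cy = cell.centroid_y_um / px
        cx = cell.centroid_x_um / px
        r0 = max(0, int(cy - a - 2))
        r1 = min(h, int(cy + a + 3))
        c0 = max(0, int(cx - a - 2))
        c1 = min(w, int(cx + a + 3))
        if r1 <= r0 or c1 <= c0:
            continue
        dx = cc_grid[r0:r1, c0:c1] - cx
        dy = rr_grid[r0:r1, c0:c1] - cy
        u = dx * np.cos(th) + dy * np.sin(th)
        v = -dx * np.sin(th) + dy * np.cos(th)
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        level = 0.8 + 0.2 * rng.random()
        patch = nuclei[r0:r1, c0:c1]
        patch[inside] = np.maximum(patch[inside], level)

    vecad = filters.gaussian(vecad, 0.7, preserve_range=True)
    actin = filters.gaussian(actin, 0.8, preserve_range=True)
    nuclei = filters.gaussian(nuclei, 1.0, preserve_range=True)
    return np.stack([nuclei, vecad, actin])


def _add_noise(image, snr, rng):
    gain = snr ** 2
    noisy = rng.poisson(np.clip(image, 0, None) * gain) / gain
    noisy = noisy + rng.normal(0.0, 0.3 / snr, size=image.shape)
    return np.clip(noisy, 0.0, None).astype(np.float32)


# ---------------------------------------------------------------------------
# top level
# ---------------------------------------------------------------------------

def generate_monolayer(spec: MonolayerSpec, render: bool = True
                       ) -> tuple[np.ndarray | None, GroundTruth]:
    """Render a seeded 3-channel monolayer image with exact ground truth.

    Returns ``(image, truth)`` where ``image`` is float32 of shape
    (3, H, W) in channel order (nuclei, VE-cadherin, F-actin) and
    ``truth`` carries the label map, per-cell ellipse statistics measured
    from it, and the per-junction-segment classes and lengths.  The same
    spec (same seed) always returns bit-identical output.  With
    ``render=False`` only the ground truth is built (image is None) —
    useful for large-population statistics of the generator itself.
    """
    rng = np.random.default_rng(spec.seed)
    px = spec.pixel_size
    area_px = spec.target_cell_area_um2 / px ** 2
    if spec.image_size is None:
        side = int(np.ceil(np.sqrt(spec.n_cells * area_px)))
        shape = (side, side)
    else:
        shape = tuple(spec.image_size)
    if shape[0] * shape[1] / spec.n_cells < 100:
        raise MonolayerError(
            f"{spec.n_cells} cells do not fit a {shape} image "
            "(fewer than 100 px per cell)")
    r0 = np.sqrt(shape[0] * shape[1] / spec.n_cells / np.pi)

    if spec.orientation_distribution == "uniform":
        # stratified sampling: one draw per stratum of [-90, 90), shuffled;
        # the realized population matches the uniform target closely even
        # at moderate n (population medians are calibration targets here)
        strata = rng.permutation(spec.n_cells)
        theta = -90.0 + 180.0 * (strata + rng.random(spec.n_cells)) \
            / spec.n_cells
    else:
        dev = spec.alignment_spread * rng.standard_normal(spec.n_cells)
        theta = ((spec.flow_direction + dev + 90.0) % 180.0) - 90.0
    ratios = np.clip(
        spec.ratio_median * np.exp(
            spec.ratio_log_sigma * rng.standard_normal(spec.n_cells)),
        1.02, 6.0)
    th = np.radians(theta)
    units = np.column_stack([np.cos(th), np.sin(th)])   # (x, y)

    centers = _sample_centers(rng, spec.n_cells, shape, r0, units, ratios)
    labels = _label_map(shape, centers, units, ratios, r0)

    h, w = shape
    rows = []
    for p in measure.regionprops(labels):
        r0b, c0b, r1b, c1b = p.bbox
        major = p.axis_major_length * px
        minor = max(p.axis_minor_length * px, 1e-9)
        orient = props_orientation_deg(p)
        rows.append({
            "cell_id": p.label,
            "centroid_x_um": p.centroid[1] * px,
            "centroid_y_um": p.centroid[0] * px,
            "orientation_deg": orient,
            "major_um": major, "minor_um": minor,
            "axis_ratio": major / minor,
            "eccentricity": np.sqrt(max(0.0, 1.0 - (minor / major) ** 2)),
            "area_um2": p.area * px ** 2,
            "alignment_deg": float(
                alignment_angle(orient, spec.flow_direction)),
            "on_border": r0b == 0 or c0b == 0 or r1b == h or c1b == w,
        })
    cells = pd.DataFrame(rows)

    junctions, seg_pixels = _junction_truth(
        labels, px, spec.faj_fraction, rng)
    truth = GroundTruth(cells, junctions, labels, seg_pixels, spec)
    if not render:
        return None, truth
    clean = _render_channels(shape, cells, junctions, seg_pixels, spec, rng)
    image = _add_noise(clean + 0.03, spec.snr, rng)
    return image, truth


def write_monolayer(path_prefix: str | Path, image: np.ndarray,
                    truth: GroundTruth) -> None:
    """Write the image as a multi-page TIFF plus ground-truth CSVs."""
    prefix = Path(path_prefix)
    tifffile.imwrite(f"{prefix}.tif", image, photometric="minisblack")
    truth.cells.to_csv(f"{prefix}_cells.csv", index=False)
    truth.junctions.to_csv(f"{prefix}_junctions.csv", index=False)
    tifffile.imwrite(f"{prefix}_labels.tif", truth.label_map.astype(np.int32))


def read_monolayer_image(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)
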