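"""Single-cell morphometry: nuclei/cell segmentation and feature profiles.

The segmentation chain mirrors a standard high-content-screening setup:
adaptive local thresholding of the nuclei channel, watershed splitting of
touching nuclei, a lower size filter for debris, then seeded growing of
cell territories guided by the VE-cadherin boundary signal (an
intensity-weighted Voronoi partition).  Per-cell shape follows the
second-central-moment ellipse; the profile extractor adds intensity,
texture, moment, radial-distribution and colocalization families per
channel in a fixed, documented order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats
from skimage import feature, filters, measure, morphology, segmentation


# ---------------------------------------------------------------------------
# orientation conventions
# ---------------------------------------------------------------------------

def props_orientation_deg(props) -> float:
    """Major-axis angle in degrees CCW from the image x-axis (columns),
    in [-90, 90).

    skimage's ``regionprops.orientation`` measures from the row axis; this
    converts to the flow-frame convention used throughout the package
    (flow runs along +x).
    """
    deg = 90.0 - np.degrees(props.orientation)
    return ((deg + 90.0) % 180.0) - 90.0


def alignment_angle(orientation_deg, flow_direction_deg=0.0):
    """Absolute acute angle (deg, in [0, 90]) between an axis and the flow.

    Axes are direction-less: 120 deg and -60 deg denote the same axis, so
    the difference is folded modulo 180 and reflected into [0, 90].
    """
    d = np.abs(np.asarray(orientation_deg, dtype=float)
               - np.asarray(flow_direction_deg, dtype=float)) % 180.0
    return np.minimum(d, 180.0 - d)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

@dataclass
class LabelMap:
    """Nuclei and cell label rasters sharing one pixel grid."""

    nuclei: np.ndarray
    cells: np.ndarray
    pixel_size: float  # um/px


def segment_nuclei(nuclei_channel: np.ndarray, pixel_size: float,
                   min_size_um2: float = 30.0,
                   block_size: int = 51,
                   offset: float = 0.15,
                   smooth_sigma: float = 1.0,
                   h_um: float = 0.6,
                   distance_sigma: float = 2.0) -> np.ndarray:
    """Label individual nuclei in a single-channel image.

    Adaptive (gaussian-mean) local threshold -> connected components ->
    watershed split of touching nuclei on the distance transform with
    h-maxima seed suppression -> removal of components below
    ``min_size_um2``.  A blank image yields zero labels.

    ``offset`` is relative to the robust intensity maximum (99.9th
    percentile), so the default suits any linear intensity scale.
    """
    img = np.asarray(nuclei_channel, dtype=float)
    if img.ndim != 2:
        raise ValueError("nuclei channel must be a single 2D image")
    top = np.percentile(img, 99.9)
    if top <= 0 or np.ptp(img) == 0:
        return np.zeros(img.shape, dtype=np.int32)
    smoothed = filters.gaussian(img, smooth_sigma, preserve_range=True)
    local = filters.threshold_local(smoothed, block_size=block_size,
                                    method="gaussian")
    mask = smoothed > (local + offset * top)
    mask = ndi.binary_fill_holes(mask)
    min_px = max(1, int(round(min_size_um2 / pixel_size ** 2)))
    mask = morphology.remove_small_objects(mask, max_size=min_px - 1)
    if not mask.any():
        return np.zeros(img.shape, dtype=np.int32)
    # smoothing the distance map suppresses spurious ridge maxima from
    # boundary noise before h-maxima seed selection
    dist = filters.gaussian(ndi.distance_transform_edt(mask),
                            distance_sigma, preserve_range=True)
    h_px = max(1.0, h_um / pixel_size)
    peaks = morphology.h_maxima(dist, h_px)
    markers, _ = ndi.label(peaks)
    labels = segmentation.watershed(-dist, markers, mask=mask)
    sizes = np.bincount(labels.ravel())
    small = np.nonzero(sizes < min_px)[0]
    if small.size:
        labels[np.isin(labels, small)] = 0
    labels, _, _ = segmentation.relabel_sequential(labels)
    return labels.astype(np.int32)


def segment_cells(nuclei_labels: np.ndarray,
                  vecadherin_channel: np.ndarray,
                  smooth_sigma: float = 1.0,
                  geometric_weight: float = 0.05) -> np.ndarray:
    """Grow cell territories from nuclei seeds against VE-cadherin ridges.

    Watershed on a cost image combining the (normalized) VE-cadherin
    intensity with a small seed-distance term; boundaries therefore lock
    onto junction ridges where signal exists and fall back to the
    geometric Voronoi partition of the seeds where the channel is flat.
    Every pixel is assigned to exactly one cell; zero nuclei give zero
    cells.
    """
    nuclei_labels = np.asarray(nuclei_labels)
    if nuclei_labels.max() == 0:
        return np.zeros(nuclei_labels.shape, dtype=np.int32)
    img = np.asarray(vecadherin_channel, dtype=float)
    smoothed = filters.gaussian(img, smooth_sigma, preserve_range=True)
    rng_ = np.ptp(smoothed)
    ridge = (smoothed - smoothed.min()) / rng_ if rng_ > 0 \
        else np.zeros_like(smoothed)
    dist = ndi.distance_transform_edt(nuclei_labels == 0)
    dmax = dist.max()
    geo = dist / dmax if dmax > 0 else dist
    cost = ridge + geometric_weight * geo
    return segmentation.watershed(cost, nuclei_labels).astype(np.int32)


def match_labels(candidate: np.ndarray, reference: np.ndarray) -> dict[int, int]:
    """Map each candidate label to the reference label of maximum overlap."""
    cand = candidate.ravel()
    ref = reference.ravel()
    keep = cand > 0
    pairs, counts = np.unique(
        np.stack([cand[keep], ref[keep]]), axis=1, return_counts=True)
    best: dict[int, tuple[int, int]] = {}
    for (c, r), n in zip(pairs.T, counts):
        if c not in best or n > best[c][1]:
            best[c] = (int(r), int(n))
    return {c: r for c, (r, _) in best.items()}


# ---------------------------------------------------------------------------
# shape
# ---------------------------------------------------------------------------

def shape_features(cell_labels: np.ndarray, pixel_size: float,
                   flow_direction: float = 0.0,
                   min_area_px: int = 9) -> pd.DataFrame:
    """Second-moment ellipse statistics per labelled cell.

    Columns: cell_id, centroid_x_um, centroid_y_um, orientation_deg,
    major_um, minor_um, axis_ratio, eccentricity, area_um2,
    alignment_deg, on_border, excluded.  Cells below ``min_area_px`` are
    flagged ``excluded`` (degenerate moments).
    """
    labels = np.asarray(cell_labels)
    h, w = labels.shape
    rows = []
    for p in measure.regionprops(labels):
        r0, c0, r1, c1 = p.bbox
        border = r0 == 0 or c0 == 0 or r1 == h or c1 == w
        excluded = p.area < min_area_px or p.axis_major_length <= 0
        if excluded:
            orient, major, minor, ratio, ecc, align = (np.nan,) * 6
        else:
            orient = props_orientation_deg(p)
            major = p.axis_major_length * pixel_size
            minor = p.axis_minor_length * pixel_size
            minor = max(minor, 1e-9)
            ratio = major / minor
            ecc = np.sqrt(max(0.0, 1.0 - (minor / major) ** 2))
            align = float(alignment_angle(orient, flow_direction))
        rows.append({
            "cell_id": p.label,
            "centroid_x_um": p.centroid[1] * pixel_size,
            "centroid_y_um": p.centroid[0] * pixel_size,
            "orientation_deg": orient,
            "major_um": major, "minor_um": minor,
            "axis_ratio": ratio, "eccentricity": ecc,
            "area_um2": p.area * pixel_size ** 2,
            "alignment_deg": align,
            "on_border": border, "excluded": excluded,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# profile extraction
# ---------------------------------------------------------------------------

_INTENSITY_STATS = ("mean", "std", "median", "mad", "q10", "q25", "q75",
                    "q90", "min", "max", "integrated", "mass_displacement")
_TEXTURE_PROPS = ("contrast", "dissimilarity", "homogeneity", "ASM",
                  "energy", "correlation")
_TEXTURE_DISTANCES = (2, 5)
_N_RINGS = 4
_MOMENT_NAMES = tuple(f"nu{i}{j}" for i, j in
                      ((1, 1), (2, 0), (0, 2), (2, 1), (1, 2), (3, 0), (0, 3))) \
    + tuple(f"hu{k}" for k in range(7))
_SHAPE_FEATURES = ("area_um2", "perimeter_um", "major_um", "minor_um",
                   "axis_ratio", "eccentricity", "orientation_deg",
                   "alignment_deg", "solidity", "extent")


def profile_feature_names(channel_names: tuple[str, ...]) -> list[str]:
    """The fixed feature ordering of :func:`extract_profile`."""
    names: list[str] = []
    for ch in channel_names:
        names += [f"intensity_{ch}_{s}" for s in _INTENSITY_STATS]
    for ch in channel_names:
        for d in _TEXTURE_DISTANCES:
            names += [f"texture_{ch}_d{d}_{p}" for p in _TEXTURE_PROPS]
    for ch in channel_names:
        names += [f"moment_{ch}_{m}" for m in _MOMENT_NAMES]
    for ch in channel_names:
        names += [f"radial_{ch}_ring{k}" for k in range(_N_RINGS)]
    for i, a in enumerate(channel_names):
        for b in channel_names[i + 1:]:
            names += [f"coloc_{a}_{b}_corr", f"coloc_{a}_{b}_m1",
                      f"coloc_{a}_{b}_m2"]
    names += [f"shape_{s}" for s in _SHAPE_FEATURES]
    return names


def _intensity_block(sub: np.ndarray, mask: np.ndarray,
                     pixel_size: float) -> list[float]:
    v = sub[mask]
    q10, q25, q75, q90 = np.percentile(v, [10, 25, 75, 90])
    total = v.sum()
    rr, cc = np.nonzero(mask)
    geo = np.array([rr.mean(), cc.mean()])
    if total > 0:
        com = np.array([np.average(rr, weights=v), np.average(cc, weights=v)])
        md = float(np.linalg.norm(com - geo)) * pixel_size
    else:
        md = 0.0
    return [v.mean(), v.std(), float(np.median(v)),
            float(np.median(np.abs(v - np.median(v)))),
            q10, q25, q75, q90, v.min(), v.max(), total, md]


def _texture_block(sub: np.ndarray, mask: np.ndarray) -> list[float]:
    v = sub.copy()
    inside = v[mask]
    lo, hi = inside.min(), inside.max()
    if hi <= lo:
        quant = np.zeros(v.shape, dtype=np.uint8)
    else:
        quant = np.clip(((v - lo) / (hi - lo) * 15), 0, 15).astype(np.uint8)
    quant = np.where(mask, quant + 1, 0).astype(np.uint8)  # 0 = outside
    out: list[float] = []
    for d in _TEXTURE_DISTANCES:
        glcm = feature.graycomatrix(
            quant, distances=[d], angles=[0, np.pi / 2], levels=17,
            symmetric=True, normed=False)
        glcm = glcm[1:, 1:, :, :].astype(float)  # drop outside-mask level
        s = glcm.sum(axis=(0, 1), keepdims=True)
        glcm = glcm / np.where(s > 0, s, 1.0)
        for pname in _TEXTURE_PROPS:
            vals = feature.graycoprops(glcm, pname)
            out.append(float(np.nanmean(vals)))
    return out


def _moment_block(sub: np.ndarray, mask: np.ndarray) -> list[float]:
    img = np.where(mask, sub, 0.0)
    nu = measure.moments_normalized(measure.moments_central(img, order=3))
    vals = [nu[i, j] for i, j in
            ((1, 1), (2, 0), (0, 2), (2, 1), (1, 2), (3, 0), (0, 3))]
    hu = measure.moments_hu(nu)
    return [float(x) for x in vals] + [float(x) for x in hu]


def _radial_block(sub: np.ndarray, mask: np.ndarray) -> list[float]:
    rr, cc = np.nonzero(mask)
    center = np.array([rr.mean(), cc.mean()])
    r = np.hypot(rr - center[0], cc - center[1])
    rmax = r.max()
    if rmax == 0:
        return [1.0] + [0.0] * (_N_RINGS - 1)
    bins = np.minimum((r / rmax * _N_RINGS).astype(int), _N_RINGS - 1)
    v = sub[mask]
    total = v.sum()
    if total <= 0:
        return [0.0] * _N_RINGS
    return [float(v[bins == k].sum() / total) for k in range(_N_RINGS)]


def _coloc_block(sub_a: np.ndarray, sub_b: np.ndarray,
                 mask: np.ndarray) -> list[float]:
    a, b = sub_a[mask], sub_b[mask]
    if a.std() == 0 or b.std() == 0:
        corr = 1.0 if np.array_equal(a, b) else 0.0
    else:
        corr = float(np.corrcoef(a, b)[0, 1])
    ta = a > (a.mean() + a.std())
    tb = b > (b.mean() + b.std())
    m1 = float(a[tb].sum() / a.sum()) if a.sum() > 0 else 0.0
    m2 = float(b[ta].sum() / b.sum()) if b.sum() > 0 else 0.0
    return [corr, m1, m2]


def extract_profile(cell_labels: np.ndarray, channels: np.ndarray,
                    pixel_size: float, flow_direction: float = 0.0,
                    channel_names: tuple[str, ...] = ("nuclei", "vecadherin",
                                                      "factin"),
                    exclude_border: bool = True) -> pd.DataFrame:
    """Per-cell feature vectors across all channels.

    ``channels`` has shape (n_channels, H, W).  Families, in order:
    intensity, co-occurrence texture, normalized central + Hu moments,
    radial distribution, pairwise colocalization, shape.  Border-touching
    cells are flagged and (by default) excluded.
    """
    channels = np.asarray(channels, dtype=float)
    if channels.ndim != 3 or channels.shape[0] < 2:
        raise ValueError("channels must be (n_channels >= 2, H, W)")
    if channels.shape[0] != len(channel_names):
        raise ValueError("channel_names must match the number of channels")
    labels = np.asarray(cell_labels)
    shapes = shape_features(labels, pixel_size, flow_direction)
    shapes = shapes.set_index("cell_id")
    names = profile_feature_names(channel_names)
    records, ids, borders = [], [], []
    for p in measure.regionprops(labels):
        cid = p.label
        srow = shapes.loc[cid]
        if bool(srow["excluded"]):
            continue
        if exclude_border and bool(srow["on_border"]):
            continue
        sl = p.slice
        mask = labels[sl] == cid
        subs = [channels[k][sl] for k in range(channels.shape[0])]
        feats: list[float] = []
        for sub in subs:
            feats += _intensity_block(sub, mask, pixel_size)
        for sub in subs:
            feats += _texture_block(sub, mask)
        for sub in subs:
            feats += _moment_block(sub, mask)
        for sub in subs:
            feats += _radial_block(sub, mask)
        for i in range(len(subs)):
            for j in range(i + 1, len(subs)):
                feats += _coloc_block(subs[i], subs[j], mask)
        feats += [srow["area_um2"], p.perimeter * pixel_size,
                  srow["major_um"], srow["minor_um"], srow["axis_ratio"],
                  srow["eccentricity"], srow["orientation_deg"],
                  srow["alignment_deg"], p.solidity, p.extent]
        records.append(feats)
        ids.append(cid)
        borders.append(bool(srow["on_border"]))
    out = pd.DataFrame(records, columns=names)
    out.insert(0, "cell_id", ids)
    out.insert(1, "on_border", borders)
    return out


# ---------------------------------------------------------------------------
# group summaries
# ---------------------------------------------------------------------------

def summarize_groups(records: pd.DataFrame, group_col: str,
                     value_cols: list[str] | None = None) -> pd.DataFrame:
    """Median/IQR, mean +- SEM per group plus one-way ANOVA per metric.

    Requires >= 2 groups with >= 2 observations each.  Metrics with zero
    variance in every group are flagged ``degenerate`` (ANOVA undefined).
    """
    groups = records[group_col].unique()
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    counts = records.groupby(group_col).size()
    if (counts < 2).any():
        raise ValueError("every group needs at least two observations")
    if value_cols is None:
        value_cols = [c for c in records.columns
                      if c != group_col and
                      pd.api.types.is_numeric_dtype(records[c])]
    rows = []
    for col in value_cols:
        samples = [records.loc[records[group_col] == g, col].dropna().to_numpy()
                   for g in groups]
        degenerate = all(np.ptp(s) == 0 for s in samples if s.size)
        if degenerate:
            f = p = np.nan
        else:
            f, p = stats.f_oneway(*samples)
        for g, s in zip(groups, samples):
            q1, med, q3 = np.percentile(s, [25, 50, 75]) if s.size else (np.nan,) * 3
            rows.append({
                "metric": col, "group": g, "n": s.size,
                "median": med, "q1": q1, "q3": q3,
                "mean": s.mean() if s.size else np.nan,
                "sem": stats.sem(s) if s.size > 1 else np.nan,
                "anova_F": f, "anova_p": p, "degenerate": degenerate,
            })
    return pd.DataFrame(rows)
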