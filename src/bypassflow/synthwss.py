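"""Synthetic pulsatile WSS fields emulating the four wall regimes.

A CFD stand-in: each regime is represented by a biased axial sinusoid plus
an independent transverse sinusoid,

    tau_axial(t)      = A (b + sin(2 pi t / T))
    tau_transverse(t) = C sin(2 pi t / T)

whose cycle statistics have closed forms.  With ``m(b)`` the cycle mean of
``|b + sin|``,

    m(b)       = (2/pi) (b asin(b) + sqrt(1 - b^2))   for 0 <= b <= 1
               = b                                     for b >= 1
    TAWSS      = A m(b)            (transverse-free)
    OSI        = 0.5 (1 - b/m(b))  (transverse-free)
    TransWSS   = 2 C / pi          (exact, any A, b)

Calibration inverts these maps (scalar root-finding on b, then a small
least-squares polish when the transverse component perturbs TAWSS/OSI) so
a generated field hits requested regime targets.  The stagnation regime is
simply a target TAWSS of ~1e-6 dyne/cm^2 with a strongly reversing bias, so
OSI stays high while the magnitude is negligible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize

from .fields import WallMesh, WSSField
from .geometry import REGIMES, RegionWindows

#: bias ratio used to represent a strictly unidirectional (OSI = 0) waveform
_UNIDIRECTIONAL_BIAS = 1e6


class CalibrationError(ValueError):
    """Raised when regime targets cannot be met by the waveform family."""


@dataclass(frozen=True)
class RegimeSpec:
    """Target cycle statistics for one wall regime."""

    regime: str
    target_tawss: float          # dyne/cm^2
    target_osi: float            # [0, 0.5)
    target_transwss: float = 0.0  # dyne/cm^2
    seed: int = 0
    jitter: float = 0.02         # relative node-to-node amplitude noise

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.target_tawss < 0:
            raise CalibrationError("target_tawss must be >= 0")
        if not (0.0 <= self.target_osi < 0.5):
            raise CalibrationError("target_osi must lie in [0, 0.5)")
        if self.target_transwss < 0:
            raise CalibrationError("target_transwss must be >= 0")
        if self.target_transwss > self.target_tawss:
            raise CalibrationError("target_transwss cannot exceed target_tawss")
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")


@dataclass(frozen=True)
class WaveformParams:
    """Calibrated waveform family parameters for one regime."""

    amplitude: float            # A, dyne/cm^2
    bias_ratio: float           # b
    transverse_amplitude: float  # C, dyne/cm^2


def default_regime_specs(base_seed: int = 0) -> dict[str, RegimeSpec]:
    """Per-regime targets: TAWSS/OSI from the per-location wall statistics
    of the bypass channel (region means), TransWSS chosen consistent with
    its definition (nonnegative, <= TAWSS) and preserving the qualitative
    ordering HS ~ high, DS moderate, PF low, ST ~ 0."""
    rows = {
        "ST": (1.5e-6, 0.42, 0.0),
        "DS": (0.11, 0.20, 0.04),
        "HS": (0.35, 0.08, 0.10),
        "PF": (0.32, 0.06, 0.02),
    }
    return {
        r: RegimeSpec(r, *rows[r], seed=base_seed + i)
        for i, r in enumerate(REGIMES)
    }


def mean_abs_biased_sin(bias_ratio: float) -> float:
    """Closed-form cycle mean of |b + sin(theta)|."""
    b = float(bias_ratio)
    if b < 0:
        raise ValueError("bias_ratio must be >= 0")
    if b >= 1.0:
        return b
    return (2.0 / np.pi) * (b * np.arcsin(b) + np.sqrt(1.0 - b * b))


def osi_of_bias(bias_ratio: float) -> float:
    """Closed-form OSI of the biased sinusoid (transverse-free)."""
    b = float(bias_ratio)
    if b >= 1.0:
        return 0.0
    return 0.5 * (1.0 - b / mean_abs_biased_sin(b))


def biased_sinusoid_waveform(amplitude: float, bias_ratio: float,
                             period: float = 1.0,
                             n_steps: int = 1000) -> WSSField:
    """Single-node axial waveform ``A (b + sin(2 pi t / T)) x_hat``."""
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if n_steps < 8:
        raise ValueError("need at least 8 time steps")
    t = np.arange(n_steps) / n_steps
    ax = waveform_components(
        WaveformParams(amplitude, bias_ratio, 0.0), t)[0]
    values = np.zeros((1, n_steps, 3))
    values[0, :, 0] = ax
    return WSSField(values, period=period)


def waveform_components(params: WaveformParams,
                        t_frac: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(axial, transverse) waveform samples at cycle fractions ``t_frac``.

    A bias ratio at or above the unidirectional sentinel collapses the
    sinusoidal term, giving a constant axial stress ``A * b`` -> emitted as
    ``amplitude`` directly.
    """
    theta = 2.0 * np.pi * np.asarray(t_frac, dtype=float)
    if params.bias_ratio >= _UNIDIRECTIONAL_BIAS:
        ax = np.full(theta.shape, params.amplitude * params.bias_ratio)
    else:
        ax = params.amplitude * (params.bias_ratio + np.sin(theta))
    tr = params.transverse_amplitude * np.sin(theta)
    return ax, tr


def _achieved_metrics(params: WaveformParams, n_steps: int = 2048):
    """(TAWSS, OSI, TransWSS) of the emitted waveform by quadrature."""
    t = np.arange(n_steps) / n_steps
    ax, tr = waveform_components(params, t)
    mag = np.hypot(ax, tr)
    i_abs = mag.mean()
    mean_ax, mean_tr = ax.mean(), tr.mean()
    mean_mag = np.hypot(mean_ax, mean_tr)
    ta = i_abs
    os_ = 0.5 * (1.0 - mean_mag / i_abs) if i_abs > 0 else 0.0
    if mean_mag < 1e-12 * max(1.0, i_abs):
        tw = 0.0
    else:
        e = np.array([mean_ax, mean_tr]) / mean_mag
        perp = np.array([-e[1], e[0]])
        tw = np.abs(ax * perp[0] + tr * perp[1]).mean()
    return ta, os_, tw


def calibrate_waveform(spec: RegimeSpec) -> WaveformParams:
    """Waveform parameters whose cycle statistics hit the spec targets.

    The transverse amplitude follows exactly from the target TransWSS
    (C = pi * TransWSS / 2).  The bias ratio is found by scalar
    root-finding on the closed-form OSI map; when the transverse term is
    non-negligible a bounded least-squares polish on (A, b) restores the
    TAWSS/OSI targets of the combined waveform.
    """
    c = 0.5 * np.pi * spec.target_transwss
    if spec.target_tawss == 0.0:
        if spec.target_transwss > 0:
            raise CalibrationError("cannot have TransWSS > 0 with zero TAWSS")
        return WaveformParams(0.0, 0.0, 0.0)
    if spec.target_osi == 0.0:
        if spec.target_transwss > 0:
            raise CalibrationError(
                "a transverse component forces OSI > 0; target_osi=0 is "
                "infeasible with target_transwss > 0")
        # constant unidirectional stress
        return WaveformParams(spec.target_tawss / _UNIDIRECTIONAL_BIAS,
                              _UNIDIRECTIONAL_BIAS, 0.0)
    # transverse-free closed-form solution
    b0 = optimize.brentq(lambda b: osi_of_bias(b) - spec.target_osi,
                         1e-12, 1.0 - 1e-12, xtol=1e-12)
    a0 = spec.target_tawss / mean_abs_biased_sin(b0)
    params = WaveformParams(a0, b0, c)
    if c > 1e-12 * spec.target_tawss:
        def resid(x):
            a, b = x
            ta, os_, _ = _achieved_metrics(WaveformParams(a, b, c))
            return [(ta - spec.target_tawss) / spec.target_tawss,
                    (os_ - spec.target_osi) / max(spec.target_osi, 0.05)]

        sol = optimize.least_squares(
            resid, [a0, b0], bounds=([1e-30, 0.0], [np.inf, 10.0]),
            xtol=1e-14, ftol=1e-14)
        params = WaveformParams(sol.x[0], sol.x[1], c)
        ta, os_, tw = _achieved_metrics(params)
        if (abs(ta - spec.target_tawss) > 0.02 * spec.target_tawss
                or abs(os_ - spec.target_osi) > 0.02 * max(spec.target_osi, 1e-6)
                or abs(tw - spec.target_transwss)
                > 0.05 * max(spec.target_transwss, 1e-12)):
            raise CalibrationError(
                f"targets {spec} infeasible for the waveform family "
                f"(achieved TAWSS={ta:.4g}, OSI={os_:.4g}, TransWSS={tw:.4g})")
    return params


def _region_weights(axial_mm: np.ndarray, windows: RegionWindows,
                    transition_halfwidth: float) -> dict[str, np.ndarray]:
    """Cosine-ramp blending weight per region for every axial position.

    Inside a window (beyond the transition band) the weight is 1; it ramps
    to 0 across ``+-transition_halfwidth`` around each window edge.
    Adjacent windows (DS|HS) therefore cross-fade smoothly; isolated
    windows keep weight 1 after normalization.
    """
    h = transition_halfwidth
    weights = {}
    for name, (a, b) in windows.as_dict().items():
        if h <= 0:
            w = ((axial_mm >= a) & (axial_mm < b)).astype(float)
        else:
            rise = np.clip((axial_mm - (a - h)) / (2 * h), 0.0, 1.0)
            fall = np.clip(((b + h) - axial_mm) / (2 * h), 0.0, 1.0)
            edge = np.minimum(rise, fall)
            w = 0.5 * (1.0 - np.cos(np.pi * edge))
        weights[name] = w
    return weights


def generate_field(mesh: WallMesh, windows: RegionWindows,
                   specs: dict[str, RegimeSpec] | None = None,
                   n_steps: int = 200, period: float = 1.0,
                   transition_halfwidth: float = 0.2) -> WSSField:
    """Per-node WSS time series from calibrated regime waveforms.

    Each node receives the cosine-ramp-blended mix of the calibrated
    regime waveforms covering its axial position, expressed in the node's
    tangent frame (axial unit vector and azimuthal unit vector), with a
    deterministic per-node multiplicative jitter drawn from each spec's
    seed.  Raises if any node is covered by no window or transition band.
    """
    specs = specs or default_regime_specs()
    t = np.arange(n_steps) / n_steps
    weights = _region_weights(mesh.axial_mm, windows, transition_halfwidth)
    total = np.sum([weights[r] for r in specs], axis=0)
    if np.any(total <= 1e-12):
        bad = np.nonzero(total <= 1e-12)[0]
        raise ValueError(
            f"{bad.size} mesh nodes (e.g. axial={mesh.axial_mm[bad[:3]]}) lie "
            "outside every window and transition band")
    e_ax = mesh.axial_unit()
    e_az = mesh.azimuthal_unit()
    values = np.zeros((mesh.n_nodes, n_steps, 3))
    for name, spec in specs.items():
        params = calibrate_waveform(spec)
        ax, tr = waveform_components(params, t)
        rng = np.random.default_rng(spec.seed)
        factor = 1.0 + spec.jitter * rng.standard_normal(mesh.n_nodes)
        factor = np.clip(factor, 0.5, 1.5)
        w = weights[name] / total * factor
        values += w[:, None, None] * (
            e_ax[:, None, :] * ax[None, :, None]
            + e_az[:, None, :] * tr[None, :, None])
    return WSSField(values, period=period)
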