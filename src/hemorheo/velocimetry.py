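"""Micro-PIV: displacement estimation and shear-rate extraction.

Velocities are estimated from fluorescent tracer-particle image pairs by
multi-pass cross-correlation: a coarse pass with 64×64 px interrogation
windows predicts the displacement, and a refining 32×32 px pass with 50%
overlap measures it.  Windows are weighted anisotropically (4:1 in the
streamwise x-direction, matching unidirectional microchannel flow),
peaks are located to subpixel precision by a three-point Gaussian fit,
and outliers are flagged by the normalized median test and replaced by
local medians.

Image convention: ``frame[row, col]`` with the flow along columns (x)
and the transverse/wall-normal direction along rows (y).  Displacement
is measured in pixels from frame A to frame B; conversion to mm/s uses
``u = d_px · α_c / dt`` with α_c in μm/px and dt in ms.

The N repeated velocity fields of one measurement are averaged in time
and then along the streamwise direction into a single transverse
profile; the per-point temporal spread is reported as
``RMS = sqrt[(N·Σu_i² − (Σu_i)²) / (N(N−1))]``, the sample standard
deviation over the N fields.  The shear rate is the slope of that
profile over the central part of the blood layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.signal import fftconvolve

from .errors import ConfigurationError, DetectionError, DomainError, FitError

__all__ = [
    "ParticleImagePair", "VectorField", "VelocityProfile", "ShearEstimate",
    "remove_background", "piv_multipass", "displacement_to_velocity",
    "velocity_rms", "temporal_average_profile", "detect_blood_layer",
    "estimate_shear_rate", "select_dt_ms",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ParticleImagePair:
    """One tracer-image pair with its acquisition metadata."""

    frame_a: np.ndarray
    frame_b: np.ndarray
    dt_ms: float
    pixel_scale_um: float

    def __post_init__(self):
        self.frame_a = np.asarray(self.frame_a, dtype=float)
        self.frame_b = np.asarray(self.frame_b, dtype=float)
        if self.frame_a.shape != self.frame_b.shape:
            raise DomainError("frame pair must share a shape")
        if not self.dt_ms > 0:
            raise DomainError("inter-frame time dt must be positive")
        if not self.pixel_scale_um > 0:
            raise DomainError("pixel scale must be positive")


@dataclass
class VectorField:
    """Displacement (or velocity) vectors on the interrogation grid.

    ``x``/``y`` are window-center coordinates in pixels; ``u``/``v`` are
    the streamwise/transverse components.  ``valid`` marks vectors that
    passed validation; ``replaced`` marks those substituted by a local
    median.
    """

    x: np.ndarray
    y: np.ndarray
    u: np.ndarray
    v: np.ndarray
    valid: np.ndarray
    replaced: np.ndarray
    units: str = "px"

    def scaled(self, factor: float, units: str) -> "VectorField":
        return VectorField(self.x, self.y, self.u * factor, self.v * factor,
                           self.valid, self.replaced, units=units)


@dataclass
class VelocityProfile:
    """Transverse profile after temporal and streamwise averaging."""

    y_um: np.ndarray
    u_mm_s: np.ndarray
    rms_mm_s: np.ndarray
    n_fields: int


@dataclass(frozen=True)
class ShearEstimate:
    """Shear rate from the linear part of a velocity profile."""

    shear_rate_s1: float
    fit_intercept_mm_s: float
    fit_window_um: Tuple[float, float]
    r_squared: float
    n_points: int


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def remove_background(stack: Sequence[np.ndarray],
                      method: str = "min") -> list:
    """Subtract a static per-pixel background from every frame.

    ``min`` (default) uses the per-pixel temporal minimum — robust for
    sparse bright tracers on a static background; ``mean`` subtracts the
    temporal mean.  Output is clipped at zero.  The result is invariant
    to adding any constant to all frames.
    """
    frames = [np.asarray(f, dtype=float) for f in stack]
    if len(frames) < 2:
        raise ConfigurationError(
            "background removal needs at least 2 frames")
    shape = frames[0].shape
    if any(f.shape != shape for f in frames):
        raise DomainError("all frames must share a shape")
    arr = np.stack(frames)
    bg = arr.min(axis=0) if method == "min" else arr.mean(axis=0)
    if method not in ("min", "mean"):
        raise ConfigurationError(f"unknown background method {method!r}")
    return [np.clip(f - bg, 0.0, None) for f in frames]


# ---------------------------------------------------------------------------
# cross-correlation engine
# ---------------------------------------------------------------------------


def _window_weight(size: int, x_weight_ratio: float) -> np.ndarray:
    """Anisotropic Gaussian window weight, elongated x:y = ratio:1."""
    sig_x = size / 4.0
    sig_y = sig_x / x_weight_ratio
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    return np.exp(-0.5 * (((xx - c) / sig_x) ** 2 + ((yy - c) / sig_y) ** 2))


def _subpixel(corr: np.ndarray, pi: int, pj: int) -> Tuple[float, float]:
    """Three-point Gaussian peak interpolation (parabolic fallback)."""

    def interp(cm, c0, cp):
        if cm > 0 and c0 > 0 and cp > 0:
            denom = 2.0 * (np.log(cm) - 2.0 * np.log(c0) + np.log(cp))
            if denom < 0:
                return (np.log(cm) - np.log(cp)) / denom
        denom = 2.0 * (cm - 2.0 * c0 + cp)
        return (cm - cp) / denom if denom != 0 else 0.0

    di = interp(corr[pi - 1, pj], corr[pi, pj], corr[pi + 1, pj])
    dj = interp(corr[pi, pj - 1], corr[pi, pj], corr[pi, pj + 1])
    return di, dj


def _correlate_window(win_a: np.ndarray, win_b: np.ndarray,
                      weight: np.ndarray) -> Optional[Tuple[float, float]]:
    """Displacement (dy, dx) of pattern B relative to A, or None if flat."""
    a = win_a - win_a.mean()
    b = win_b - win_b.mean()
    if not (np.any(a) and np.any(b)):
        return None
    a *= weight
    b *= weight
    corr = fftconvolve(b, a[::-1, ::-1], mode="full")
    pi, pj = np.unravel_index(np.argmax(corr), corr.shape)
    if pi in (0, corr.shape[0] - 1) or pj in (0, corr.shape[1] - 1):
        return None
    di, dj = _subpixel(corr, pi, pj)
    n = win_a.shape[0]
    return (pi - (n - 1) + di, pj - (n - 1) + dj)


def _median_validate(u: np.ndarray, v: np.ndarray, valid: np.ndarray,
                     threshold: float = 2.0, eps: float = 0.1):
    """Normalized median test (3×3 neighborhood); returns updated masks.

    Outliers and invalid vectors are replaced by the local median of
    their valid neighbors; replacements are reported, never silent.
    """
    ny, nx = u.shape
    out = valid.copy()
    for comp in (u, v):
        resid = np.zeros_like(comp)
        for i in range(ny):
            for j in range(nx):
                neigh = []
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        if di == dj == 0:
                            continue
                        ii, jj = i + di, j + dj
                        if 0 <= ii < ny and 0 <= jj < nx and valid[ii, jj]:
                            neigh.append(comp[ii, jj])
                if not neigh:
                    continue
                med = np.median(neigh)
                rm = np.median(np.abs(np.asarray(neigh) - med))
                resid[i, j] = abs(comp[i, j] - med) / (rm + eps)
        out &= resid <= threshold

    replaced = np.zeros_like(out)
    u_f, v_f = u.copy(), v.copy()
    for i in range(ny):
        for j in range(nx):
            if out[i, j]:
                continue
            neigh_u, neigh_v = [], []
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    ii, jj = i + di, j + dj
                    if (di or dj) and 0 <= ii < ny and 0 <= jj < nx \
                            and out[ii, jj]:
                        neigh_u.append(u[ii, jj])
                        neigh_v.append(v[ii, jj])
            if neigh_u:
                u_f[i, j] = np.median(neigh_u)
                v_f[i, j] = np.median(neigh_v)
                replaced[i, j] = True
    return u_f, v_f, out | replaced, replaced


def _single_pass(frame_a, frame_b, window, step, weight, predictor=None,
                 grid=None):
    """One correlation pass; predictor (int px) shifts the B windows."""
    h, w = frame_a.shape
    rows = np.arange(0, h - window + 1, step)
    cols = np.arange(0, w - window + 1, step)
    u = np.zeros((rows.size, cols.size))
    v = np.zeros_like(u)
    valid = np.zeros(u.shape, dtype=bool)
    for a_i, r in enumerate(rows):
        for a_j, c in enumerate(cols):
            py = px = 0
            if predictor is not None:
                py, px = predictor(r + window / 2.0, c + window / 2.0)
            rb, cb = r + py, c + px
            if not (0 <= rb <= h - window and 0 <= cb <= w - window):
                continue
            res = _correlate_window(frame_a[r:r + window, c:c + window],
                                    frame_b[rb:rb + window, cb:cb + window],
                                    weight)
            if res is None:
                continue
            dv, du = res
            if abs(du) > window / 2.0 or abs(dv) > window / 2.0:
                continue
            v[a_i, a_j] = dv + py
            u[a_i, a_j] = du + px
            valid[a_i, a_j] = True
    x = cols + (window - 1) / 2.0
    y = rows + (window - 1) / 2.0
    return x, y, u, v, valid


def piv_multipass(pair: ParticleImagePair, initial_window: int = 64,
                  final_window: int = 32, overlap_fraction: float = 0.5,
                  x_weight_ratio: float = 4.0,
                  validation_threshold: float = 2.0) -> VectorField:
    """Two-pass cross-correlation PIV on one image pair (displacement, px).

    The coarse pass (``initial_window``) provides an integer predictor
    that shifts the second-pass interrogation windows
    (``final_window``, 50% overlap by default) in frame B, keeping the
    residual displacement small so the three-point subpixel fit is
    accurate.  Invalid vectors are flagged, median-replaced and marked.
    """
    fa, fb = pair.frame_a, pair.frame_b
    if min(fa.shape) < initial_window:
        raise DomainError(
            f"frames {fa.shape} smaller than the initial window "
            f"{initial_window}")
    step1 = int(initial_window * (1 - overlap_fraction))
    step2 = int(final_window * (1 - overlap_fraction))
    w1 = _window_weight(initial_window, x_weight_ratio)
    w2 = _window_weight(final_window, x_weight_ratio)

    x1, y1, u1, v1, val1 = _single_pass(fa, fb, initial_window, step1, w1)
    u1, v1, val1, _ = _median_validate(u1, v1, val1, validation_threshold)

    def predictor(yc, xc):
        i = int(np.argmin(np.abs(y1 - yc)))
        j = int(np.argmin(np.abs(x1 - xc)))
        return int(round(v1[i, j])), int(round(u1[i, j]))

    x2, y2, u2, v2, val2 = _single_pass(fa, fb, final_window, step2, w2,
                                        predictor=predictor)
    u2, v2, valid, replaced = _median_validate(u2, v2, val2,
                                               validation_threshold)
    return VectorField(x=x2, y=y2, u=u2, v=v2, valid=valid,
                       replaced=replaced, units="px")


def displacement_to_velocity(fieldv: VectorField, dt_ms: float,
                             pixel_scale_um: float) -> VectorField:
    """Scale pixel displacements to mm/s: u·α_c/dt (μm/ms ≡ mm/s)."""
    if not dt_ms > 0:
        raise DomainError("dt must be positive")
    if not pixel_scale_um > 0:
        raise DomainError("pixel scale must be positive")
    return fieldv.scaled(pixel_scale_um / dt_ms, units="mm/s")


def select_dt_ms(max_speed_mm_s: float, pixel_scale_um: float,
                 target_displacement_px: float = 8.0) -> float:
    """dt that puts the fastest tracer displacement at the target (6–10 px)."""
    if not max_speed_mm_s > 0:
        raise DomainError("maximum speed must be positive")
    return target_displacement_px * pixel_scale_um / max_speed_mm_s


# ---------------------------------------------------------------------------
# averaging and shear extraction
# ---------------------------------------------------------------------------


def velocity_rms(samples: np.ndarray, axis: int = 0) -> np.ndarray:
    """RMS fluctuation sqrt[(N·Σu² − (Σu)²)/(N(N−1))] over N repeats."""
    u = np.asarray(samples, dtype=float)
    N = u.shape[axis]
    if N < 2:
        raise DomainError("RMS needs at least 2 repeated fields")
    s1 = np.sum(u, axis=axis)
    s2 = np.sum(u ** 2, axis=axis)
    var = np.clip((N * s2 - s1 ** 2) / (N * (N - 1.0)), 0.0, None)
    return np.sqrt(var)


def temporal_average_profile(fields: Sequence[VectorField],
                             pixel_scale_um: Optional[float] = None
                             ) -> VelocityProfile:
    """Average N velocity fields in time, then streamwise, into a profile.

    Per grid point: temporal mean and RMS over the N fields; both are
    then averaged along the streamwise (x) direction, giving one value
    per transverse position.  Fields must share the grid and units.
    """
    if len(fields) < 2:
        raise DomainError("need at least 2 fields to average")
    shape = fields[0].u.shape
    if any(f.u.shape != shape for f in fields):
        raise DomainError("fields must share the interrogation grid")
    stack = np.stack([f.u for f in fields])          # (N, ny, nx)
    mean_uv = stack.mean(axis=0)
    rms_uv = velocity_rms(stack, axis=0)
    u_prof = mean_uv.mean(axis=1)
    rms_prof = rms_uv.mean(axis=1)
    y = fields[0].y.astype(float)
    scale = pixel_scale_um if pixel_scale_um is not None else 1.0
    return VelocityProfile(y_um=y * scale, u_mm_s=u_prof,
                           rms_mm_s=rms_prof, n_fields=len(fields))


def detect_blood_layer(y_positions: np.ndarray, tracer_density: np.ndarray,
                       threshold_fraction: float = 0.5
                       ) -> Tuple[float, float]:
    """Locate the tracer-laden (blood) layer from a transverse density profile.

    Returns the maximal contiguous interval where the density is at
    least ``threshold_fraction`` of its maximum, with the edges refined
    by linear interpolation of the threshold crossing.
    """
    y = np.asarray(y_positions, dtype=float)
    d = np.asarray(tracer_density, dtype=float)
    if y.shape != d.shape or y.size < 2:
        raise DomainError("positions and densities must be matching vectors")
    peak = d.max()
    if peak <= 0:
        raise DetectionError("tracer density profile is empty")
    thr = threshold_fraction * peak
    above = d >= thr
    if not above.any():
        raise DetectionError("no position reaches the density threshold")
    # maximal contiguous run of above-threshold samples
    runs = []
    start = None
    for i, a in enumerate(above):
        if a and start is None:
            start = i
        elif not a and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, above.size - 1))
    i0, i1 = max(runs, key=lambda r: r[1] - r[0])

    y_lo, y_hi = y[i0], y[i1]
    if i0 > 0 and d[i0 - 1] != d[i0]:
        y_lo = np.interp(thr, [d[i0 - 1], d[i0]], [y[i0 - 1], y[i0]])
    if i1 < y.size - 1 and d[i1 + 1] != d[i1]:
        y_hi = np.interp(thr, [d[i1 + 1], d[i1]], [y[i1 + 1], y[i1]])
    return float(y_lo), float(y_hi)


def estimate_shear_rate(profile: VelocityProfile,
                        layer: Tuple[float, float],
                        inner_fraction: float = 0.8) -> ShearEstimate:
    """Shear rate as the slope of u(y) over the central part of the layer.

    An ordinary least-squares line is fitted over the central
    ``inner_fraction`` of ``layer`` and the slope converted from
    (mm/s)/μm to 1/s (×1000).
    """
    y_lo, y_hi = sorted(layer)
    center = 0.5 * (y_lo + y_hi)
    half = 0.5 * inner_fraction * (y_hi - y_lo)
    lo, hi = center - half, center + half
    sel = (profile.y_um >= lo) & (profile.y_um <= hi) & np.isfinite(
        profile.u_mm_s)
    if np.count_nonzero(sel) < 3:
        raise FitError(
            f"need at least 3 profile points inside [{lo:.1f}, {hi:.1f}] μm, "
            f"got {np.count_nonzero(sel)}")
    y = profile.y_um[sel]
    u = profile.u_mm_s[sel]
    slope, intercept = np.polyfit(y, u, 1)
    pred = slope * y + intercept
    ss_tot = np.sum((u - u.mean()) ** 2)
    r2 = 1.0 - np.sum((u - pred) ** 2) / ss_tot if ss_tot > 0 else 1.0
    return ShearEstimate(shear_rate_s1=float(slope * 1000.0),
                         fit_intercept_mm_s=float(intercept),
                         fit_window_um=(float(lo), float(hi)),
                         r_squared=float(r2),
                         n_points=int(np.count_nonzero(sel)))
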