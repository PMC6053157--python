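"""Ground-truth generators for every input the pipeline consumes.

The generators replace the laboratory recordings (which were never
deposited) with physically constructed stand-ins:

* :func:`gen_coflow_experiment` — a two-fluid duct velocity field whose
  interface position follows from the pump flow-rate ratio and the
  imposed viscosity ratio, exactly as in the bench experiment;
* :func:`gen_particle_frames` — fluorescent-tracer image pairs advected
  by the mid-plane velocity profile of such a field (tracers seeded in
  the blood stream, as in the experiments);
* :func:`gen_aggregate_frames` — bright-field frames with dark
  rouleau-chain / cluster / disk objects under non-uniform illumination;
* :func:`gen_viscosity_samples` — (shear rate, viscosity) curves drawn
  from a power-law or Carreau truth model with optional multiplicative
  noise.

Every generator is fully determined by its ``seed`` and returns a
machine-readable truth record alongside the data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import scipy.ndimage as ndi

from . import coflow
from .aggregates import DEFAULT_SIZE_BINS_UM2, FrameStack, classify_size_bins
from .errors import ConfigurationError, DomainError, HemorheoError
from .reference import CarreauParams, PowerLawParams
from .rheology import ViscosityCurve, carreau_viscosity, power_law_viscosity
from .units import CP_TO_PA_S
from .velocimetry import ParticleImagePair, select_dt_ms

__all__ = [
    "ExperimentTruth", "ParticleTruth", "AggregateSceneTruth",
    "gen_coflow_experiment", "gen_particle_frames", "gen_aggregate_frames",
    "gen_viscosity_samples",
]


# ---------------------------------------------------------------------------
# co-flow experiments
# ---------------------------------------------------------------------------


@dataclass
class ExperimentTruth:
    """Everything the synthetic co-flow experiment knows about itself."""

    geometry: coflow.ChannelGeometry
    mu_reference_pa_s: float
    mu_test_pa_s: float
    q_reference_ul_hr: float
    q_test_ul_hr: float
    interface_Y: float
    mid_plane_shear_rate_s1: float
    pressure_gradient_pa_m: float
    seed: int

    def to_json(self, path) -> None:
        d = dataclasses.asdict(self)
        d["geometry"] = dataclasses.asdict(self.geometry)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)


def _blood_layer_shear(field: coflow.DuctField,
                       inner_fraction: float = 0.8) -> float:
    """OLS slope (1/s) of the mid-plane profile over the central part of
    the blood layer — the same definition the velocimetry stage uses."""
    y, u = field.mid_plane_profile()
    w = field.geometry.width_um
    y_lo = -0.5 * w
    y_hi = field.geometry.interface_Y * w
    c = 0.5 * (y_lo + y_hi)
    half = 0.5 * inner_fraction * (y_hi - y_lo)
    sel = (y >= c - half) & (y <= c + half)
    slope = np.polyfit(y[sel], u[sel], 1)[0]   # mm/s per μm
    return float(slope * 1000.0)


def gen_coflow_experiment(mu_ratio: float, q_ratio: float = 4.0,
                          width_um: float = 110.0, depth_um: float = 60.0,
                          mu_reference_cp: float = 1.0,
                          q_test_ul_hr: float = 10.0,
                          grid_shape: Tuple[int, int] = (201, 201),
                          seed: int = 0
                          ) -> Tuple[ExperimentTruth, coflow.DuctField]:
    """Build a fully consistent synthetic viscometry experiment.

    The pumps fix Q1/Q2 = ``q_ratio`` (reference over test; the bench
    default runs the reference at four times the blood flow rate) and
    the physics then fixes the interface position; the finite-difference
    field is scaled so the test stream carries ``q_test_ul_hr``.
    """
    if not (mu_ratio > 0 and q_ratio > 0):
        raise DomainError("viscosity and flow ratios must be positive")
    beta = depth_um / width_um
    Y = coflow.solve_interface_position(q_ratio, mu_ratio, beta)
    geometry = coflow.ChannelGeometry(width_um, depth_um, Y)
    mu_ref = mu_reference_cp * CP_TO_PA_S
    mu_test = mu_ratio * mu_ref

    field = coflow.fd_velocity_field(geometry, mu_ref, mu_test,
                                     pressure_gradient_pa_m=1e5,
                                     grid_shape=grid_shape)
    scale = q_test_ul_hr / field.flow_rate_2_ul_hr
    field.axial_velocity_mm_s *= scale
    field.flow_rate_1_ul_hr *= scale
    field.flow_rate_2_ul_hr *= scale
    field.pressure_gradient_pa_m *= scale

    truth = ExperimentTruth(
        geometry=geometry,
        mu_reference_pa_s=mu_ref,
        mu_test_pa_s=mu_test,
        q_reference_ul_hr=field.flow_rate_1_ul_hr,
        q_test_ul_hr=field.flow_rate_2_ul_hr,
        interface_Y=Y,
        mid_plane_shear_rate_s1=_blood_layer_shear(field),
        pressure_gradient_pa_m=field.pressure_gradient_pa_m,
        seed=seed,
    )
    return truth, field


# ---------------------------------------------------------------------------
# tracer-particle image pairs
# ---------------------------------------------------------------------------


@dataclass
class ParticleTruth:
    """Ground truth for a generated tracer-image sequence."""

    row_y_um: np.ndarray          # transverse position of each pixel row
    row_u_mm_s: np.ndarray        # mid-plane velocity at each row
    row_displacement_px: np.ndarray
    dt_ms: float
    pixel_scale_um: float
    blood_rows: Tuple[int, int]   # [first, last] seeded pixel row
    shear_rate_s1: float          # blood-layer shear of the source field
    seed: int

    def to_json(self, path) -> None:
        d = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
             for k, v in dataclasses.asdict(self).items()}
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)


def _render_gaussian_spots(shape: Tuple[int, int], pos: np.ndarray,
                           amplitudes: np.ndarray, sigma: float
                           ) -> np.ndarray:
    """Additively render particles as Gaussian intensity spots."""
    r = int(np.ceil(4 * sigma))
    H, W = shape
    img = np.zeros((H + 2 * r, W + 2 * r))
    if len(pos):
        py = pos[:, 0] + r
        px = pos[:, 1] + r
        cy = np.round(py).astype(int)
        cx = np.round(px).astype(int)
        offs = np.arange(-r, r + 1)
        oy, ox = np.meshgrid(offs, offs, indexing="ij")
        yy = cy[:, None, None] + oy[None]
        xx = cx[:, None, None] + ox[None]
        vals = amplitudes[:, None, None] * np.exp(
            -((yy - py[:, None, None]) ** 2 + (xx - px[:, None, None]) ** 2)
            / (2 * sigma ** 2))
        inside = (yy >= 0) & (yy < img.shape[0]) & (xx >= 0) & (xx < img.shape[1])
        np.add.at(img, (yy[inside], xx[inside]), vals[inside])
    return img[r:-r, r:-r]


def gen_particle_frames(field: coflow.DuctField, n_pairs: int = 100,
                        dt_ms: Optional[float] = None,
                        pixel_scale_um: float = 0.27,
                        seeding_density: float = 0.03,
                        particle_sigma_px: float = 1.2,
                        particle_amplitude: float = 150.0,
                        noise_sigma: float = 2.0,
                        frame_width_px: int = 256,
                        illumination_ramp: float = 0.0,
                        seed: int = 0
                        ) -> Tuple[List[ParticleImagePair], ParticleTruth]:
    """Tracer-particle image pairs advected by the mid-plane velocity.

    Rows span the channel width; tracers are seeded uniformly in the
    blood (test) stream only, mirroring the sample preparation, so the
    transverse tracer-density profile marks the blood layer.  Frame B of
    each pair advects every particle by ``u(y)·dt``.  ``dt_ms`` defaults
    to the value that puts the fastest displacement at 8 px (the 6–10 px
    working range).
    """
    if not seeding_density > 0:
        raise DomainError("seeding density must be positive")
    rng = np.random.default_rng(seed)
    w = field.geometry.width_um
    n_rows = int(round(w / pixel_scale_um))
    rows = np.arange(n_rows)
    row_y = -0.5 * w + (rows + 0.5) * pixel_scale_um

    y_prof, u_prof = field.mid_plane_profile()
    row_u = np.interp(row_y, y_prof, u_prof)     # mm/s

    y_if = field.geometry.interface_Y * w
    blood = row_y < y_if
    if not blood.any():
        raise DomainError("no blood layer inside the frame")
    b0, b1 = int(np.flatnonzero(blood)[0]), int(np.flatnonzero(blood)[-1])

    u_max = float(np.abs(row_u[blood]).max())
    if dt_ms is None:
        dt_ms = select_dt_ms(u_max, pixel_scale_um)
    disp_row = row_u * dt_ms / pixel_scale_um    # px
    if np.abs(disp_row[blood]).max() > frame_width_px:
        raise DomainError("displacement exceeds the frame; reduce dt")

    shape = (n_rows, frame_width_px)
    ramp = 1.0
    if illumination_ramp:
        ramp = 1.0 + illumination_ramp * (
            np.linspace(-0.5, 0.5, frame_width_px)[None, :])

    n_particles = int(seeding_density * (b1 - b0 + 1) * frame_width_px)
    pairs = []
    for _ in range(n_pairs):
        pos = np.column_stack([
            rng.uniform(b0, b1 + 1, n_particles),
            rng.uniform(0, frame_width_px, n_particles),
        ])
        amp = particle_amplitude * rng.uniform(0.7, 1.3, n_particles)
        disp = np.interp(pos[:, 0], rows, disp_row)
        fa = _render_gaussian_spots(shape, pos, amp, particle_sigma_px)
        fb = _render_gaussian_spots(
            shape, np.column_stack([pos[:, 0], pos[:, 1] + disp]), amp,
            particle_sigma_px)
        fa = fa * ramp + rng.normal(0, noise_sigma, shape)
        fb = fb * ramp + rng.normal(0, noise_sigma, shape)
        pairs.append(ParticleImagePair(np.clip(fa, 0, None),
                                       np.clip(fb, 0, None),
                                       dt_ms=dt_ms,
                                       pixel_scale_um=pixel_scale_um))

    truth = ParticleTruth(
        row_y_um=row_y, row_u_mm_s=row_u, row_displacement_px=disp_row,
        dt_ms=dt_ms, pixel_scale_um=pixel_scale_um, blood_rows=(b0, b1),
        shear_rate_s1=_blood_layer_shear(field), seed=seed)
    return pairs, truth


# ---------------------------------------------------------------------------
# bright-field aggregate frames
# ---------------------------------------------------------------------------


@dataclass
class AggregateSceneTruth:
    """Per-frame object lists plus the generator's parameters."""

    frames: List[List[Dict]]      # dicts: shape, area_um2, centroid, class
    pixel_scale_um: float
    illumination_ramp_fraction: float
    noise_sigma: float
    bin_edges_um2: Sequence[float]
    seed: int

    def per_frame_areas(self) -> List[List[float]]:
        return [[o["area_um2"] for o in objs] for objs in self.frames]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=float)


def _raster_disk(radius_px: float) -> np.ndarray:
    r = int(np.ceil(radius_px))
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    return (yy ** 2 + xx ** 2) <= radius_px ** 2


def _raster_rouleau(rng, n_cells: int, long_axis_px: float,
                    short_axis_px: float) -> np.ndarray:
    """Stack-of-coins chain: overlapping ellipses along a jittered line."""
    theta = rng.uniform(0, np.pi)           # chain direction
    step = 0.75 * short_axis_px
    length = n_cells * step + long_axis_px
    r = int(np.ceil(length / 2 + long_axis_px))
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    mask = np.zeros(yy.shape, dtype=bool)
    a, b = long_axis_px / 2.0, short_axis_px / 2.0
    for i in range(n_cells):
        t = (i - (n_cells - 1) / 2.0) * step
        cy, cx = t * np.sin(theta), t * np.cos(theta)
        ang = theta + np.pi / 2 + rng.normal(0, 0.15)
        yr = (yy - cy) * np.cos(ang) + (xx - cx) * np.sin(ang)
        xr = -(yy - cy) * np.sin(ang) + (xx - cx) * np.cos(ang)
        mask |= (xr / a) ** 2 + (yr / b) ** 2 <= 1.0
    return _crop_mask(mask)


def _raster_cluster(rng, n_cells: int, cell_radius_px: float) -> np.ndarray:
    """3-D cluster proxy: union of randomly packed disks."""
    blob_r = cell_radius_px * (1 + np.sqrt(n_cells))
    r = int(np.ceil(blob_r + cell_radius_px)) + 1
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    mask = np.zeros(yy.shape, dtype=bool)
    for _ in range(n_cells):
        rho = blob_r * np.sqrt(rng.uniform())
        phi = rng.uniform(0, 2 * np.pi)
        cy, cx = rho * np.sin(phi), rho * np.cos(phi)
        mask |= ((yy - cy) ** 2 + (xx - cx) ** 2) <= cell_radius_px ** 2
    # keep the largest connected piece so the object is one aggregate
    lab, n = ndi.label(mask)
    if n > 1:
        sizes = np.bincount(lab.ravel())[1:]
        mask = lab == (1 + int(np.argmax(sizes)))
    return _crop_mask(mask)


def _crop_mask(mask: np.ndarray) -> np.ndarray:
    ys, xs = np.nonzero(mask)
    return mask[ys.min():ys.max() + 1, xs.min():xs.max() + 1]


def gen_aggregate_frames(n_frames: int = 200,
                         frame_shape: Tuple[int, int] = (300, 640),
                         pixel_scale_um: float = 0.2,
                         mean_objects_per_frame: float = 5.0,
                         shape_mix: Optional[Dict[str, float]] = None,
                         disk_radius_um: Tuple[float, float] = (3.0, 18.0),
                         rouleau_cells: Tuple[int, int] = (3, 25),
                         cluster_cells: Tuple[int, int] = (5, 60),
                         rbc_long_axis_um: float = 8.0,
                         rbc_short_axis_um: float = 2.4,
                         min_separation_px: int = 3,
                         allow_overlap: bool = False,
                         illumination_ramp_fraction: float = 0.2,
                         noise_sigma: float = 5.0,
                         background_intensity: float = 200.0,
                         object_intensity: float = 70.0,
                         psf_sigma_px: float = 1.0,
                         bin_edges_um2: Sequence[float] = DEFAULT_SIZE_BINS_UM2,
                         max_area_fraction: float = 0.45,
                         min_object_area_um2: float = 25.0,
                         seed: int = 0
                         ) -> Tuple[FrameStack, AggregateSceneTruth]:
    """Bright-field frames of dark RBC aggregates with known areas.

    Objects are disks, rouleau chains (overlapping ellipses, RBC-sized
    coins) and cluster blobs (unions of disks), placed independently per
    frame; with ``allow_overlap=False`` objects keep at least
    ``min_separation_px`` clearance so every drawn object is separately
    countable.  The recorded truth area is the rasterized pixel count —
    what a perfect detector would measure.  A multiplicative linear
    illumination ramp and additive Gaussian noise emulate the imaging
    imperfections; total object coverage above ``max_area_fraction``
    raises, mirroring the regime where single-frame sizing is ill-posed.
    """
    shape_mix = shape_mix or {"disk": 0.3, "rouleau": 0.5, "cluster": 0.2}
    names = sorted(shape_mix)
    probs = np.array([shape_mix[k] for k in names], dtype=float)
    probs /= probs.sum()
    rng = np.random.default_rng(seed)
    H, W = frame_shape

    long_px = rbc_long_axis_um / pixel_scale_um
    short_px = rbc_short_axis_um / pixel_scale_um
    cell_r_px = 0.5 * rbc_long_axis_um / pixel_scale_um * 0.55

    sep = int(min_separation_px)
    frames, truth_frames = [], []
    for _ in range(n_frames):
        # occupancy is padded by the separation so halos never clip
        occupancy = np.zeros((H + 2 * sep, W + 2 * sep), dtype=bool)
        img_mask = np.zeros(frame_shape, dtype=bool)
        objs = []
        n_obj = rng.poisson(mean_objects_per_frame)
        for _ in range(n_obj):
            kind = names[rng.choice(len(names), p=probs)]
            if kind == "disk":
                mask = _raster_disk(rng.uniform(*disk_radius_um)
                                    / pixel_scale_um)
            elif kind == "rouleau":
                mask = _raster_rouleau(rng, int(rng.integers(*rouleau_cells)),
                                       long_px, short_px)
            else:
                mask = _raster_cluster(rng, int(rng.integers(*cluster_cells)),
                                       cell_r_px)
            mh, mw = mask.shape
            if mh >= H or mw >= W:
                continue
            # degenerate shapes below a few cells are not aggregates
            if mask.sum() * pixel_scale_um ** 2 < min_object_area_um2:
                continue
            halo = np.pad(mask, sep)
            if sep:
                halo = ndi.binary_dilation(halo, structure=np.ones((3, 3)),
                                           iterations=sep)
            placed = False
            for _try in range(60):
                r0 = int(rng.integers(0, H - mh))
                c0 = int(rng.integers(0, W - mw))
                window = occupancy[r0:r0 + mh + 2 * sep,
                                   c0:c0 + mw + 2 * sep]
                if not allow_overlap and np.any(window & halo):
                    continue
                img_mask[r0:r0 + mh, c0:c0 + mw] |= mask
                window |= halo
                area_px = int(mask.sum())
                area_um2 = area_px * pixel_scale_um ** 2
                cls = int(classify_size_bins([area_um2], bin_edges_um2)
                          .argmax())
                objs.append({"shape": kind, "area_um2": float(area_um2),
                             "area_px": area_px,
                             "centroid": (r0 + mh / 2.0, c0 + mw / 2.0),
                             "size_class": cls})
                placed = True
                break
            if not placed and not allow_overlap:
                # crowded frame: skip this object rather than loop forever
                continue
        covered = int(img_mask.sum())
        if covered / (H * W) > max_area_fraction:
            raise HemorheoError(
                f"object coverage {covered / (H * W):.2f} exceeds "
                f"max_area_fraction={max_area_fraction}; single-frame sizing "
                "is ill-posed at this density")
        img = np.full(frame_shape, background_intensity)
        img[img_mask] = object_intensity
        if illumination_ramp_fraction:
            ramp = 1.0 + illumination_ramp_fraction * np.linspace(
                -0.5, 0.5, W)[None, :]
            img = img * ramp
        if psf_sigma_px:
            img = ndi.gaussian_filter(img, psf_sigma_px)
        img = img + rng.normal(0, noise_sigma, frame_shape)
        frames.append(np.clip(img, 0, None))
        truth_frames.append(objs)

    stack = FrameStack(frames=frames, pixel_scale_um=pixel_scale_um,
                       frame_rate_hz=160.0)
    truth = AggregateSceneTruth(
        frames=truth_frames, pixel_scale_um=pixel_scale_um,
        illumination_ramp_fraction=illumination_ramp_fraction,
        noise_sigma=noise_sigma, bin_edges_um2=list(bin_edges_um2), seed=seed)
    return stack, truth


# ---------------------------------------------------------------------------
# viscosity curves
# ---------------------------------------------------------------------------


def gen_viscosity_samples(model: str,
                          params: Union[PowerLawParams, CarreauParams,
                                        Sequence[float]],
                          gamma_range: Tuple[float, float] = (1.0, 50.0),
                          m: int = 40,
                          noise_sigma: float = 0.0,
                          plasma_viscosity_cp: Optional[float] = None,
                          hematocrit_pct: Optional[float] = None,
                          temperature_c: Optional[float] = None,
                          seed: int = 0) -> ViscosityCurve:
    """Draw (shear rate, viscosity) samples from a truth model.

    Shear rates are log-spaced over ``gamma_range``; ``noise_sigma`` is
    the relative standard deviation of multiplicative Gaussian noise
    (0 gives exact model values).
    """
    if m < 5:
        raise DomainError("need at least 5 samples")
    lo, hi = gamma_range
    if not (lo > 0 and hi > lo):
        raise DomainError("gamma_range must be positive and increasing")
    g = np.logspace(np.log10(lo), np.log10(hi), m)
    if model == "powerlaw":
        p = (params if isinstance(params, PowerLawParams)
             else PowerLawParams(*params))
        mu = power_law_viscosity(g, p.K, p.n)
        meta = {"model": "powerlaw", "K": p.K, "n": p.n}
    elif model == "carreau":
        p = (params if isinstance(params, CarreauParams)
             else CarreauParams(*params))
        mu = carreau_viscosity(g, p.mu_zero, p.mu_inf, p.lam, p.n, p.a)
        meta = {"model": "carreau", "mu_zero": p.mu_zero, "mu_inf": p.mu_inf,
                "lam": p.lam, "n": p.n, "a": p.a}
    else:
        raise ConfigurationError(f"unknown model {model!r}")
    if noise_sigma:
        rng = np.random.default_rng(seed)
        mu = mu * np.clip(1.0 + noise_sigma * rng.standard_normal(m), 1e-6,
                          None)
    meta.update({"noise_sigma": noise_sigma, "seed": seed,
                 "gamma_range": list(gamma_range)})
    return ViscosityCurve(g, mu, plasma_viscosity_cp=plasma_viscosity_cp,
                          hematocrit_pct=hematocrit_pct,
                          temperature_c=temperature_c, metadata=meta)
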