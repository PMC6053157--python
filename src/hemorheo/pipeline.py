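"""End-to-end orchestration of the measurement chain.

One synthetic or recorded experiment flows through:

tracer frames ──► background removal ──► multi-pass PIV ──► averaged
profile ──► blood-layer detection (tracer density) ──► shear rate, and
in parallel the layer edge gives the interface position Y, which with
the pump flow rates inverts the stratified-flow model into the blood's
apparent viscosity (divided by the donor plasma viscosity when known);
bright-field frames ──► illumination correction ──► segmentation ──►
areas ──► per-recording statistics.

Each run produces :class:`ResultRow` records — one per (sample, flow
rate, temperature) — and every written file carries provenance
(config hash, seed, package version).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__, coflow
from .aggregates import (DEFAULT_SIZE_BINS_UM2, FrameStack,
                         correct_illumination, measure_aggregate_areas,
                         segment_aggregates, summarize_recording)
from .errors import HemorheoError
from .rheology import relative_viscosity
from .units import CP_TO_PA_S, PA_S_TO_CP
from .velocimetry import (ParticleImagePair, detect_blood_layer,
                          displacement_to_velocity, estimate_shear_rate,
                          piv_multipass, remove_background,
                          temporal_average_profile)

log = logging.getLogger("hemorheo.pipeline")

__all__ = ["ExperimentConfig", "ResultRow", "run_viscometry_pipeline",
           "run_aggregate_pipeline", "write_results", "read_results"]


@dataclass
class ExperimentConfig:
    """Resolved configuration of one experiment run."""

    width_um: float = 110.0
    depth_um: float = 60.0
    q_reference_ul_hr: float = 40.0
    q_test_ul_hr: float = 10.0
    mu_reference_cp: float = 1.0
    plasma_viscosity_cp: Optional[float] = None
    pixel_scale_piv_um: float = 0.27
    pixel_scale_hs_um: float = 0.2
    dt_ms: Optional[float] = None
    hematocrit_pct: Optional[float] = None
    temperature_c: Optional[float] = None
    sample_label: str = "synthetic"
    interface_Y_override: Optional[float] = None
    min_area_um2: float = 20.0
    inner_fraction: float = 0.8
    layer_threshold_fraction: float = 0.5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise HemorheoError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class ResultRow:
    """One row of the result table: one (sample, flow rate, temperature)."""

    sample_label: str
    hematocrit_pct: Optional[float]
    temperature_c: Optional[float]
    q_test_ul_hr: Optional[float]
    shear_rate_s1: Optional[float] = None
    mean_aggregate_area_um2: Optional[float] = None
    area_stderr_um2: Optional[float] = None
    apparent_viscosity_cp: Optional[float] = None
    relative_viscosity: Optional[float] = None
    interface_Y: Optional[float] = None
    warnings: str = ""


_RESULT_COLUMNS = [f.name for f in dataclasses.fields(ResultRow)]


def _tracer_density_profile(pairs: Sequence[ParticleImagePair]
                            ) -> Tuple[np.ndarray, np.ndarray]:
    """Mean intensity per transverse pixel row across all frames (μm, a.u.)."""
    mean_img = np.mean([p.frame_a for p in pairs], axis=0)
    dens = mean_img.mean(axis=1)
    dens = np.clip(dens - np.median(dens[dens <= np.percentile(dens, 20)]),
                   0.0, None)
    scale = pairs[0].pixel_scale_um
    y = (np.arange(dens.size) + 0.5) * scale
    return y, dens


def run_viscometry_pipeline(pairs: Sequence[ParticleImagePair],
                            config: ExperimentConfig) -> Tuple[ResultRow, Dict]:
    """Shear rate + apparent viscosity from one tracer-pair recording.

    Returns the result row and a diagnostics dict with every
    intermediate quantity (profile, layer, fit, inversion residual).
    """
    warnings: List[str] = []
    dt = pairs[0].dt_ms
    scale = pairs[0].pixel_scale_um

    frames_a = remove_background([p.frame_a for p in pairs])
    frames_b = remove_background([p.frame_b for p in pairs])
    fields = []
    for a, b in zip(frames_a, frames_b):
        vf = piv_multipass(ParticleImagePair(a, b, dt, scale))
        fields.append(displacement_to_velocity(vf, dt, scale))
    profile = temporal_average_profile(fields, pixel_scale_um=scale)

    y_dens, dens = _tracer_density_profile(pairs)
    y_lo, y_hi = detect_blood_layer(y_dens, dens,
                                    config.layer_threshold_fraction)
    log.info("blood layer: [%.1f, %.1f] um", y_lo, y_hi)

    shear = estimate_shear_rate(profile, (y_lo, y_hi),
                                inner_fraction=config.inner_fraction)

    # the tracer-laden blood stream starts at the y=0 wall, so its far
    # edge is the fluid interface
    if config.interface_Y_override is not None:
        Y = config.interface_Y_override
    else:
        Y = float(np.clip(y_hi / config.width_um - 0.5, -0.499, 0.499))

    geometry = coflow.ChannelGeometry(config.width_um, config.depth_um,
                                      interface_Y=Y)
    problem = coflow.CoflowProblem(
        mu_reference=config.mu_reference_cp * CP_TO_PA_S,
        q_reference_ul_hr=config.q_reference_ul_hr,
        q_test_ul_hr=config.q_test_ul_hr)
    mu_app_cp = coflow.apparent_viscosity(problem, geometry) * PA_S_TO_CP

    rel = None
    if config.plasma_viscosity_cp is not None:
        rel = relative_viscosity(mu_app_cp, config.plasma_viscosity_cp)
    else:
        warnings.append("plasma viscosity not provided; relative viscosity "
                        "left empty")
        log.warning(warnings[-1])

    row = ResultRow(
        sample_label=config.sample_label,
        hematocrit_pct=config.hematocrit_pct,
        temperature_c=config.temperature_c,
        q_test_ul_hr=config.q_test_ul_hr,
        shear_rate_s1=shear.shear_rate_s1,
        apparent_viscosity_cp=mu_app_cp,
        relative_viscosity=rel,
        interface_Y=Y,
        warnings="; ".join(warnings),
    )
    diagnostics = {
        "profile": profile, "layer_um": (y_lo, y_hi), "shear": shear,
        "interface_Y": Y, "mu_ratio": mu_app_cp / config.mu_reference_cp,
        "n_fields": len(fields),
    }
    return row, diagnostics


def run_aggregate_pipeline(stack: FrameStack, config: ExperimentConfig,
                           shear_rate_s1: Optional[float] = None,
                           bin_edges_um2: Sequence[float] =
                           DEFAULT_SIZE_BINS_UM2) -> Tuple[ResultRow, Dict]:
    """Aggregate-size statistics for one recording, joined with its shear."""
    per_frame = []
    for i, frame in enumerate(stack.frames):
        corrected = correct_illumination(frame)
        mask = segment_aggregates(corrected, stack.pixel_scale_um,
                                  min_area_um2=config.min_area_um2,
                                  frame_index=i)
        per_frame.append(measure_aggregate_areas(mask, stack.pixel_scale_um))
    record = summarize_recording(per_frame, bin_edges_um2=bin_edges_um2)
    warn = ""
    if record.n_empty_frames == record.n_frames:
        warn = "no aggregates detected in any frame"
        log.warning(warn)
    row = ResultRow(
        sample_label=config.sample_label,
        hematocrit_pct=config.hematocrit_pct,
        temperature_c=config.temperature_c,
        q_test_ul_hr=config.q_test_ul_hr,
        shear_rate_s1=shear_rate_s1,
        mean_aggregate_area_um2=record.recording_mean_um2,
        area_stderr_um2=record.recording_stderr_um2,
        warnings=warn,
    )
    return row, {"record": record}


def write_results(rows: Sequence[ResultRow], path, fmt: str = "csv",
                  config: Optional[ExperimentConfig] = None) -> None:
    """Write result rows as CSV (stable column order) or JSON.

    A provenance sidecar ``<path>.provenance.json`` records the package
    version, seed and config hash.
    """
    path = Path(path)
    df = pd.DataFrame([dataclasses.asdict(r) for r in rows],
                      columns=_RESULT_COLUMNS)
    if fmt == "csv":
        df.to_csv(path, index=False)
    elif fmt == "json":
        df.to_json(path, orient="records", indent=2)
    else:
        raise HemorheoError(f"unknown format {fmt!r}")
    prov = {"package": "hemorheo", "version": __version__,
            "n_rows": len(rows)}
    if config is not None:
        prov.update({"config_digest": config.digest(), "seed": config.seed})
    with open(str(path) + ".provenance.json", "w") as fh:
        json.dump(prov, fh, indent=2)


def read_results(path) -> pd.DataFrame:
    """Read back a result table written by :func:`write_results`."""
    path = Path(path)
    if path.suffix == ".json":
        return pd.read_json(path)
    return pd.read_csv(path)
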