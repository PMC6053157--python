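"""Shared fixtures: synthetic experiments reused across test modules."""

import numpy as np
import pytest

from hemorheo import synthetic
from hemorheo.velocimetry import (ParticleImagePair, displacement_to_velocity,
                                  piv_multipass, remove_background)

BETA = 60.0 / 110.0


@pytest.fixture(scope="session")
def coflow_bundle():
    """One full synthetic viscometry experiment (truth ratio 5, pumps 4:1)."""
    truth, field = synthetic.gen_coflow_experiment(mu_ratio=5.0, q_ratio=4.0,
                                                   seed=11)
    pairs, ptruth = synthetic.gen_particle_frames(field, n_pairs=8, seed=12)
    return {"truth": truth, "field": field, "pairs": pairs, "ptruth": ptruth}


@pytest.fixture(scope="session")
def piv_fields(coflow_bundle):
    """Velocity fields (mm/s) recovered by PIV from the bundle's pairs."""
    pairs = coflow_bundle["pairs"]
    dt, scale = pairs[0].dt_ms, pairs[0].pixel_scale_um
    frames_a = remove_background([p.frame_a for p in pairs])
    frames_b = remove_background([p.frame_b for p in pairs])
    out = []
    for a, b in zip(frames_a, frames_b):
        vf = piv_multipass(ParticleImagePair(a, b, dt, scale))
        out.append(displacement_to_velocity(vf, dt, scale))
    return out


@pytest.fixture(scope="session")
def aggregate_recording():
    """A 60-frame synthetic bright-field recording with truth."""
    stack, truth = synthetic.gen_aggregate_frames(n_frames=60, seed=7)
    return stack, truth


def render_particles(rng, shape, positions, amplitude=150.0, sigma=1.2):
    """Minimal independent particle renderer for PIV unit tests."""
    img = np.zeros(shape)
    r = 5
    for y, x in positions:
        y0, x0 = int(round(y)), int(round(x))
        ys = np.arange(max(0, y0 - r), min(shape[0], y0 + r + 1))
        xs = np.arange(max(0, x0 - r), min(shape[1], x0 + r + 1))
        yy, xx = np.meshgrid(ys, xs, indexing="ij")
        img[yy, xx] += amplitude * np.exp(
            -((yy - y) ** 2 + (xx - x) ** 2) / (2 * sigma ** 2))
    return img
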