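"""Shared fixtures: phantoms and tracked centerlines, generated once per session."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from aortacalc.anatomy import LandmarkSet
from aortacalc.centerline import TrackingConfig, extract_centerline
from aortacalc.phantom import default_phantom_spec, generate_phantom, place_wall_lesion

SMALL_SHAPE = (128, 128, 64)
SMALL_SPACING = (1.0, 1.0, 2.5)


@pytest.fixture(scope="session")
def cfg() -> TrackingConfig:
    return TrackingConfig()


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free lesion-free aorta phantom (coarse grid for speed)."""
    spec = default_phantom_spec(shape=SMALL_SHAPE, spacing=SMALL_SPACING)
    volume, gt = generate_phantom(spec)
    return spec, volume, gt


@pytest.fixture(scope="session")
def lesion_phantom():
    """Phantom with two wall lesions per segment, away from boundaries."""
    spec = default_phantom_spec(shape=SMALL_SHAPE, spacing=SMALL_SPACING)
    rng = np.random.default_rng(11)
    b = spec.segment_boundaries()
    for seg in range(5):
        for _ in range(2):
            spec.lesions.append(
                place_wall_lesion(
                    spec,
                    arc_s=float(rng.uniform(b[seg] + 8, b[seg + 1] - 8)),
                    angle_deg=float(rng.uniform(0, 360)),
                    size_mm=(3.0, 3.0, 2.5),
                    hu=float(rng.uniform(150, 800)),
                )
            )
    volume, gt = generate_phantom(spec)
    return spec, volume, gt


@pytest.fixture(scope="session")
def tracked(lesion_phantom, cfg):
    """Centerline extracted from the lesion phantom, plus its landmark set."""
    spec, volume, gt = lesion_phantom
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cl = extract_centerline(volume, gt.seeds["C_A"], gt.seeds["C_D"], cfg)
    return cl, LandmarkSet.from_dict(gt.landmarks)


def cylinder_volume(radius=15.0, tilt_deg=0.0, shape=(96, 96, 48),
                    spacing=(1.0, 1.0, 2.5), lumen_hu=40.0, background_hu=-100.0):
    """A (possibly tilted) cylinder along +z through the grid centre.

    Returns (volume, axis_point_at_z) where the callable gives the analytic
    axis position at a world z level.
    """
    from aortacalc.volume import CTVolume

    nx, ny, nz = shape
    sx, sy, sz = spacing
    cx, cy = nx * sx / 2.0, ny * sy / 2.0
    slope = np.tan(np.radians(tilt_deg))
    zmid = nz * sz / 2.0
    xs = (np.arange(nx) * sx)[:, None, None]
    ys = (np.arange(ny) * sy)[None, :, None]
    zs = (np.arange(nz) * sz)[None, None, :]
    # true circular cylinder: distance to the tilted axis line <= radius
    t = np.array([np.sin(np.radians(tilt_deg)), 0.0, np.cos(np.radians(tilt_deg))])
    dx, dy, dz = xs - cx, ys - cy, zs - zmid
    proj = dx * t[0] + dy * t[1] + dz * t[2]
    dist2 = dx**2 + dy**2 + dz**2 - proj**2
    mask = dist2 <= radius**2
    data = np.full(shape, background_hu, dtype=np.float32)
    data[mask] = lumen_hu
    vol = CTVolume(data, spacing)

    def axis_at(z: float) -> np.ndarray:
        return np.array([cx + slope * (z - zmid), cy, z])

    return vol, axis_at
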