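"""Synthetic thoracic-aorta CT phantoms with analytically known ground truth.

The phantom is a constant-HU blood-pool tube — an ascending cylinder, a
toroidal arch lying in the x-z plane, and a descending cylinder — embedded in
a noisy soft-tissue background, with calcified wall lesions of known geometry
and attenuation.  Everything downstream (centerline tracking, segment
partition, Agatston scoring) can be validated against the parametric
centerline and the per-voxel scoring oracle defined here.

Coordinates are world millimetres; the third array axis is axial
(inferior -> superior), matching :class:`~aortacalc.volume.CTVolume`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .volume import CTVolume

__all__ = [
    "LesionSpec",
    "PhantomSpec",
    "GroundTruth",
    "PhantomGeometryError",
    "default_phantom_spec",
    "place_wall_lesion",
    "generate_phantom",
    "analytic_agatston",
    "AGATSTON_THRESHOLD_HU",
]

#: HU threshold above which tissue counts as calcified (scoring convention).
AGATSTON_THRESHOLD_HU = 130.0


class PhantomGeometryError(ValueError):
    """Raised when a phantom specification does not fit inside its grid."""


@dataclass
class LesionSpec:
    """A synthetic calcification: axis-aligned cuboid or ellipsoid of uniform HU.

    ``extents`` are full lengths (mm) along x/y/z; ``segment`` is the nominal
    aortic segment (1-5) the lesion was placed in, used as ground truth for
    the assignment stage.
    """

    center: tuple[float, float, float]
    extents: tuple[float, float, float]
    hu: float
    shape: str = "cuboid"  # "cuboid" | "ellipsoid"
    segment: int = 0

    def __post_init__(self) -> None:
        if self.shape not in ("cuboid", "ellipsoid"):
            raise ValueError(f"unknown lesion shape {self.shape!r}")
        if any(e <= 0 for e in self.extents):
            raise ValueError("lesion extents must be positive")

    def mask_in(self, volume: CTVolume) -> np.ndarray:
        """Boolean voxel mask of this lesion by analytic containment of voxel centres."""
        cx, cy, cz = self.center
        ex, ey, ez = (e / 2.0 for e in self.extents)
        xs = volume.axis_coords(0)[:, None, None] - cx
        ys = volume.axis_coords(1)[None, :, None] - cy
        zs = volume.axis_coords(2)[None, None, :] - cz
        if self.shape == "cuboid":
            # half-open faces: an extent of k pixels covers exactly k voxel centres
            return ((xs >= -ex) & (xs < ex) & (ys >= -ey) & (ys < ey)
                    & (zs >= -ez) & (zs < ez))
        return (xs / ex) ** 2 + (ys / ey) ** 2 + (zs / ez) ** 2 <= 1.0


@dataclass
class PhantomSpec:
    """Parametric aorta phantom: two vertical cylinders joined by a torus arc.

    The arch torus lies in the plane y = ``arch_center[1]`` and spans
    ``arch_span_deg`` degrees from the ascending attachment (torus angle 180°)
    towards the descending side (angle 180° - span).  With the default 180°
    span the tube tangent is continuous at both joints.  ``lumen_diameter_mm``
    may be a single value or per-part ``(ascending, arch, descending)``.
    """

    shape: tuple[int, int, int] = (512, 512, 80)
    spacing: tuple[float, float, float] = (0.5, 0.5, 2.5)
    background_hu: float = -100.0
    noise_sd: float = 0.0
    lumen_hu: float = 40.0
    ascending_origin: tuple[float, float, float] = (0.0, 0.0, 0.0)  # bottom of ascending axis
    ascending_length: float = 0.0
    descending_origin: tuple[float, float, float] = (0.0, 0.0, 0.0)  # bottom of descending axis
    descending_length: float = 0.0
    arch_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    arch_radius: float = 30.0
    arch_span_deg: float = 180.0
    lumen_diameter_mm: float | tuple[float, float, float] = 30.0
    lesions: list[LesionSpec] = field(default_factory=list)
    landmarks: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    seed_level_z: float = 0.0  # axial level of the seed pair (pulmonary bifurcation)
    seed: int = 0

    # -- derived geometry -------------------------------------------------

    def diameters(self) -> tuple[float, float, float]:
        d = self.lumen_diameter_mm
        if np.isscalar(d):
            return (float(d), float(d), float(d))  # type: ignore[arg-type]
        return tuple(float(x) for x in d)  # type: ignore[return-value]

    @property
    def arch_arc_length(self) -> float:
        """Analytic arc length of the toroidal arch, R * span (mm)."""
        return self.arch_radius * math.radians(self.arch_span_deg)

    @property
    def total_length(self) -> float:
        return self.ascending_length + self.arch_arc_length + self.descending_length

    def centerline_point(self, s: float | np.ndarray) -> np.ndarray:
        """Parametric centerline position at arc length ``s`` (proximal -> distal)."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        out = np.empty((s.size, 3))
        la, larc = self.ascending_length, self.arch_arc_length
        asc = s <= la
        arch = (s > la) & (s <= la + larc)
        desc = s > la + larc
        a0 = np.asarray(self.ascending_origin)
        out[asc] = a0 + np.outer(s[asc], [0, 0, 1.0])
        cx, cy, cz = self.arch_center
        phi = math.pi - (s[arch] - la) / self.arch_radius
        out[arch, 0] = cx + self.arch_radius * np.cos(phi)
        out[arch, 1] = cy
        out[arch, 2] = cz + self.arch_radius * np.sin(phi)
        # descending: straight down from the arc end point
        phi_end = math.pi - math.radians(self.arch_span_deg)
        top = np.array([cx + self.arch_radius * math.cos(phi_end), cy,
                        cz + self.arch_radius * math.sin(phi_end)])
        out[desc] = top - np.outer(s[desc] - la - larc, [0, 0, 1.0])
        return out if out.shape[0] > 1 else out[0]

    def centerline_tangent(self, s: float | np.ndarray) -> np.ndarray:
        s = np.atleast_1d(np.asarray(s, dtype=float))
        out = np.zeros((s.size, 3))
        la, larc = self.ascending_length, self.arch_arc_length
        asc = s <= la
        arch = (s > la) & (s <= la + larc)
        desc = s > la + larc
        out[asc] = [0, 0, 1.0]
        phi = math.pi - (s[arch] - la) / self.arch_radius
        out[arch, 0] = np.sin(phi)
        out[arch, 2] = -np.cos(phi)
        out[desc] = [0, 0, -1.0]
        return out if out.shape[0] > 1 else out[0]

    def local_diameter(self, s: float | np.ndarray) -> np.ndarray:
        s = np.atleast_1d(np.asarray(s, dtype=float))
        da, dt, dd = self.diameters()
        la, larc = self.ascending_length, self.arch_arc_length
        out = np.where(s <= la, da, np.where(s <= la + larc, dt, dd))
        return out if out.shape[0] > 1 else out[0]

    def segment_boundaries(self) -> np.ndarray:
        """Analytic arc lengths of the six segment boundaries (LMCA .. distal end)."""
        la, larc = self.ascending_length, self.arch_arc_length
        lm = self._project(self.landmarks["LMCA"])
        b12 = self.seed_level_z - self.ascending_origin[2]
        b23 = self._project(self.landmarks["RSA"])
        b34 = self._project(self.landmarks["LSA"])
        b45 = la + larc + (self.arch_center[2] - self.landmarks["CS"][2])
        return np.array([lm, b12, b23, b34, b45, self.total_length])

    def _project(self, point) -> float:
        s = np.linspace(0.0, self.total_length, 4096)
        p = self.centerline_point(s)
        return float(s[np.argmin(np.linalg.norm(p - np.asarray(point), axis=1))])

    def segment_of_arc(self, s: float) -> int:
        b = self.segment_boundaries()
        return int(np.searchsorted(b[1:5], s, side="right")) + 1


@dataclass
class GroundTruth:
    """Analytic truth for one phantom: centerline samples, segment arcs, lesion scores."""

    arc: np.ndarray                # (N,) arc lengths, mm
    points: np.ndarray             # (N, 3) world mm
    tangents: np.ndarray           # (N, 3) unit
    diameters: np.ndarray          # (N,) mm
    segment_boundaries: np.ndarray  # (6,) arc lengths, mm
    lesion_scores: list[float]
    lesion_segments: list[int]
    seeds: dict[str, np.ndarray]   # C_A, C_D world positions
    landmarks: dict[str, np.ndarray]

    @property
    def total_length(self) -> float:
        return float(self.arc[-1])

    @property
    def segment_lengths_cm(self) -> np.ndarray:
        return np.diff(self.segment_boundaries) / 10.0


def default_phantom_spec(
    shape: tuple[int, int, int] = (512, 512, 80),
    spacing: tuple[float, float, float] = (0.5, 0.5, 2.5),
    arch_radius: float = 30.0,
    lumen_diameter_mm: float | tuple[float, float, float] = 30.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    lesions: list[LesionSpec] | None = None,
) -> PhantomSpec:
    """A consistent default geometry scaled to the grid extent.

    The arch apex sits just below the volume top; the ascending cylinder ends
    (proximally) at the LMCA level and the descending cylinder runs to near the
    volume bottom (diaphragm).  Landmarks are placed at anatomically plausible
    stations: RSA/LSA on the arch at 135°/45° torus angle, CS near the root.
    """
    nx, ny, nz = shape
    sx, sy, sz = spacing
    X, Y, Z = nx * sx, ny * sy, nz * sz
    d = max(np.atleast_1d(lumen_diameter_mm).astype(float))
    cx, cy = X / 2.0, Y / 2.0
    z_arch = Z - arch_radius - d / 2.0 - 2 * sz
    desc_bottom = 2 * sz
    asc_bottom = desc_bottom + 0.18 * Z
    # pulmonary bifurcation sits just below the arch underside
    seed_z = z_arch - 12.5
    cs_z = asc_bottom + 0.12 * Z
    if z_arch <= seed_z or seed_z <= asc_bottom:
        raise PhantomGeometryError("grid too small for the default aorta geometry")
    R = arch_radius
    spec = PhantomSpec(
        shape=shape,
        spacing=spacing,
        noise_sd=noise_sd,
        ascending_origin=(cx - R, cy, asc_bottom),
        ascending_length=z_arch - asc_bottom,
        descending_origin=(cx + R, cy, desc_bottom),
        descending_length=z_arch - desc_bottom,
        arch_center=(cx, cy, z_arch),
        arch_radius=R,
        arch_span_deg=180.0,
        lumen_diameter_mm=lumen_diameter_mm,
        seed_level_z=seed_z,
        seed=seed,
        lesions=list(lesions) if lesions else [],
    )
    da, dt, dd = spec.diameters()
    spec.landmarks = {
        "LMCA": (cx - R + da / 2.0 + 2.0, cy, asc_bottom),
        "RSA": _arch_landmark(spec, 135.0),
        "LSA": _arch_landmark(spec, 45.0),
        "CS": (cx - R - da / 2.0 - 2.0, cy, cs_z),
    }
    return spec


def _arch_landmark(spec: PhantomSpec, phi_deg: float) -> tuple[float, float, float]:
    """A point just outside the arch wall at torus angle phi (branch ostium)."""
    cx, cy, cz = spec.arch_center
    r_out = spec.arch_radius + spec.diameters()[1] / 2.0 + 2.0
    phi = math.radians(phi_deg)
    return (cx + r_out * math.cos(phi), cy, cz + r_out * math.sin(phi))


def place_wall_lesion(
    spec: PhantomSpec,
    arc_s: float,
    angle_deg: float = 0.0,
    size_mm: tuple[float, float, float] = (4.0, 4.0, 2.5),
    hu: float = 450.0,
    shape: str = "cuboid",
) -> LesionSpec:
    """Create a lesion centred on the lumen wall at arc length ``arc_s``.

    ``angle_deg`` rotates the lesion around the local centerline tangent;
    0° points within the arch plane (outer curvature), 90° points along +y.
    """
    p = np.asarray(spec.centerline_point(arc_s), dtype=float)
    t = np.asarray(spec.centerline_tangent(arc_s), dtype=float)
    ey = np.array([0.0, 1.0, 0.0])
    er = np.cross(t, ey)
    er /= np.linalg.norm(er)
    a = math.radians(angle_deg)
    direction = math.cos(a) * er + math.sin(a) * ey
    radius = float(spec.local_diameter(arc_s)) / 2.0
    center = p + radius * direction
    return LesionSpec(center=tuple(center), extents=size_mm, hu=hu,
                      shape=shape, segment=spec.segment_of_arc(arc_s))


# -- rasterization ---------------------------------------------------------


def _tube_mask(spec: PhantomSpec, volume: CTVolume) -> np.ndarray:
    xs = volume.axis_coords(0)[:, None, None]
    ys = volume.axis_coords(1)[None, :, None]
    zs = volume.axis_coords(2)[None, None, :]
    da, dt, dd = spec.diameters()

    ax, ay, az = spec.ascending_origin
    asc = (
        ((xs - ax) ** 2 + (ys - ay) ** 2 <= (da / 2) ** 2)
        & (zs >= az)
        & (zs <= az + spec.ascending_length)
    )
    dx, dy, dz = spec.descending_origin
    desc = (
        ((xs - dx) ** 2 + (ys - dy) ** 2 <= (dd / 2) ** 2)
        & (zs >= dz)
        & (zs <= dz + spec.descending_length)
    )
    cx, cy, cz = spec.arch_center
    rho = np.sqrt((xs - cx) ** 2 + (zs - cz) ** 2)  # broadcasts (nx, 1, nz)
    dist2 = (rho - spec.arch_radius) ** 2 + (ys - cy) ** 2
    phi = np.degrees(np.arctan2(zs - cz, xs - cx))  # (-180, 180]
    arch = (dist2 <= (dt / 2) ** 2) & (phi >= 180.0 - spec.arch_span_deg)
    return asc | desc | arch


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, GroundTruth]:
    """Rasterize the phantom and return the volume plus its analytic ground truth.

    Background voxels receive ``background_hu`` plus Gaussian noise; lumen and
    lesion voxels are noise-free at their nominal HU so that scores computed
    from the written volume match the analytic lesion values exactly.
    """
    extent = np.array(spec.shape) * np.array(spec.spacing)
    da, dt, dd = spec.diameters()
    ax, ay, az = spec.ascending_origin
    dx, dy, dz = spec.descending_origin
    cx, cy, cz = spec.arch_center
    R, rt = spec.arch_radius, dt / 2.0
    z_low_arch = cz + R * math.sin(math.radians(180.0 - min(spec.arch_span_deg, 270.0)))
    boxes = {
        "ascending cylinder": (
            [ax - da / 2, ay - da / 2, az],
            [ax + da / 2, ay + da / 2, az + spec.ascending_length],
        ),
        "descending cylinder": (
            [dx - dd / 2, dy - dd / 2, dz],
            [dx + dd / 2, dy + dd / 2, dz + spec.descending_length],
        ),
        "arch torus": (
            [cx - R - rt, cy - rt, min(z_low_arch, cz) - rt],
            [cx + R + rt, cy + rt, cz + R + rt],
        ),
    }
    for name, (lo, hi) in boxes.items():
        if np.any(np.asarray(lo) < 0) or np.any(np.asarray(hi) > extent):
            raise PhantomGeometryError(f"aorta tube leaves the grid near the {name}")

    rng = np.random.default_rng(spec.seed)
    data = np.full(spec.shape, spec.background_hu, dtype=np.float32)
    if spec.noise_sd > 0:
        data += rng.normal(0.0, spec.noise_sd, size=spec.shape).astype(np.float32)
    volume = CTVolume(data, spec.spacing)

    tube = _tube_mask(spec, volume)
    volume.data[tube] = spec.lumen_hu

    for i, lesion in enumerate(spec.lesions):
        c = np.asarray(lesion.center)
        if np.any(c - np.asarray(lesion.extents) / 2 < 0) or np.any(
            c + np.asarray(lesion.extents) / 2 > extent
        ):
            raise PhantomGeometryError(f"lesion {i} at {lesion.center} lies outside the grid")
        m = lesion.mask_in(volume)
        if not m.any():
            raise PhantomGeometryError(f"lesion {i} rasterizes to zero voxels")
        volume.data[m] = lesion.hu

    n = max(int(spec.total_length), 64)
    arc = np.linspace(0.0, spec.total_length, n)
    gt = GroundTruth(
        arc=arc,
        points=np.atleast_2d(spec.centerline_point(arc)),
        tangents=np.atleast_2d(spec.centerline_tangent(arc)),
        diameters=np.atleast_1d(spec.local_diameter(arc)),
        segment_boundaries=spec.segment_boundaries() if spec.landmarks else np.zeros(6),
        lesion_scores=[analytic_agatston(l, volume) for l in spec.lesions],
        lesion_segments=[l.segment for l in spec.lesions],
        seeds={
            "C_A": np.array([spec.ascending_origin[0], spec.ascending_origin[1], spec.seed_level_z]),
            "C_D": np.array([spec.descending_origin[0], spec.descending_origin[1], spec.seed_level_z]),
        },
        landmarks={k: np.asarray(v, dtype=float) for k, v in spec.landmarks.items()},
    )
    return volume, gt


# -- scoring oracle --------------------------------------------------------


def analytic_agatston(lesion: LesionSpec, volume: CTVolume) -> float:
    """Per-voxel brute-force Agatston score of one rasterized lesion.

    Independent of the detection pipeline: the lesion's voxels are found by
    analytic containment, thresholded at 130 HU, and scored slice by slice as
    (area in mm²) × density weight of the slice peak HU (1: 130-199, 2:
    200-299, 3: 300-399, 4: ≥400).  Returns 0 when no voxel reaches 130 HU.
    """
    mask = lesion.mask_in(volume)
    px_area = volume.spacing[0] * volume.spacing[1]
    score = 0.0
    for k in range(volume.shape[2]):
        hu = volume.data[:, :, k][mask[:, :, k]]
        hu = hu[hu >= AGATSTON_THRESHOLD_HU]
        if hu.size == 0:
            continue
        peak = float(hu.max())
        if peak >= 400:
            w = 4
        elif peak >= 300:
            w = 3
        elif peak >= 200:
            w = 2
        else:
            w = 1
        score += hu.size * px_area * w
    return score
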