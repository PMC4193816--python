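"""Thoracic-aorta centerline extraction by inscribed-circle tracking.

From two user seed points (ascending ``C_A`` and descending ``C_D`` at the
pulmonary-bifurcation level) the tracker inscribes a maximal circle in each
vessel cross-section: axial slices for the straight descending/ascending
portions, and obliquely resliced planes swept in 2° steps along a
semitoroidal path (to 240° by default) for the curvilinear arch.  The circle
found in each plane seeds the next.  A post-processing pass re-reslices every
cross-section perpendicular to the smoothed centerline tangent so diameters
are measured in true orthogonal planes.

All positions are world millimetres.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import label as cc_label
from scipy.ndimage import map_coordinates, uniform_filter1d

from .volume import CTVolume

__all__ = [
    "TrackingConfig",
    "CenterlinePoint",
    "Centerline",
    "PlaneImage",
    "SeedError",
    "DegenerateLumenError",
    "TruncationWarning",
    "inscribe_circle",
    "reslice_oblique",
    "track_descending",
    "track_arch",
    "perpendicular_correction",
    "extract_centerline",
]


class SeedError(ValueError):
    """The seed point does not sit in lumen-like tissue."""


class DegenerateLumenError(RuntimeError):
    """The inscribed circle collapsed below one pixel."""


class TruncationWarning(UserWarning):
    """Tracking stopped before the end of the intended range."""


@dataclass
class TrackingConfig:
    """Numeric knobs of the tracker.

    The angular step/span match the oblique-plane sweep of the arch (2° steps
    to 240°, endpoint inclusive -> 121 planes).  Lumen membership is relative:
    a sample is lumen-like when within ``hu_tolerance`` of the median HU in a
    5x5 patch around the seed; the patch median must itself fall inside
    ``lumen_hu_range`` (unenhanced blood pool) for the seed to be accepted.
    """

    angular_step_deg: float = 2.0
    angular_span_deg: float = 240.0
    hu_tolerance: float = 60.0
    growth_step_mm: float = 0.25
    max_iterations: int = 50
    center_tol_mm: float = 0.05
    coverage: float = 0.95
    n_perimeter: int = 72
    max_radius_mm: float = 30.0
    plane_size_mm: float = 80.0
    plane_pixel_mm: float | None = None  # default: min in-plane voxel spacing
    lumen_hu_range: tuple[float, float] = (-50.0, 129.0)
    smooth_window: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.angular_step_deg:
            raise ValueError("angular step must be positive")
        if self.angular_span_deg < 0 or (
            self.angular_span_deg > 0 and self.angular_step_deg > self.angular_span_deg
        ):
            raise ValueError("0 < step <= span required")
        if self.hu_tolerance <= 0 or self.growth_step_mm <= 0 or self.center_tol_mm <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class CenterlinePoint:
    position: np.ndarray      # world mm
    diameter: float           # mm
    normal: np.ndarray        # unit normal of the measurement plane
    plane_kind: str           # "axial" | "oblique"
    arc_length: float = 0.0   # mm from the proximal terminus


class Centerline:
    """Ordered centerline, proximal (LMCA level) -> distal (diaphragm)."""

    def __init__(self, points: list[CenterlinePoint]):
        if not points:
            raise ValueError("empty centerline")
        self.points = points
        self._recompute_arc()
        self.positions = np.array([p.position for p in points])
        self.diameters = np.array([p.diameter for p in points])
        self.normals = np.array([p.normal for p in points])
        self.arc = np.array([p.arc_length for p in points])

    def _recompute_arc(self) -> None:
        s = 0.0
        prev = None
        for p in self.points:
            if prev is not None:
                s += float(np.linalg.norm(p.position - prev))
            p.arc_length = s
            prev = p.position

    def __len__(self) -> int:
        return len(self.points)

    @property
    def total_length(self) -> float:
        return float(self.arc[-1])

    def nearest(self, point: np.ndarray) -> tuple[int, float, float]:
        """Index, arc length and distance of the centerline point nearest ``point``.

        Ties break toward the proximal (first) point.
        """
        d = np.linalg.norm(self.positions - np.asarray(point, dtype=float), axis=1)
        i = int(np.argmin(d))
        return i, float(self.arc[i]), float(d[i])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "index": np.arange(len(self)),
                "x_mm": self.positions[:, 0],
                "y_mm": self.positions[:, 1],
                "z_mm": self.positions[:, 2],
                "arc_length_mm": self.arc,
                "diameter_mm": self.diameters,
                "nx": self.normals[:, 0],
                "ny": self.normals[:, 1],
                "nz": self.normals[:, 2],
                "plane_kind": [p.plane_kind for p in self.points],
            }
        )


# -- 2-D circle inscription ------------------------------------------------

_SENTINEL = -2000.0


def _sample2d(image: np.ndarray, pts_mm: np.ndarray, spacing: np.ndarray) -> np.ndarray:
    """Bilinear samples of a 2-D image at in-plane mm positions (origin at pixel 0,0)."""
    coords = np.vstack([pts_mm[:, 0] / spacing[0], pts_mm[:, 1] / spacing[1]])
    return map_coordinates(
        image.astype(np.float64), coords, order=1, mode="constant", cval=_SENTINEL
    )


def inscribe_circle(
    image: np.ndarray,
    spacing: tuple[float, float] | np.ndarray,
    seed_mm: np.ndarray,
    cfg: TrackingConfig,
) -> tuple[np.ndarray, float]:
    """Maximal lumen-inscribed circle in a 2-D cross-section.

    Alternates radius growth (in ``growth_step_mm`` steps while at least
    ``coverage`` of the perimeter samples remain lumen-like) with recentring
    to the centroid of the lumen-like perimeter samples, until the centre
    moves less than ``center_tol_mm`` or ``max_iterations`` is reached.  A
    final recentring to the centroid of the connected lumen region around
    the circle resolves the slack a maximal circle has inside the elongated
    cross-sections produced by oblique cuts, then the radius is re-fitted.

    Returns ``(center_mm, radius_mm)`` in the image's in-plane mm frame.
    """
    spacing = np.asarray(spacing, dtype=float)
    seed = np.asarray(seed_mm, dtype=float)
    i, j = (np.round(seed / spacing)).astype(int)
    ni, nj = image.shape
    if not (0 <= i < ni and 0 <= j < nj):
        raise SeedError(f"seed {seed} outside the image")
    patch = image[max(i - 2, 0): i + 3, max(j - 2, 0): j + 3]
    ref = float(np.median(patch))
    lo, hi = cfg.lumen_hu_range
    if not (lo <= ref <= hi):
        raise SeedError(f"seed patch median {ref:.0f} HU outside lumen range [{lo}, {hi}]")
    if abs(float(_sample2d(image, seed[None, :], spacing)[0]) - ref) > cfg.hu_tolerance:
        raise SeedError("seed pixel is not lumen-like")

    ang = np.linspace(0.0, 2 * math.pi, cfg.n_perimeter, endpoint=False)
    units = np.column_stack([np.cos(ang), np.sin(ang)])
    dr = cfg.growth_step_mm

    def good_mask(center: np.ndarray, radius: float) -> np.ndarray:
        vals = _sample2d(image, center + radius * units, spacing)
        return np.abs(vals - ref) <= cfg.hu_tolerance

    def grow(center: np.ndarray, r: float) -> float:
        # batched growth: test all candidate radii at once
        n_steps = max(int((cfg.max_radius_mm - r) / dr), 0)
        if not n_steps:
            return r
        radii = r + dr * np.arange(1, n_steps + 1)
        pts = center[None, None, :] + radii[:, None, None] * units[None, :, :]
        vals = _sample2d(image, pts.reshape(-1, 2), spacing).reshape(len(radii), -1)
        cov = np.mean(np.abs(vals - ref) <= cfg.hu_tolerance, axis=1)
        bad = np.nonzero(cov < cfg.coverage)[0]
        if not bad.size:
            return float(radii[-1])
        return float(radii[bad[0] - 1]) if bad[0] > 0 else r

    def shrink(center: np.ndarray, r: float) -> float:
        while r > dr and np.mean(good_mask(center, r)) < cfg.coverage:
            r -= dr
        return r

    center = seed.copy()
    r = float(max(spacing))
    for _ in range(cfg.max_iterations):
        r = grow(center, r)
        good = good_mask(center, r)
        if not good.any():
            raise DegenerateLumenError("no lumen-like perimeter samples")
        new_center = (center + r * units[good]).mean(axis=0)
        # shrink until the recentred circle satisfies the coverage condition
        r = shrink(new_center, r)
        moved = float(np.linalg.norm(new_center - center))
        center = new_center
        if moved < cfg.center_tol_mm:
            break

    # resolve in-plane slack: recentre on the connected lumen region centroid
    lumen = np.abs(image - ref) <= cfg.hu_tolerance
    labels, _ = cc_label(lumen)
    ci, cj = np.clip((np.round(center / spacing)).astype(int), 0, np.array(image.shape) - 1)
    comp = labels[ci, cj]
    if comp > 0:
        ii, jj = np.nonzero(labels == comp)
        pts = np.column_stack([ii * spacing[0], jj * spacing[1]])
        near = np.linalg.norm(pts - center, axis=1) <= max(3.0 * r, 5.0)
        if near.any():
            new_center = pts[near].mean(axis=0)
            r = shrink(new_center, r)
            r = grow(new_center, r)
            center = new_center
    if r < float(min(spacing)):
        raise DegenerateLumenError(f"inscribed circle collapsed (r = {r:.2f} mm)")
    return center, _refine_radius(image, spacing, center, r, ref, cfg, units)


def _refine_radius(
    image: np.ndarray,
    spacing: np.ndarray,
    center: np.ndarray,
    r: float,
    ref: float,
    cfg: TrackingConfig,
    units: np.ndarray,
) -> float:
    """Subpixel radius: median over rays of the half-maximum edge crossing.

    Each ray's lumen edge is located where the profile falls halfway between
    the lumen reference and the local outside value (full-width-half-maximum
    sizing), with linear sub-sample interpolation.  This removes the
    half-step/digitisation bias of the grow-and-stop rule and is robust to
    the interpolation blur of oblique reslices; the median is robust to the
    few rays that leave the section through its elongated direction.
    """
    step = 0.1 * float(min(spacing))
    t_lo = max(r - 3.0, float(min(spacing)))
    ts = np.arange(t_lo, r + 4.0, step)
    pts = center[None, None, :] + ts[None, :, None] * units[:, None, :]
    vals = _sample2d(image, pts.reshape(-1, 2), spacing).reshape(len(units), len(ts))
    inside = np.abs(vals - ref) <= cfg.hu_tolerance
    first_out = np.argmin(inside, axis=1)  # 0 when the ray never leaves
    crossings = np.full(len(units), ts[-1])
    for i in np.nonzero(~inside.all(axis=1))[0]:
        k = first_out[i]
        # local outside level ~1 voxel beyond the lumen-band exit
        k_out = min(k + int(round(1.0 / step * float(min(spacing)))), len(ts) - 1)
        half = 0.5 * (ref + vals[i, k_out])
        prof = vals[i, : k_out + 1]
        below = np.nonzero(prof <= half)[0] if ref > half else np.nonzero(prof >= half)[0]
        if below.size == 0 or below[0] == 0:
            crossings[i] = ts[max(k - 1, 0)]
            continue
        j = below[0]
        v0, v1 = prof[j - 1], prof[j]
        frac = (half - v0) / (v1 - v0) if v1 != v0 else 0.5
        crossings[i] = ts[j - 1] + frac * step
    return float(np.median(crossings))


# -- oblique reslicing -----------------------------------------------------


@dataclass
class PlaneImage:
    """A 2-D multiplanar reformation with its world geometry."""

    data: np.ndarray
    spacing: np.ndarray           # (2,) mm/pixel
    corner: np.ndarray            # world position of pixel (0, 0)
    e1: np.ndarray                # unit in-plane axes
    e2: np.ndarray
    normal: np.ndarray = field(default=None)  # type: ignore[assignment]

    def to_world(self, uv_mm: np.ndarray) -> np.ndarray:
        uv = np.asarray(uv_mm, dtype=float)
        return self.corner + uv[..., 0, None] * self.e1 + uv[..., 1, None] * self.e2 \
            if uv.ndim > 1 else self.corner + uv[0] * self.e1 + uv[1] * self.e2


def reslice_oblique(
    volume: CTVolume,
    origin: np.ndarray,
    e1: np.ndarray,
    e2: np.ndarray,
    size_mm: float,
    pixel_mm: float,
) -> PlaneImage:
    """Trilinear reslice of ``volume`` on the plane through ``origin`` spanned by e1/e2.

    The returned image is a ``size_mm`` x ``size_mm`` window centred on
    ``origin``; positions outside the grid read as a large negative sentinel.
    """
    e1 = np.asarray(e1, dtype=float)
    e2 = np.asarray(e2, dtype=float)
    n = np.cross(e1, e2)
    if np.linalg.norm(n) < 1e-8:
        raise ValueError("degenerate (parallel) in-plane axes")
    e1 = e1 / np.linalg.norm(e1)
    e2 = e2 / np.linalg.norm(e2)
    n = n / np.linalg.norm(n)
    npix = int(round(size_mm / pixel_mm)) + 1
    uv = (np.arange(npix) - (npix - 1) / 2.0) * pixel_mm
    world = (
        np.asarray(origin, dtype=float)[None, None, :]
        + uv[:, None, None] * e1[None, None, :]
        + uv[None, :, None] * e2[None, None, :]
    )
    vox = (world - volume.origin) / volume.spacing
    samples = map_coordinates(
        volume.data,
        [vox[..., 0], vox[..., 1], vox[..., 2]],
        order=1,
        mode="constant",
        cval=_SENTINEL,
    )
    corner = np.asarray(origin, dtype=float) + uv[0] * e1 + uv[0] * e2
    return PlaneImage(samples, np.array([pixel_mm, pixel_mm]), corner, e1, e2, n)


# -- tracking --------------------------------------------------------------


def _perp_axis(t: np.ndarray) -> np.ndarray:
    """A unit vector perpendicular to ``t`` (least-aligned coordinate axis)."""
    a = np.zeros(3)
    a[np.argmin(np.abs(t))] = 1.0
    e = np.cross(t, a)
    return e / np.linalg.norm(e)


def track_descending(
    volume: CTVolume, start: np.ndarray, cfg: TrackingConfig
) -> list[CenterlinePoint]:
    """Axial-slice circle tracking from ``start`` downward to the volume bottom.

    The circle centre found in each slice seeds the next slice below.  Points
    are returned top-first (tracking order).  Stops with a
    :class:`TruncationWarning` where inscription first fails (typically at the
    end of the vessel).
    """
    start = np.asarray(start, dtype=float)
    k0 = int(round((start[2] - volume.origin[2]) / volume.spacing[2]))
    k0 = min(max(k0, 0), volume.shape[2] - 1)
    sp2 = volume.spacing[:2]
    seed2 = start[:2] - volume.origin[:2]
    points: list[CenterlinePoint] = []
    for k in range(k0, -1, -1):
        try:
            c2, r = inscribe_circle(volume.data[:, :, k], sp2, seed2, cfg)
        except (SeedError, DegenerateLumenError) as exc:
            if k < k0:
                warnings.warn(
                    f"axial tracking truncated at slice {k} "
                    f"(last success {k + 1}): {exc}",
                    TruncationWarning,
                    stacklevel=2,
                )
            else:
                raise
            break
        pos = np.array([c2[0] + volume.origin[0], c2[1] + volume.origin[1],
                        volume.origin[2] + k * volume.spacing[2]])
        points.append(CenterlinePoint(pos, 2 * r, np.array([0.0, 0.0, 1.0]), "axial"))
        seed2 = c2
    return points


def track_arch(
    volume: CTVolume,
    seed_ascending: np.ndarray,
    seed_descending: np.ndarray,
    cfg: TrackingConfig,
) -> tuple[list[CenterlinePoint], np.ndarray]:
    """Oblique-plane tracking along a semitoroidal path over the arch.

    Planes are generated at angles 0°, step, ..., span (endpoint inclusive)
    around a horizontal axis through the midpoint of the two seeds; 0° is the
    axial plane at the ascending seed and 180° the axial plane at the
    descending seed.  Each plane is resliced by trilinear interpolation and
    the previous circle centre (projected into the new plane) seeds the next
    inscription.  Returns the tracked points and their sweep angles.
    """
    ca = np.asarray(seed_ascending, dtype=float)
    cd = np.asarray(seed_descending, dtype=float)
    chord = cd - ca
    chord[2] = 0.0
    half = float(np.linalg.norm(chord)) / 2.0
    if half < 1e-6:
        raise SeedError("seed points coincide in-plane")
    u = chord / (2 * half)
    zhat = np.array([0.0, 0.0, 1.0])
    e_axis = np.cross(zhat, u)  # horizontal rotation axis direction
    mid = (ca + cd) / 2.0
    pix = cfg.plane_pixel_mm or float(min(volume.spacing[:2]))

    thetas_deg = np.arange(0.0, cfg.angular_span_deg + cfg.angular_step_deg / 2,
                           cfg.angular_step_deg)
    def path_point(th: float) -> np.ndarray:
        return mid - half * math.cos(th) * u + half * math.sin(th) * zhat

    points: list[CenterlinePoint] = []
    kept_thetas: list[float] = []
    prev_center = ca.copy()
    prev_th = 0.0
    for th_deg in thetas_deg:
        th = math.radians(th_deg)
        normal = math.sin(th) * u + math.cos(th) * zhat
        # advance the plane by the semitoroidal path increment, anchored at
        # the circle centre found in the previous plane: the sweep follows
        # the schedule while staying on the vessel even when the true arch
        # is not a perfect torus around the seed midpoint
        origin = prev_center + path_point(th) - path_point(prev_th)
        e1 = e_axis
        e2 = np.cross(normal, e1)
        plane = reslice_oblique(volume, origin, e1, e2, cfg.plane_size_mm, pix)
        half_uv = (plane.data.shape[0] - 1) / 2.0 * pix
        try:
            c2, r = inscribe_circle(plane.data, plane.spacing,
                                    np.array([half_uv, half_uv]), cfg)
        except (SeedError, DegenerateLumenError) as exc:
            if th_deg > 0:
                warnings.warn(
                    f"arch tracking truncated at {th_deg:.0f}°: {exc}",
                    TruncationWarning,
                    stacklevel=2,
                )
            else:
                raise
            break
        pos = plane.corner + c2[0] * plane.e1 + c2[1] * plane.e2
        if not volume.contains_world(pos):
            warnings.warn(
                f"arch path left the volume at {th_deg:.0f}°", TruncationWarning, stacklevel=2
            )
            break
        points.append(CenterlinePoint(pos, 2 * r, normal, "oblique"))
        kept_thetas.append(th_deg)
        prev_center = pos
        prev_th = th
    return points, np.asarray(kept_thetas)


# -- merging and correction ------------------------------------------------


def _merge_tracks(
    ascending: list[CenterlinePoint],
    arch: list[CenterlinePoint],
    arch_thetas: np.ndarray,
    descending: list[CenterlinePoint],
    axial_spacing: float,
) -> list[CenterlinePoint]:
    """Concatenate the three tracks proximal -> distal.

    Where the oblique sweep (beyond 180°) overlaps the axial descending
    track, each oblique point is kept only if its plane is more perpendicular
    to the local tangent (estimated from the axial track) than an axial plane
    would be; for a near-vertical descending aorta the axial points win.
    """
    merged: list[CenterlinePoint] = list(reversed(ascending))
    desc_pos = np.array([p.position for p in descending]) if descending else None

    def local_tangent_desc(z: float) -> np.ndarray:
        k = int(np.argmin(np.abs(desc_pos[:, 2] - z)))
        k2 = min(k + 1, len(descending) - 1)
        k1 = max(k - 1, 0)
        t = desc_pos[k1] - desc_pos[k2]  # proximal -> distal is downward
        nrm = np.linalg.norm(t)
        return t / nrm if nrm > 0 else np.array([0.0, 0.0, -1.0])

    for pt, th in zip(arch, arch_thetas):
        if merged and np.linalg.norm(pt.position - merged[-1].position) < 0.25 * axial_spacing:
            continue  # duplicate of the seed-level axial plane
        if th > 180.0 and desc_pos is not None and pt.position[2] <= desc_pos[0, 2]:
            t = local_tangent_desc(pt.position[2])
            if abs(np.dot(pt.normal, t)) <= abs(t[2]):
                continue  # an axial plane is at least as perpendicular here
        merged.append(pt)
    for pt in descending:
        if merged and np.linalg.norm(pt.position - merged[-1].position) < 0.25 * axial_spacing:
            continue
        merged.append(pt)
    return merged


def perpendicular_correction(
    centerline: Centerline, volume: CTVolume, cfg: TrackingConfig
) -> Centerline:
    """Re-measure every cross-section in the plane orthogonal to the local tangent.

    Tangents come from the smoothed polyline; each point is re-resliced and
    re-inscribed (seeded at its current position).  Where re-inscription
    fails the prior estimate is kept.  Output normals equal the tangents, so
    |normal · tangent| = 1 everywhere.
    """
    pos = centerline.positions
    if len(pos) < 3:
        return centerline
    w = min(cfg.smooth_window, len(pos))
    smooth = uniform_filter1d(pos, size=w, axis=0, mode="nearest")
    arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(smooth, axis=0), axis=1))])
    arc = arc + 1e-9 * np.arange(len(arc))  # guard strictly-increasing for gradient
    tangents = np.gradient(smooth, arc, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    pix = cfg.plane_pixel_mm or float(min(volume.spacing[:2]))
    new_points: list[CenterlinePoint] = []
    for i, p in enumerate(centerline.points):
        t = tangents[i]
        e1 = _perp_axis(t)
        e2 = np.cross(t, e1)
        try:
            plane = reslice_oblique(volume, p.position, e1, e2, cfg.plane_size_mm, pix)
            half_uv = (plane.data.shape[0] - 1) / 2.0 * pix
            c2, r = inscribe_circle(plane.data, plane.spacing,
                                    np.array([half_uv, half_uv]), cfg)
            newpos = plane.corner + c2[0] * plane.e1 + c2[1] * plane.e2
            new_points.append(CenterlinePoint(newpos, 2 * r, t.copy(), p.plane_kind))
        except (SeedError, DegenerateLumenError, ValueError) as exc:
            warnings.warn(
                f"perpendicular correction kept prior estimate at point {i}: {exc}",
                TruncationWarning,
                stacklevel=2,
            )
            new_points.append(CenterlinePoint(p.position.copy(), p.diameter, t.copy(),
                                              p.plane_kind))
    # drop any point that does not advance along the path
    cleaned = [new_points[0]]
    for p in new_points[1:]:
        if np.linalg.norm(p.position - cleaned[-1].position) > 1e-9:
            cleaned.append(p)
    return Centerline(cleaned)


def extract_centerline(
    volume: CTVolume,
    seed_ascending: np.ndarray,
    seed_descending: np.ndarray,
    cfg: TrackingConfig | None = None,
) -> Centerline:
    """Full centerline, proximal (ascending root) -> distal (diaphragm).

    Orchestrates: axial tracking down the ascending aorta from ``C_A``,
    oblique semitoroidal tracking over the arch, axial tracking down the
    descending aorta from ``C_D``, merge/de-duplication, and the
    perpendicularity correction.
    """
    cfg = cfg or TrackingConfig()
    asc = track_descending(volume, seed_ascending, cfg)
    arch, thetas = track_arch(volume, seed_ascending, seed_descending, cfg)
    desc = track_descending(volume, seed_descending, cfg)
    merged = _merge_tracks(asc, arch, thetas, desc, float(volume.spacing[2]))
    # two correction passes: the first fixes positions (and hence tangents),
    # the second re-measures diameters in planes orthogonal to the improved
    # tangents; further passes change nothing within tolerance
    corrected = perpendicular_correction(Centerline(merged), volume, cfg)
    return perpendicular_correction(corrected, volume, cfg)
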