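"""Calcified-lesion detection, Agatston scoring and segment assignment.

Candidates are 26-connected 3-D components of voxels at or above 130 HU with
at least 1 mm² of area in some axial slice.  Manual per-slice validation is
replaced by a geometric surrogate: a candidate is accepted when its centroid
lies within ``margin`` x the local lumen radius of the centerline, which
keeps aortic wall calcium and rejects spine, ribs and coronary calcium away
from the aortic root.  Scores follow the classical Agatston rule — per-slice
area (mm²) times a 1-4 weight set by the slice peak HU — with no
slice-thickness rescaling (scores are reported on the native slices).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .anatomy import SegmentMap
from .centerline import Centerline
from .volume import CTVolume

__all__ = [
    "Lesion",
    "ScoreTable",
    "CALCIUM_THRESHOLD_HU",
    "MIN_LESION_AREA_MM2",
    "detect_candidates",
    "validate_lesions",
    "agatston_score",
    "density_weight",
    "assign_segment",
    "accumulate_scores",
]

CALCIUM_THRESHOLD_HU = 130.0
MIN_LESION_AREA_MM2 = 1.0


def density_weight(peak_hu: float) -> int:
    """Agatston density factor of a slice from its peak attenuation."""
    if peak_hu >= 400:
        return 4
    if peak_hu >= 300:
        return 3
    if peak_hu >= 200:
        return 2
    return 1


@dataclass
class Lesion:
    """One connected calcified component."""

    lesion_id: int
    voxels: tuple[np.ndarray, np.ndarray, np.ndarray]  # index arrays (i, j, k)
    slice_areas: dict[int, float]       # axial index -> area (mm²)
    slice_peaks: dict[int, float]       # axial index -> peak HU
    centroid: np.ndarray                # world mm
    peak_hu: float
    score: float = 0.0
    state: str = "candidate"            # candidate | accepted | rejected
    segment: int | None = None

    @property
    def n_voxels(self) -> int:
        return int(self.voxels[0].size)

    @property
    def max_slice_area(self) -> float:
        return max(self.slice_areas.values())


@dataclass
class ScoreTable:
    """Per-segment accumulated Agatston scores and lesion counts."""

    segment_scores: np.ndarray = field(default_factory=lambda: np.zeros(5))
    segment_counts: np.ndarray = field(default_factory=lambda: np.zeros(5, dtype=int))

    @property
    def total(self) -> float:
        return float(self.segment_scores.sum())

    @property
    def standard_total(self) -> float:
        """Score over the segments a standard cardiac scan covers (1 and 5)."""
        return float(self.segment_scores[0] + self.segment_scores[4])


def detect_candidates(volume: CTVolume) -> list[Lesion]:
    """All 26-connected components >= 130 HU with >= 1 mm² in some axial slice."""
    mask = volume.data >= CALCIUM_THRESHOLD_HU
    if not mask.any():
        return []
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
    px_area = float(volume.spacing[0] * volume.spacing[1])
    out: list[Lesion] = []
    objects = ndimage.find_objects(labels)
    lesion_id = 0
    for comp, slc in enumerate(objects, start=1):
        sub = labels[slc] == comp
        idx = np.nonzero(sub)
        vox = tuple(idx[a] + slc[a].start for a in range(3))
        ks, counts = np.unique(vox[2], return_counts=True)
        areas = {int(k): float(c * px_area) for k, c in zip(ks, counts)}
        if max(areas.values()) < MIN_LESION_AREA_MM2:
            continue
        hu = volume.data[vox]
        peaks = {int(k): float(hu[vox[2] == k].max()) for k in ks}
        centroid = volume.voxel_to_world(np.column_stack(vox).mean(axis=0))
        lesion = Lesion(
            lesion_id=lesion_id,
            voxels=vox,
            slice_areas=areas,
            slice_peaks=peaks,
            centroid=centroid,
            peak_hu=float(hu.max()),
        )
        lesion.score = agatston_score(lesion, volume.spacing)
        out.append(lesion)
        lesion_id += 1
    return out


def agatston_score(lesion: Lesion, spacing: np.ndarray) -> float:
    """Sum over axial slices of slice area (mm²) x density weight of the slice peak."""
    return float(
        sum(
            area * density_weight(lesion.slice_peaks[k])
            for k, area in lesion.slice_areas.items()
        )
    )


def validate_lesions(
    candidates: list[Lesion],
    centerline: Centerline,
    margin: float = 1.5,
) -> list[Lesion]:
    """Accept candidates whose centroid lies within ``margin`` x local radius.

    The local radius is the lumen radius at the nearest centerline point.
    Returns the accepted lesions; every candidate's ``state`` is updated in
    place.
    """
    accepted: list[Lesion] = []
    for lesion in candidates:
        i, _, dist = centerline.nearest(lesion.centroid)
        radius = centerline.diameters[i] / 2.0
        if dist <= margin * radius:
            lesion.state = "accepted"
            accepted.append(lesion)
        else:
            lesion.state = "rejected"
    return accepted


def assign_segment(
    lesion: Lesion, centerline: Centerline, segment_map: SegmentMap
) -> int:
    """Segment containing the orthogonal projection of the lesion centroid.

    The centroid projects to the nearest centerline point; the arc length of
    that point selects the segment (boundary hits go to the distal segment).
    Projections proximal of the first or distal of the last boundary clamp to
    the terminal segments with a warning.
    """
    _, arc, _ = centerline.nearest(lesion.centroid)
    b = segment_map.boundaries
    if arc < b[0] or arc > b[5]:
        warnings.warn(
            f"lesion {lesion.lesion_id} projects outside the segmented range "
            f"(arc {arc:.1f} mm); clamped to the terminal segment",
            stacklevel=2,
        )
    lesion.segment = segment_map.segment_of(arc)
    return lesion.segment


def accumulate_scores(lesions: list[Lesion], segment_map: SegmentMap) -> ScoreTable:
    """Per-segment sums and counts over assigned, accepted lesions."""
    table = ScoreTable()
    for lesion in lesions:
        if lesion.segment is None:
            raise ValueError(f"lesion {lesion.lesion_id} has no assigned segment")
        table.segment_scores[lesion.segment - 1] += lesion.score
        table.segment_counts[lesion.segment - 1] += 1
    return table


def lesion_table(lesions: list[Lesion], volume: CTVolume):
    """Flat per-lesion table (for CSV export)."""
    import pandas as pd

    voxel_vol = float(np.prod(volume.spacing))
    rows = []
    for l in lesions:
        rows.append(
            {
                "lesion_id": l.lesion_id,
                "n_voxels": l.n_voxels,
                "volume_mm3": l.n_voxels * voxel_vol,
                "peak_hu": l.peak_hu,
                "agatston": l.score,
                "segment_id": l.segment if l.segment is not None else -1,
                "centroid_x": l.centroid[0],
                "centroid_y": l.centroid[1],
                "centroid_z": l.centroid[2],
                "state": l.state,
            }
        )
    return pd.DataFrame(rows)
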