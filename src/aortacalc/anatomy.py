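"""Partition of the aortic centerline into the five thoracic segments.

Four user landmarks bound the segments: the left main coronary artery (LMCA)
marks the proximal terminus, the right and left subclavian arteries (RSA,
LSA) bound the arch, and the coronary sinus (CS) axial level — projected onto
the descending limb — separates the proximal from the distal descending
aorta.  The seed-pair axial level splits the ascending aorta, so segments 1
and 5 coincide with the coverage of a standard (non-extended) cardiac scan:
segment 1 = proximal ascending, 2 = distal ascending, 3 = arch,
4 = proximal descending, 5 = distal descending.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .centerline import Centerline

__all__ = [
    "LandmarkSet",
    "SegmentMap",
    "SegmentationError",
    "project_landmark",
    "divide_segments",
    "segment_lengths",
    "STANDARD_SEGMENTS",
    "EXTENDED_ONLY_SEGMENTS",
]

#: Segments visible on a standard cardiac scan vs. only on the extended scan.
STANDARD_SEGMENTS = (1, 5)
EXTENDED_ONLY_SEGMENTS = (2, 3, 4)

_LANDMARK_WARN_MM = 50.0


class SegmentationError(ValueError):
    """Landmark projections do not yield a valid proximal->distal partition."""


@dataclass
class LandmarkSet:
    """World-mm positions of the four anatomical landmarks."""

    LMCA: np.ndarray
    RSA: np.ndarray
    LSA: np.ndarray
    CS: np.ndarray

    def __post_init__(self) -> None:
        for name in ("LMCA", "RSA", "LSA", "CS"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))

    @classmethod
    def from_dict(cls, d: dict) -> "LandmarkSet":
        return cls(LMCA=d["LMCA"], RSA=d["RSA"], LSA=d["LSA"], CS=d["CS"])


@dataclass
class SegmentMap:
    """Five contiguous arc-length intervals tiling the centerline.

    ``boundaries`` holds the six interval edges in mm (proximal terminus,
    1|2, 2|3, 3|4, 4|5, distal terminus).  Intervals are half-open, closed at
    their proximal edge; an arc length exactly on an interior boundary
    belongs to the distal segment.
    """

    boundaries: np.ndarray  # (6,) arc lengths, mm

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        if self.boundaries.shape != (6,):
            raise SegmentationError("a segment map needs exactly 6 boundaries")
        d = np.diff(self.boundaries)
        if np.any(d <= 0):
            i = int(np.argmax(d <= 0))
            raise SegmentationError(
                f"non-monotonic boundaries: edge {i} at {self.boundaries[i]:.2f} mm "
                f">= edge {i + 1} at {self.boundaries[i + 1]:.2f} mm"
            )

    @property
    def lengths_cm(self) -> np.ndarray:
        return np.diff(self.boundaries) / 10.0

    def segment_of(self, arc_mm: float) -> int:
        """Segment id (1-5) containing ``arc_mm``; boundary hits go distal."""
        s = int(np.searchsorted(self.boundaries[1:5], arc_mm, side="right")) + 1
        return min(max(s, 1), 5)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "segment_id": np.arange(1, 6),
                "start_mm": self.boundaries[:-1],
                "end_mm": self.boundaries[1:],
                "length_cm": self.lengths_cm,
            }
        )


def project_landmark(centerline: Centerline, point: np.ndarray) -> float:
    """Arc length of the centerline point nearest ``point`` (ties -> proximal)."""
    _, arc, dist = centerline.nearest(point)
    if dist > _LANDMARK_WARN_MM:
        warnings.warn(
            f"landmark {np.asarray(point)} is {dist:.0f} mm from the centerline "
            "(implausible placement)",
            stacklevel=2,
        )
    return arc


def _arc_at_axial_level(centerline: Centerline, z_mm: float, limb: str) -> float:
    """Arc length where the given limb of the centerline crosses axial level z.

    The limb split is at the arch apex (the most superior point): points
    before it form the ascending limb, after it the descending limb.
    """
    apex = int(np.argmax(centerline.positions[:, 2]))
    if limb == "ascending":
        idx = np.arange(0, apex + 1)
    else:
        idx = np.arange(apex, len(centerline))
    zs = centerline.positions[idx, 2]
    return float(centerline.arc[idx[np.argmin(np.abs(zs - z_mm))]])


def divide_segments(
    centerline: Centerline,
    landmarks: LandmarkSet,
    seed_level_z: float,
) -> SegmentMap:
    """Partition the centerline into the five thoracic segments.

    Boundaries, proximal to distal: LMCA projection (start), the seed-pair
    axial level on the ascending limb (1|2), the RSA projection (2|3), the
    LSA projection (3|4), the CS axial level on the descending limb (4|5),
    and the distal terminus (end).
    """
    start = project_landmark(centerline, landmarks.LMCA)
    b12 = _arc_at_axial_level(centerline, seed_level_z, "ascending")
    b23 = project_landmark(centerline, landmarks.RSA)
    b34 = project_landmark(centerline, landmarks.LSA)
    b45 = _arc_at_axial_level(centerline, float(landmarks.CS[2]), "descending")
    end = centerline.total_length
    return SegmentMap(np.array([start, b12, b23, b34, b45, end]))


def segment_lengths(segment_map: SegmentMap) -> np.ndarray:
    """The five segment lengths in cm (the per-cm normalizer for lesion density)."""
    return segment_map.lengths_cm
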