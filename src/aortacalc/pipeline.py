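"""End-to-end driver: phantoms -> centerlines -> segments -> scores -> cohort report.

The pipeline is deterministic under a fixed seed: every stage's randomness
derives from ``PipelineConfig.seed``, and a manifest with SHA-256 hashes of
all written tables plus the configuration hash is emitted so two runs of the
same config can be compared byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .anatomy import LandmarkSet, SegmentMap, divide_segments
from .centerline import Centerline, CenterlinePoint, TrackingConfig, extract_centerline
from .cohort import (
    age_tertile_prevalence,
    classify_group,
    derive_tac,
    detection_overlap,
    lesion_distribution,
    prevalence_by_segment,
)
from .lesions import accumulate_scores, assign_segment, detect_candidates, lesion_table, validate_lesions
from .phantom import default_phantom_spec, place_wall_lesion, generate_phantom
from .synthcohort import SEGMENT_COLUMNS, CohortSpec, generate_cohort
from .volume import CTVolume, read_volume

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "score_volume",
    "write_centerline_csv",
    "read_centerline_csv",
    "write_segment_csv",
    "read_segment_csv",
]

log = logging.getLogger("aortacalc")


@dataclass
class PipelineConfig:
    """Run configuration; round-trips losslessly through YAML."""

    out_dir: str = "aortacalc_out"
    n_subjects: int = 10
    grid_shape: tuple[int, int, int] = (128, 128, 64)
    grid_spacing: tuple[float, float, float] = (1.0, 1.0, 2.5)
    noise_sd: float = 5.0
    n_lesions_range: tuple[int, int] = (1, 6)
    lesion_hu_range: tuple[float, float] = (150.0, 900.0)
    validation_margin: float = 1.5
    tracking: dict = field(default_factory=dict)
    volumes: list = field(default_factory=list)  # optional: [{volume, seeds, landmarks}]
    seed: int = 0
    version: str = ""

    def __post_init__(self) -> None:
        if not self.version:
            self.version = __version__

    def tracking_config(self) -> TrackingConfig:
        return TrackingConfig(**self.tracking)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("grid_shape", "grid_spacing", "n_lesions_range", "lesion_hu_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate_paths(self) -> None:
        for entry in self.volumes:
            for key in ("volume", "seeds"):
                p = entry.get(key)
                if p and not Path(p).exists():
                    raise FileNotFoundError(f"configured {key} path does not exist: {p}")


# -- table I/O -------------------------------------------------------------


def write_centerline_csv(centerline: Centerline, path: str | Path) -> None:
    centerline.to_dataframe().to_csv(path, index=False)


def read_centerline_csv(path: str | Path) -> Centerline:
    df = pd.read_csv(path)
    pts = [
        CenterlinePoint(
            position=np.array([r.x_mm, r.y_mm, r.z_mm]),
            diameter=float(r.diameter_mm),
            normal=np.array([r.nx, r.ny, r.nz]),
            plane_kind=str(r.plane_kind),
        )
        for r in df.itertuples()
    ]
    return Centerline(pts)


def write_segment_csv(segment_map: SegmentMap, path: str | Path) -> None:
    segment_map.to_dataframe().to_csv(path, index=False)


def read_segment_csv(path: str | Path) -> SegmentMap:
    df = pd.read_csv(path)
    boundaries = np.concatenate([df["start_mm"].to_numpy(), df["end_mm"].to_numpy()[-1:]])
    return SegmentMap(boundaries)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# -- per-volume scoring ----------------------------------------------------


def score_volume(
    volume: CTVolume,
    seed_ascending: np.ndarray,
    seed_descending: np.ndarray,
    landmarks: LandmarkSet,
    cfg: TrackingConfig | None = None,
    margin: float = 1.5,
):
    """Centerline + segments + validated, assigned, accumulated lesion scores."""
    cfg = cfg or TrackingConfig()
    centerline = extract_centerline(volume, seed_ascending, seed_descending, cfg)
    segment_map = divide_segments(centerline, landmarks, float(seed_ascending[2]))
    candidates = detect_candidates(volume)
    accepted = validate_lesions(candidates, centerline, margin=margin)
    for lesion in accepted:
        assign_segment(lesion, centerline, segment_map)
    table = accumulate_scores(accepted, segment_map)
    return centerline, segment_map, candidates, table


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full synthetic study and write its report bundle.

    Per subject: generate a phantom with randomized wall lesions, extract the
    centerline from the ground-truth seed pair, partition it with the
    ground-truth landmarks, detect/validate/score lesions, and accumulate
    per-segment scores.  Covariates come from the stochastic cohort
    generator; imaging-derived segment scores replace the sampled ones before
    the population summary is computed.
    """
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    cfg = config.tracking_config()

    subject_rows = []
    lesion_frames = []
    seg_length_rows = []
    for i in range(config.n_subjects):
        t0 = time.time()
        sub_seed = int(rng.integers(0, 2**31 - 1))
        sub_rng = np.random.default_rng(sub_seed)
        spec = default_phantom_spec(
            shape=config.grid_shape,
            spacing=config.grid_spacing,
            noise_sd=config.noise_sd,
            seed=sub_seed,
        )
        n_lesions = int(sub_rng.integers(config.n_lesions_range[0],
                                         config.n_lesions_range[1] + 1))
        boundaries = spec.segment_boundaries()
        margin_mm = 6.0
        for _ in range(n_lesions):
            seg = int(sub_rng.integers(0, 5))
            lo, hi = boundaries[seg] + margin_mm, boundaries[seg + 1] - margin_mm
            if hi <= lo:
                continue
            spec.lesions.append(
                place_wall_lesion(
                    spec,
                    arc_s=float(sub_rng.uniform(lo, hi)),
                    angle_deg=float(sub_rng.uniform(0, 360)),
                    hu=float(sub_rng.uniform(*config.lesion_hu_range)),
                )
            )
        volume, gt = generate_phantom(spec)
        centerline, segment_map, candidates, table = score_volume(
            volume,
            gt.seeds["C_A"],
            gt.seeds["C_D"],
            LandmarkSet.from_dict(gt.landmarks),
            cfg,
            margin=config.validation_margin,
        )
        lf = lesion_table(candidates, volume)
        lf.insert(0, "subject", i)
        lesion_frames.append(lf)
        seg_length_rows.append(segment_map.lengths_cm)
        row = {"subject": i, "n_points": len(centerline),
               "n_lesions_true": len(spec.lesions),
               "n_lesions_detected": len(candidates)}
        for s in range(5):
            row[SEGMENT_COLUMNS[s]] = float(table.segment_scores[s])
        subject_rows.append(row)
        log.info("subject %d: %d centerline points, %d lesions, %.1f s",
                 i, len(centerline), len(candidates), time.time() - t0)

    imaging = pd.DataFrame(subject_rows)
    covars = generate_cohort(
        CohortSpec(n=config.n_subjects, mode="stochastic", seed=config.seed)
    ).drop(columns=SEGMENT_COLUMNS)
    cohort = covars.join(imaging.set_index("subject"), on="id")
    cohort = derive_tac(cohort)
    cohort["group"] = classify_group(cohort)

    mean_lengths = np.mean(np.vstack(seg_length_rows), axis=0)
    lesions_all = pd.concat(lesion_frames, ignore_index=True) if lesion_frames else pd.DataFrame()
    seg_counts = np.array([
        int((lesions_all["segment_id"] == s).sum()) if len(lesions_all) else 0
        for s in range(1, 6)
    ])

    cohort.to_csv(out / "cohort.csv", index=False)
    lesions_all.to_csv(out / "lesions.csv", index=False)
    prevalence_by_segment(cohort).to_csv(out / "segment_prevalence.csv", index=False)
    lesion_distribution(seg_counts, mean_lengths).to_csv(out / "lesion_distribution.csv",
                                                         index=False)
    if config.n_subjects >= 3:
        age_tertile_prevalence(cohort).to_csv(out / "age_tertile_prevalence.csv", index=False)
    summary = detection_overlap(cohort)
    summary["mean_segment_lengths_cm"] = [float(x) for x in mean_lengths]
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))

    config_text = yaml.safe_dump(dataclasses.asdict(config))
    manifest = {
        "version": config.version,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "tables": {p.name: _sha256(p) for p in sorted(out.glob("*.csv"))},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {"cohort": cohort, "lesions": lesions_all, "summary": summary,
            "manifest": manifest, "out_dir": str(out)}
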