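"""End-to-end orchestration: video file(s) in, kinematic features out.

Per clip the stages run in a fixed order: read, trim to the first five
seconds, stabilize, optionally resize, face ROI (per-frame detection +
union box), mouth ROI inside the face crop, tongue segmentation, and the
kinematic reduction.  Quality rejections (face lost in too many frames,
no usable tongue locations) exclude the clip with a recorded reason but
never abort a batch -- mirroring how poor clips are excluded rather than
repaired in practice.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import roi as _roi
from . import segmentation as _seg
from . import stats as _stats
from . import video as _video
from .fixtures import load_ground_truth
from .kinematics import KinematicsParams, SweepProfile, UnusableVideoError
from .kinematics import locate_tongue, profile

__all__ = [
    "RunConfig",
    "ClipResult",
    "process_clip",
    "run_pipeline",
    "run_report",
    "load_reference_samples",
    "load_clinical_records",
]

log = logging.getLogger(__name__)

PROFILE_COLUMNS = [
    "video_id", "n_sweeps", "mean_sweep_duration_s", "n_errors",
    "n_runs", "n_undetected_frames", "fps",
]


@dataclass(frozen=True)
class RunConfig:
    """Settings for a pipeline run."""

    inputs: tuple[str, ...]
    out_dir: str
    mode: str = "batch"  # "single" or "batch"
    detector: str = "oracle"
    segmenter: str = "chroma"
    trim_duration_s: float | None = 5.0  # None or 0: keep full length
    target_height_px: int | None = None  # None: keep input resolution
    stabilization: _video.StabilizationParams = field(
        default_factory=_video.StabilizationParams
    )
    kinematics: KinematicsParams = field(default_factory=KinematicsParams)
    seed: int = 0
    skip_stabilization: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("single", "batch"):
            raise ValueError("mode must be 'single' or 'batch'")
        if self.mode == "single" and len(self.inputs) != 1:
            raise ValueError("single mode takes exactly one input video")
        if not self.inputs:
            raise ValueError("no input videos given")


@dataclass(frozen=True)
class ClipResult:
    video_id: str
    status: str  # "included" or "excluded"
    profile: SweepProfile | None = None
    reason: str = ""


def _make_segmenter(name: str) -> _seg.SegmentationBackend:
    if name == "chroma":
        return _seg.ChromaBackend()
    if name.startswith("external:"):
        return _seg.ExternalMaskBackend(name.split(":", 1)[1])
    raise ValueError(f"unknown segmentation backend: {name!r}")


def process_clip(
    path: str | Path,
    config: RunConfig,
    detector: _roi.DetectorBackend | None = None,
) -> SweepProfile:
    """Run the full per-clip pipeline; raises on quality rejection."""
    clip = _video.read_video(path)
    original_height = clip.height
    if config.trim_duration_s:
        clip = _video.trim_clip(clip, config.trim_duration_s)
    if not config.skip_stabilization:
        clip = _video.stabilize(clip, config.stabilization)
    if config.target_height_px is not None:
        clip = _video.standardize(clip, config.target_height_px)

    if detector is None:
        if config.detector != "oracle":
            raise ValueError(f"unknown detector backend: {config.detector!r}")
        truth = load_ground_truth(path)
        detector = _roi.OracleDetector(
            truth, scale=clip.height / original_height
        )

    face_track = _roi.detect_face_track(clip, detector)
    face_clip = _roi.extract_roi(clip, face_track.union)
    mouth_detector = (
        detector.for_face_crop(face_track.union)
        if hasattr(detector, "for_face_crop")
        else detector
    )
    mouth_track = _roi.detect_mouth_track(face_clip, mouth_detector)
    mouth_clip = _roi.extract_roi(face_clip, mouth_track.union)

    masks = _seg.segment_clip(mouth_clip, _make_segmenter(config.segmenter))
    record = locate_tongue(masks, config.kinematics.midline_frac)
    return profile(record, config.kinematics)


def run_pipeline(config: RunConfig) -> list[ClipResult]:
    """Process every input; write the profiles CSV and a JSON run report."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results: list[ClipResult] = []
    for path in config.inputs:
        vid = Path(path).stem
        try:
            prof = process_clip(path, config)
            results.append(ClipResult(vid, "included", prof))
            log.info("pipeline: %s included (%d sweeps)", vid, prof.n_sweeps)
        except (_roi.VideoQualityError, UnusableVideoError) as exc:
            results.append(ClipResult(vid, "excluded", None, str(exc)))
            log.warning("pipeline: %s excluded: %s", vid, exc)

    rows = [
        {
            "video_id": r.video_id,
            "n_sweeps": r.profile.n_sweeps,
            "mean_sweep_duration_s": (
                None
                if r.profile.mean_sweep_duration_s is None
                else round(r.profile.mean_sweep_duration_s, 4)
            ),
            "n_errors": r.profile.n_errors,
            "n_runs": r.profile.n_runs,
            "n_undetected_frames": r.profile.n_undetected_frames,
            "fps": r.profile.fps,
        }
        for r in results
        if r.profile is not None
    ]
    pd.DataFrame(rows, columns=PROFILE_COLUMNS).to_csv(
        out_dir / "profiles.csv", index=False
    )
    report = {
        "n_inputs": len(config.inputs),
        "n_included": sum(r.status == "included" for r in results),
        "n_excluded": sum(r.status == "excluded" for r in results),
        "excluded": [
            {"video_id": r.video_id, "reason": r.reason}
            for r in results
            if r.status == "excluded"
        ],
    }
    (out_dir / "run_report.json").write_text(json.dumps(report, indent=1))
    return results


def load_reference_samples(path: str | Path) -> pd.DataFrame:
    """Reference-group CSV: columns group, feature, mean, sd, n."""
    df = pd.read_csv(path)
    required = {"group", "feature", "mean", "sd", "n"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"reference CSV missing columns: {sorted(missing)}")
    return df


def load_clinical_records(path: str | Path) -> list[_stats.ClinicalRecord]:
    df = pd.read_csv(path)
    return [
        _stats.ClinicalRecord(
            patient_id=str(row.patient_id),
            alsfrs_r_total=float(row.alsfrs_r_total),
            alsfrs_r_bulbar=float(row.alsfrs_r_bulbar),
            cns_bfs=float(row.cns_bfs),
            disease_duration_months=float(row.disease_duration_months),
            onset_type=str(row.onset_type),
        )
        for row in df.itertuples()
    ]


def run_report(
    cases: pd.DataFrame,
    references: pd.DataFrame,
    group_comparisons: tuple[tuple[str, str], ...] = (("all_patients", "controls"),),
    alpha: float = 0.05,
    m_comparisons: int | None = None,
) -> pd.DataFrame:
    """Build a long-format statistics table.

    ``cases`` needs columns patient_id, comparison_group, feature, value:
    every row becomes a single-case t-test against the matching reference
    group.  ``group_comparisons`` adds pooled two-sample tests between
    reference-group summaries (skipped when either group is absent).
    The Bonferroni family size defaults to the number of single-case
    tests against the control group.
    """
    for col in ("patient_id", "comparison_group", "feature", "value"):
        if col not in cases.columns:
            raise ValueError(f"cases table missing column {col!r}")
    refs = references.set_index(["group", "feature"])

    if m_comparisons is None:
        m_comparisons = int((cases["comparison_group"] == "controls").sum()) or 1
    threshold = _stats.bonferroni_threshold(alpha, m_comparisons)

    rows = []
    for row in cases.itertuples():
        key = (row.comparison_group, row.feature)
        if key not in refs.index:
            raise ValueError(
                f"reference group/feature not found: {key[0]}/{key[1]}"
            )
        ref_row = refs.loc[key]
        ref = _stats.ReferenceSample(
            mean=float(ref_row["mean"]), sd=float(ref_row["sd"]),
            n=int(ref_row["n"]), feature_name=str(row.feature),
        )
        res = _stats.single_case_t(float(row.value), ref)
        rows.append(
            {
                "comparison": f"patient {row.patient_id} vs {row.comparison_group}",
                "feature": row.feature,
                "case_value": float(row.value),
                "reference_mean": ref.mean,
                "reference_sd": ref.sd,
                "df": res.df,
                "t": round(res.t, 4),
                "p": round(res.p_two_tailed, 4),
                "significant_uncorrected": res.p_two_tailed < alpha,
                "significant_bonferroni": res.p_two_tailed < threshold,
            }
        )

    groups = set(references["group"])
    for ga, gb in group_comparisons:
        if ga not in groups or gb not in groups:
            continue
        for feature in references.loc[references["group"] == ga, "feature"]:
            a = refs.loc[(ga, feature)]
            b = refs.loc[(gb, feature)]
            res = _stats.two_sample_pooled_t(
                (float(a["mean"]), float(a["sd"]), int(a["n"])),
                (float(b["mean"]), float(b["sd"]), int(b["n"])),
            )
            rows.append(
                {
                    "comparison": f"{ga} vs {gb}",
                    "feature": feature,
                    "case_value": float(a["mean"]),
                    "reference_mean": float(b["mean"]),
                    "reference_sd": float(b["sd"]),
                    "df": res.df,
                    "t": round(res.t, 4),
                    "p": round(res.p_two_tailed, 4),
                    "significant_uncorrected": res.p_two_tailed < alpha,
                    "significant_bonferroni": res.p_two_tailed < threshold,
                }
            )
    return pd.DataFrame(rows)
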