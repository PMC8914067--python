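"""tonguekin: tongue-movement kinematics from short video clips.

Quantifies bulbar (tongue) motor function from clips of the lateral
tongue-movement task: per-frame tongue side, dwell runs, sweep counts,
sweep durations and movement errors, plus single-case and group
statistics against normative reference samples.
"""

from importlib import resources as _resources

from .fixtures import GroundTruth, SyntheticSpec, apply_jitter, generate_clip
from .kinematics import (
    KinematicsParams,
    LocationRecord,
    Run,
    SweepProfile,
    UnusableVideoError,
    count_sweeps,
    detect_errors,
    locate_tongue,
    mean_sweep_duration,
    profile,
    run_length_encode,
)
from .pipeline import RunConfig, process_clip, run_pipeline, run_report
from .roi import Box, OracleDetector, RoiTrack, VideoQualityError, union_box
from .segmentation import ChromaBackend, ChromaParams, MaskSequence, segment_clip
from .stats import (
    ClinicalRecord,
    ReferenceSample,
    TestResult,
    bonferroni_threshold,
    classify_bulbar_impaired,
    disease_progression_rate,
    pearson_validation,
    single_case_t,
    two_sample_pooled_t,
)
from .video import FrameSequence, StabilizationParams, read_video, stabilize
from .video import standardize, trim_clip, write_video

__version__ = "0.1.0"


def example_data_path(name: str):
    """Path to a bundled example-cohort CSV (``control_reference.csv``,
    ``patient_features.csv`` or ``als_clinical_scores.csv``)."""
    return _resources.files("tonguekin.data").joinpath(name)
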