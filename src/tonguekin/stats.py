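"""Statistics for comparing tongue kinematics against a reference group.

Patient cohorts in bulbar-function studies are small, so the workhorse
comparison is the single-case t-test: one patient's feature value x
against a normative sample summarised by (mean, SD, n),

    t = (mean - x) / (SD / sqrt(n)),      df = n - 1,

two-tailed.  The sign convention is positive when the case falls *below*
the reference mean (fewer sweeps than controls gives positive t).  Whole
patient groups are compared with the classical pooled-variance
two-sample t-test.  Agreement between automated and manual sweep counts
is assessed with Pearson's r.  Clinical context comes from the revised
ALS Functional Rating Scale (ALSFRS-R, total 0-48, bulbar sub-score
0-12), the CNS Bulbar Function Scale (CNS-BFS), the disease progression
rate DPR = (48 - ALSFRS-R) / disease duration in months, and a
bulbar-impairment rule (bulbar sub-score <= 11 or CNS-BFS > 43).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "ReferenceSample",
    "TestResult",
    "ClinicalRecord",
    "single_case_t",
    "two_sample_pooled_t",
    "pearson_validation",
    "bonferroni_threshold",
    "disease_progression_rate",
    "classify_bulbar_impaired",
]


@dataclass(frozen=True)
class ReferenceSample:
    """Normative group summary: sample mean, sample (n-1) SD, group size."""

    mean: float
    sd: float
    n: int
    feature_name: str = ""

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n < 2:
            raise ValueError("reference sample needs n >= 2")


@dataclass(frozen=True)
class TestResult:
    t: float
    df: int
    p_two_tailed: float
    direction: int  # sign of (reference mean - case/group mean)

    def __post_init__(self) -> None:
        if self.df < 1:
            raise ValueError("df must be >= 1")
        if not 0.0 <= self.p_two_tailed <= 1.0:
            raise ValueError("p must lie in [0, 1]")


@dataclass(frozen=True)
class ClinicalRecord:
    """One patient's clinical scores."""

    patient_id: str
    alsfrs_r_total: float
    alsfrs_r_bulbar: float
    cns_bfs: float
    disease_duration_months: float
    onset_type: str  # "bulbar" or "limb"

    def __post_init__(self) -> None:
        if not 0 <= self.alsfrs_r_total <= 48:
            raise ValueError("ALSFRS-R total must be in [0, 48]")
        if not 0 <= self.alsfrs_r_bulbar <= 12:
            raise ValueError("ALSFRS-R bulbar sub-score must be in [0, 12]")
        if self.disease_duration_months <= 0:
            raise ValueError("disease duration must be positive (months)")
        if self.onset_type not in ("bulbar", "limb"):
            raise ValueError("onset_type must be 'bulbar' or 'limb'")


def _two_tailed_p(t: float, df: int) -> float:
    return float(2.0 * sps.t.sf(abs(t), df))


def single_case_t(x: float, ref: ReferenceSample) -> TestResult:
    """Two-tailed single-case t-test of one value against a normative sample."""
    if ref.sd == 0:
        raise ValueError("degenerate reference: sd is zero")
    t = (ref.mean - x) / (ref.sd / math.sqrt(ref.n))
    df = ref.n - 1
    return TestResult(
        t=t, df=df, p_two_tailed=_two_tailed_p(t, df),
        direction=int(np.sign(ref.mean - x)),
    )


def two_sample_pooled_t(
    group: tuple[float, float, int], reference: tuple[float, float, int]
) -> TestResult:
    """Pooled-variance two-sample t from (mean, sd, n) summaries."""
    m1, s1, n1 = group
    m2, s2, n2 = reference
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    if s1 == 0 and s2 == 0:
        raise ValueError("degenerate comparison: both SDs are zero")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df
    t = (m2 - m1) / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return TestResult(
        t=t, df=df, p_two_tailed=_two_tailed_p(t, df),
        direction=int(np.sign(m2 - m1)),
    )


def pearson_validation(
    manual_counts, automated_counts
) -> tuple[float, float]:
    """Pearson r between manual and automated sweep counts, with its p value."""
    x = np.asarray(manual_counts, dtype=float)
    y = np.asarray(automated_counts, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("count lists must be 1-D and of equal length")
    if x.size < 3:
        raise ValueError("need at least three paired counts")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in one of the count lists")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-comparison significance threshold alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / m


def disease_progression_rate(rec: ClinicalRecord) -> float:
    """DPR = (48 - ALSFRS-R total) / disease duration in months."""
    return (48.0 - rec.alsfrs_r_total) / rec.disease_duration_months


def classify_bulbar_impaired(rec: ClinicalRecord) -> bool:
    """Clinical cut-off rule: bulbar sub-score <= 11 or CNS-BFS > 43."""
    for name in ("alsfrs_r_bulbar", "cns_bfs"):
        value = getattr(rec, name)
        if value is None or (isinstance(value, float) and math.isnan(value)):
            raise ValueError(f"missing clinical score: {name}")
    return rec.alsfrs_r_bulbar <= 11 or rec.cns_bfs > 43
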