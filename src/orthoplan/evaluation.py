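"""Plan-evaluation statistics: bone-position deviation between two surgical
plans, paired t-tests on cephalometric outcomes, inter-rater intraclass
correlation, and expert score summaries."""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Mapping

import numpy as np
from scipy import stats

from .cephalometry import LandmarkSet
from .kinematics import SegmentDefinition, SurgicalPlan, default_segments, plan_motions

__all__ = [
    "EvaluationError",
    "DeviationStats",
    "PairedTTest",
    "ScoreSummary",
    "deviation_stats",
    "plan_deviation",
    "paired_t",
    "icc",
    "summarize_scores",
]


class EvaluationError(ValueError):
    """Invalid evaluation input."""


@dataclass(frozen=True)
class DeviationStats:
    """Point-wise deviation summary between two plans for one segment:
    mean and SD of the Euclidean deviations (mm) and the strict-inequality
    fractions below 2, 3 and 4 mm (percent)."""

    mean_mm: float
    sd_mm: float
    pct_lt2: float
    pct_lt3: float
    pct_lt4: float
    n_points: int


def deviation_stats(distances) -> DeviationStats:
    """Summarize a set of point deviations (mm)."""
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise EvaluationError("no deviation distances")
    if np.any(d < 0):
        raise EvaluationError("distances must be nonnegative")
    sd = float(np.std(d, ddof=1)) if d.size > 1 else 0.0
    pct = {thr: 100.0 * float(np.mean(d < thr)) for thr in (2.0, 3.0, 4.0)}
    return DeviationStats(
        mean_mm=float(d.mean()),
        sd_mm=sd,
        pct_lt2=pct[2.0],
        pct_lt3=pct[3.0],
        pct_lt4=pct[4.0],
        n_points=int(d.size),
    )


def plan_deviation(
    plan_a: SurgicalPlan,
    plan_b: SurgicalPlan,
    landmarks: LandmarkSet,
    eval_points: Mapping[str, np.ndarray] | None = None,
    segments: Mapping[str, SegmentDefinition] | None = None,
) -> dict[str, DeviationStats]:
    """Per-segment bone-position deviation between two plans.

    Every evaluation point is mapped under both plans and the Euclidean
    distance between its two images is summarized.  ``eval_points`` maps
    segment id -> (n, 3) point array; by default the segment's member
    landmark positions are used.
    """
    segs = segments if segments is not None else default_segments()
    if eval_points is None:
        eval_points = {
            seg_id: np.array([landmarks[m] for m in seg.members])
            for seg_id, seg in segs.items()
        }
    motions_a = plan_motions(landmarks, plan_a, segs)
    motions_b = plan_motions(landmarks, plan_b, segs)
    out: dict[str, DeviationStats] = {}
    for seg_id, points in eval_points.items():
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if pts.size == 0:
            raise EvaluationError(f"empty evaluation point set for segment {seg_id!r}")
        if seg_id not in motions_a:
            raise EvaluationError(f"unknown segment {seg_id!r}")
        da = motions_a[seg_id].apply(pts)
        db = motions_b[seg_id].apply(pts)
        out[seg_id] = deviation_stats(np.linalg.norm(da - db, axis=1))
    return out


@dataclass(frozen=True)
class PairedTTest:
    """Two-sided paired t-test result.  ``degenerate`` marks a constant
    nonzero difference (zero variance), where the statistic is undefined."""

    statistic: float
    df: int
    pvalue: float
    degenerate: bool = False


def paired_t(x, y) -> PairedTTest:
    """Classic paired t-test with two-sided p from t with n-1 df.

    Identical samples give t = 0, p = 1; a constant nonzero difference has
    zero variance and is flagged degenerate rather than reported as a number.
    """
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise EvaluationError("paired samples must be equal-length 1D arrays")
    if a.size < 2:
        raise EvaluationError("need at least two pairs")
    d = a - b
    if np.allclose(d, 0.0):
        return PairedTTest(statistic=0.0, df=a.size - 1, pvalue=1.0)
    if np.isclose(np.var(d, ddof=1), 0.0):
        return PairedTTest(
            statistic=float("nan"), df=a.size - 1, pvalue=float("nan"), degenerate=True
        )
    res = stats.ttest_rel(a, b)
    return PairedTTest(statistic=float(res.statistic), df=a.size - 1, pvalue=float(res.pvalue))


def icc(ratings) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``ratings`` is a complete (raters x subjects) matrix.  Computed from the
    two-way ANOVA mean squares:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    with MSR the between-subject, MSC the between-rater and MSE the residual
    mean square, k raters and n subjects.  Always <= 1; equals 1 iff rater
    and residual variance are both zero.
    """
    m = np.asarray(ratings, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise EvaluationError("ratings must be a >=2 x >=2 raters-by-subjects matrix")
    if not np.all(np.isfinite(m)):
        raise EvaluationError("ratings matrix must be complete (no missing values)")
    k, n = m.shape
    grand = m.mean()
    subject_means = m.mean(axis=0)
    rater_means = m.mean(axis=1)
    ss_subjects = k * float(np.sum((subject_means - grand) ** 2))
    ss_raters = n * float(np.sum((rater_means - grand) ** 2))
    ss_total = float(np.sum((m - grand) ** 2))
    ss_error = ss_total - ss_subjects - ss_raters
    msr = ss_subjects / (n - 1)
    msc = ss_raters / (k - 1)
    mse = ss_error / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if np.isclose(denom, 0.0):
        raise EvaluationError("ICC undefined: no variance in the ratings")
    return float((msr - mse) / denom)


@dataclass(frozen=True)
class ScoreSummary:
    """Summary of 1-10 expert scores: median, mean, sample SD and histogram."""

    median: float
    mean: float
    sd: float
    histogram: dict[int, int]
    n: int


def summarize_scores(scores) -> ScoreSummary:
    """Median / mean / sample SD / histogram of integer scores in 1-10.

    A single score has SD 0 by convention.
    """
    s = np.asarray(scores)
    if s.size == 0:
        raise EvaluationError("no scores")
    if not np.all(np.equal(np.mod(s, 1), 0)) or s.min() < 1 or s.max() > 10:
        raise EvaluationError("scores must be integers in 1..10")
    s = s.astype(int)
    sd = float(np.std(s, ddof=1)) if s.size > 1 else 0.0
    hist = {i: int(np.sum(s == i)) for i in range(1, 11)}
    return ScoreSummary(
        median=float(np.median(s)), mean=float(s.mean()), sd=sd, histogram=hist, n=int(s.size)
    )
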