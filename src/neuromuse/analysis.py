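"""Session-level statistics: within-session affect-time correlations over
ten 1-minute periods, begin/end-of-study summaries, and Beck Depression
Inventory (BDI) percent change.

Correlations use Pearson's r with the two-sided p-value from the
t-transform with n-2 degrees of freedom; begin/end comparisons use a
paired two-sided t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import (
    CoverageError,
    DegenerateInputError,
    InsufficientDataError,
    ParameterError,
)
from .loop import SessionLog

AFFECT_DIMENSIONS = ("arousal", "valence", "arousal_n", "valence_n")


@dataclass
class MinuteSeries:
    """Per-period means of one affect dimension (default ten 1-min periods)."""

    period_means: np.ndarray
    dimension: str
    normalized: bool = False

    def __post_init__(self) -> None:
        self.period_means = np.asarray(self.period_means, dtype=float)
        if not np.all(np.isfinite(self.period_means)):
            raise DegenerateInputError("non-finite period mean")


def minute_means(
    log: SessionLog,
    dimension: str = "valence",
    n_periods: int = 10,
    period_s: float = 60.0,
    normalized: bool = False,
) -> MinuteSeries:
    """Mean of one affect dimension per contiguous 1-minute period.

    Pauses are excluded: periods are measured on the *active* (music
    playing) timeline, i.e. frame index x hop, so a 10-period analysis
    needs 10 minutes of affect frames regardless of how many pauses the
    session contained. ``normalized=True`` min-max normalizes the frame
    values before averaging (Pearson correlations are invariant to this).
    """
    if dimension not in AFFECT_DIMENSIONS:
        raise ParameterError(f"unknown dimension {dimension!r}")
    values = np.array(
        [getattr(r, dimension) if getattr(r, dimension) is not None else np.nan
         for r in log.records],
        dtype=float,
    )
    # warm-up frames (before calibration) have no normalized coordinate
    if dimension.endswith("_n"):
        keep = ~np.isnan(values)
        values = values[keep]
    frames_per_period = int(round(period_s / log.hop_s))
    need = n_periods * frames_per_period
    if len(values) < need:
        raise CoverageError(
            f"need {need} frames ({n_periods} x {period_s:.0f} s at "
            f"{log.hop_s} s hop) but log has {len(values)}"
        )
    if normalized:
        lo, hi = float(np.min(values[:need])), float(np.max(values[:need]))
        if hi == lo:
            raise DegenerateInputError("constant series cannot be normalized")
        values = (values - lo) / (hi - lo)
    means = values[:need].reshape(n_periods, frames_per_period).mean(axis=1)
    return MinuteSeries(period_means=means, dimension=dimension, normalized=normalized)


def time_correlation(series: MinuteSeries) -> tuple[float, float]:
    """Pearson correlation of period means against period index 1..n.

    Returns (r, two-sided p) with p from the t-transform on n-2 degrees
    of freedom. Constant series are degenerate.
    """
    y = series.period_means
    n = len(y)
    if n < 3:
        raise InsufficientDataError("need >= 3 periods for a correlation")
    if np.ptp(y) == 0:
        raise DegenerateInputError("constant period means; correlation undefined")
    r, p = stats.pearsonr(np.arange(1, n + 1, dtype=float), y)
    return float(r), float(p)


@dataclass
class StudySummary:
    """Begin/end means and SDs with the paired-difference test."""

    begin_mean: float
    begin_sd: float
    end_mean: float
    end_sd: float
    mean_difference: float
    p_value: float
    n: int
    zero_variance: bool = False


def study_summary(begin, end, paired: bool = True) -> StudySummary:
    """Summarize begin-of-study vs end-of-study affect values.

    With ``paired=True`` the vectors must be equal-length per-subject pairs
    and the p-value is a two-sided paired t-test; identical vectors have
    zero difference variance and are flagged with p = 1.
    """
    begin = np.asarray(begin, dtype=float)
    end = np.asarray(end, dtype=float)
    if begin.size < 2 or end.size < 2:
        raise InsufficientDataError("need >= 2 values per group")
    if paired and begin.size != end.size:
        raise ParameterError(
            f"paired comparison needs equal lengths, got {begin.size} vs {end.size}"
        )
    diff = end - begin if paired else None
    if paired:
        # treat differences constant to float precision as zero-variance
        tol = 1e-12 * max(1.0, float(np.max(np.abs(diff), initial=0.0)))
        if np.ptp(diff) <= tol and abs(diff[0]) <= tol:
            p = 1.0
            zero_var = True
        elif np.ptp(diff) <= tol:
            # constant non-zero difference: t is infinite, p -> 0
            p = 0.0
            zero_var = True
        else:
            p = float(stats.ttest_rel(end, begin).pvalue)
            zero_var = False
        mean_diff = float(np.mean(diff))
    else:
        res = stats.ttest_ind(end, begin)
        p = float(res.pvalue)
        zero_var = False
        mean_diff = float(np.mean(end) - np.mean(begin))
    return StudySummary(
        begin_mean=float(np.mean(begin)),
        begin_sd=float(np.std(begin, ddof=1)),
        end_mean=float(np.mean(end)),
        end_sd=float(np.std(end, ddof=1)),
        mean_difference=mean_diff,
        p_value=p,
        n=int(begin.size),
        zero_variance=zero_var,
    )


@dataclass(frozen=True)
class BDIRecord:
    """Pre/post Beck Depression Inventory scores (0-63) for one subject."""

    subject_id: str
    pre_score: float
    post_score: float

    def __post_init__(self) -> None:
        for name in ("pre_score", "post_score"):
            v = getattr(self, name)
            if not 0 <= v <= 63:
                raise ParameterError(f"{name}={v} outside the BDI range 0-63")


@dataclass
class BDIResult:
    mean_percent_improvement: float
    sd_percent_improvement: float
    per_subject: dict[str, float] = field(default_factory=dict)
    excluded: list[str] = field(default_factory=list)


def bdi_improvement(records: list[BDIRecord]) -> BDIResult:
    """Mean and SD of per-subject percent BDI improvement.

    Improvement = (pre - post) / pre x 100. Subjects with pre = 0 (no
    depression symptoms to improve on) are excluded and reported in the
    result's exclusion list; SD uses the n-1 formula (0 for n = 1).
    """
    if not records:
        raise InsufficientDataError("no BDI records")
    per = {}
    excluded = []
    for r in records:
        if r.pre_score <= 0:
            excluded.append(r.subject_id)
            continue
        per[r.subject_id] = (r.pre_score - r.post_score) / r.pre_score * 100.0
    if not per:
        raise InsufficientDataError("all subjects excluded (pre-score 0)")
    vals = np.array(list(per.values()))
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return BDIResult(
        mean_percent_improvement=float(np.mean(vals)),
        sd_percent_improvement=sd,
        per_subject=per,
        excluded=excluded,
    )


def read_bdi_csv(path) -> list[BDIRecord]:
    """BDI CSV dialect: header ``subject_id,pre,post``."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"subject_id", "pre", "post"}
    if not required.issubset(df.columns):
        raise ParameterError(f"{path}: BDI CSV needs columns {sorted(required)}")
    return [
        BDIRecord(subject_id=str(row.subject_id), pre_score=float(row.pre),
                  post_score=float(row.post))
        for row in df.itertuples()
    ]
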