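"""Breaking-CFS trial preprocessing and the direct-gaze-bias statistic.

In a breaking continuous-flash-suppression (bCFS) run, a face with direct or
averted gaze is suppressed by a dynamic mask and the participant reports the
face's quadrant as soon as it breaks into awareness, within a 15 s ceiling.
The analysis keeps response times of correctly localised trials only,
excludes participants whose mask suppressed more than 65% of trials, and
summarises each participant by

    direct_gaze_bias = mean RT (averted) - mean RT (direct),

so a positive bias means direct gaze reaches awareness faster.  The group
sanity check is a one-sample t test of the biases against zero, with a JZS
Bayes factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, ValidationError
from .inference import jzs_ttest_bf

MAX_RT_SECONDS = 15.0
EXCLUSION_MISS_THRESHOLD = 0.65
EXPECTED_TRIALS = 48  # 12 per gaze x side cell


@dataclass(frozen=True)
class GazeTrial:
    """One bCFS trial.  ``missed`` means no response within the ceiling."""

    gaze: str  # "direct" | "averted"
    true_quadrant: int
    reported_quadrant: Optional[int] = None
    rt: Optional[float] = None
    missed: bool = False

    def __post_init__(self) -> None:
        if self.gaze not in ("direct", "averted"):
            raise ValidationError(f"unknown gaze condition {self.gaze!r}")
        if self.true_quadrant not in (1, 2, 3, 4):
            raise ValidationError("true_quadrant must be 1..4")
        if self.missed != (self.rt is None):
            raise ValidationError("missed must hold exactly when rt is absent")
        if self.reported_quadrant is None and not self.missed:
            raise ValidationError("a trial without a reported quadrant is a miss")
        if self.rt is not None and not (0.0 < self.rt <= MAX_RT_SECONDS):
            raise ValidationError(f"rt must lie in (0, {MAX_RT_SECONDS}] seconds")


@dataclass
class GazeSummary:
    """Per-participant bCFS summary."""

    participant_id: str
    mean_rt_direct: float
    mean_rt_averted: float
    direct_gaze_bias: float
    n_valid_direct: int
    n_valid_averted: int
    miss_fraction: float
    excluded: bool

    @property
    def usable(self) -> bool:
        """True when the participant contributes to group-level statistics."""
        return not self.excluded and math.isfinite(self.direct_gaze_bias)


@dataclass
class GroupGazeTest:
    """One-sample t test of direct-gaze biases against zero."""

    t: float
    df: int
    p_two_sided: float
    bf01: float
    n: int
    mean_bias: float


def filter_valid_trials(trials: Sequence[GazeTrial]) -> list[GazeTrial]:
    """Keep responded, correctly localised trials with rt in (0, 15]."""
    return [t for t in trials
            if not t.missed and t.rt is not None
            and t.reported_quadrant == t.true_quadrant
            and 0.0 < t.rt <= MAX_RT_SECONDS]


def exclusion_check(trials: Sequence[GazeTrial],
                    threshold: float = EXCLUSION_MISS_THRESHOLD) -> bool:
    """True iff strictly more than ``threshold`` of trials were missed.

    Mislocalised responses count as responses here (the rule targets mask
    suppression, not localisation errors), though they never enter RT means.
    """
    if not trials:
        raise ValidationError("exclusion check requires at least one trial")
    miss_fraction = sum(t.missed for t in trials) / len(trials)
    return miss_fraction > threshold


def gaze_summary(participant_id: str, trials: Sequence[GazeTrial],
                 threshold: float = EXCLUSION_MISS_THRESHOLD,
                 stat: str = "mean",
                 sign_convention: str = "averted_minus_direct") -> GazeSummary:
    """Condition means and direct-gaze bias for one participant.

    An empty post-filter condition yields NaN statistics and an unusable
    summary rather than an exception.  ``stat`` may be "mean" (raw-second
    arithmetic mean, default) or "median".  The Figure-caption subtraction
    direction is available as ``sign_convention='direct_minus_averted'``.
    """
    if stat not in ("mean", "median"):
        raise ValidationError(f"unknown summary stat {stat!r}")
    if sign_convention not in ("averted_minus_direct", "direct_minus_averted"):
        raise ValidationError(f"unknown sign convention {sign_convention!r}")
    if not trials:
        raise ValidationError("gaze_summary requires at least one trial")
    valid = filter_valid_trials(trials)
    miss_fraction = sum(t.missed for t in trials) / len(trials)
    excluded = miss_fraction > threshold
    agg = np.mean if stat == "mean" else np.median
    rts_d = [t.rt for t in valid if t.gaze == "direct"]
    rts_a = [t.rt for t in valid if t.gaze == "averted"]
    m_d = float(agg(rts_d)) if rts_d else float("nan")
    m_a = float(agg(rts_a)) if rts_a else float("nan")
    bias = m_a - m_d
    if sign_convention == "direct_minus_averted":
        bias = -bias
    return GazeSummary(participant_id=str(participant_id), mean_rt_direct=m_d,
                       mean_rt_averted=m_a, direct_gaze_bias=bias,
                       n_valid_direct=len(rts_d), n_valid_averted=len(rts_a),
                       miss_fraction=float(miss_fraction), excluded=bool(excluded))


def group_gaze_test(summaries: Sequence[GazeSummary],
                    prior_scale: float = 0.707) -> GroupGazeTest:
    """One-sample t test (two-sided p) + JZS Bayes factor on usable biases."""
    biases = np.array([s.direct_gaze_bias for s in summaries if s.usable], dtype=float)
    n = biases.size
    if n < 2:
        raise ValidationError("group test requires at least two usable summaries")
    sd = biases.std(ddof=1)
    if sd == 0.0:
        if biases.mean() == 0.0:
            t, p = 0.0, 1.0  # perfectly null data
        else:
            raise DegenerateDataError("zero variance with nonzero mean: t undefined")
    else:
        res = stats.ttest_1samp(biases, 0.0)
        t, p = float(res.statistic), float(res.pvalue)
    bf01 = jzs_ttest_bf(t, n, prior_scale=prior_scale)
    return GroupGazeTest(t=t, df=n - 1, p_two_sided=p, bf01=bf01, n=n,
                         mean_bias=float(biases.mean()))


def read_gaze_trials(path) -> dict[str, list[GazeTrial]]:
    """Read a trial-level CSV into per-participant trial lists.

    Expected columns: participant_id, trial_index, gaze, true_quadrant,
    reported_quadrant (blank if none), rt_seconds (blank if missed).
    """
    df = pd.read_csv(path)
    return gaze_trials_from_frame(df)


def gaze_trials_from_frame(df: pd.DataFrame) -> dict[str, list[GazeTrial]]:
    required = {"participant_id", "gaze", "true_quadrant", "reported_quadrant", "rt_seconds"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"gaze trial table missing columns: {sorted(missing)}")
    if "trial_index" in df.columns:
        df = df.sort_values(["participant_id", "trial_index"])
    out: dict[str, list[GazeTrial]] = {}
    for pid, grp in df.groupby("participant_id", sort=True):
        trials = []
        for _, row in grp.iterrows():
            rt = row["rt_seconds"]
            missed = pd.isna(rt)
            rep = row["reported_quadrant"]
            trials.append(GazeTrial(
                gaze=str(row["gaze"]),
                true_quadrant=int(row["true_quadrant"]),
                reported_quadrant=None if pd.isna(rep) else int(rep),
                rt=None if missed else float(rt),
                missed=bool(missed)))
        out[str(pid)] = trials
    return out


def summarize_cohort(trials_by_participant: dict[str, list[GazeTrial]],
                     threshold: float = EXCLUSION_MISS_THRESHOLD) -> pd.DataFrame:
    """Per-participant summary table for a whole cohort."""
    rows = []
    for pid, trials in trials_by_participant.items():
        if len(trials) != EXPECTED_TRIALS:
            import warnings
            warnings.warn(f"participant {pid}: {len(trials)} trials "
                          f"(expected {EXPECTED_TRIALS})", stacklevel=2)
        s = gaze_summary(pid, trials, threshold=threshold)
        rows.append(dict(participant_id=s.participant_id,
                         mean_rt_direct=s.mean_rt_direct,
                         mean_rt_averted=s.mean_rt_averted,
                         direct_gaze_bias=s.direct_gaze_bias,
                         n_valid_direct=s.n_valid_direct,
                         n_valid_averted=s.n_valid_averted,
                         miss_fraction=s.miss_fraction,
                         excluded=s.excluded))
    return pd.DataFrame(rows)
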