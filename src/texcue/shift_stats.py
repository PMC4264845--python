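"""PSE-shift computation and group-level inference.

The quantity of interest is the per-observer PSE shift

    Delta = alpha_Combined - alpha_Separate        (log10 ratio units)

A positive shift means the Combined psychometric function sits to the right
of the Separate one: less texture contrast is needed to balance the other
cue when the cues compete in a single stimulus, i.e. texture dominates.

Group inference is a paired (one-sample) t test on the shifts, with the
standard repeated-measures effect sizes: Cohen's d = mean/SD and
r = sqrt(t^2 / (t^2 + df)).  Shifts in log units convert to "percent more
contrast required" via 100 * (10^Delta - 1), truncated to a whole percent.
A parallel analysis on the slope changes Delta-beta guards against PSE
shifts being confounded by slope changes between conditions.

No multiple-testing correction is applied across the three cue comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DegenerateSampleError, NonIdentifiableError
from .psychofit import LogisticFit

__all__ = [
    "GroupStats",
    "ShiftSummary",
    "effect_r_from_t",
    "group_test",
    "group_test_from_moments",
    "percent_more_contrast",
    "pse_shift",
    "slope_change_test",
    "summarize_comparison",
]


@dataclass(frozen=True)
class GroupStats:
    """One-sample t summary of a paired-difference sample."""

    n: int
    mean: float
    sd: float
    t_stat: float
    df: int
    p_value: float
    cohens_d: float
    effect_r: float

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean": self.mean,
            "sd": self.sd,
            "t": self.t_stat,
            "df": self.df,
            "p": self.p_value,
            "cohens_d": self.cohens_d,
            "r": self.effect_r,
        }


def effect_r_from_t(t: float, df: int) -> float:
    """Repeated-measures effect size r = sqrt(t^2 / (t^2 + df))."""
    if df < 1:
        raise ValueError("df must be >= 1")
    return math.sqrt(t * t / (t * t + df))


def pse_shift(fit_separate: LogisticFit, fit_combined: LogisticFit) -> float:
    """Delta = alpha_Combined - alpha_Separate for one observer.

    Positive values mean less texture contrast is required in the Combined
    condition.  Unconverged fits carry no trustworthy PSE and are rejected.
    """
    for name, fit in (("Separate", fit_separate), ("Combined", fit_combined)):
        if not fit.converged:
            raise NonIdentifiableError(
                f"{name} fit did not converge ({fit.message}); "
                "PSE shift is undefined"
            )
    return fit_combined.alpha - fit_separate.alpha


def group_test_from_moments(mean: float, sd: float, n: int) -> GroupStats:
    """Paired-t summary from sample moments: t = mean / (sd / sqrt(n))."""
    if n < 2:
        raise ValueError("need n >= 2 paired observations")
    if not (math.isfinite(mean) and math.isfinite(sd)) or sd < 0:
        raise ValueError("mean and sd must be finite, sd >= 0")
    if sd <= 1e-12 * max(abs(mean), 1.0):  # numerically zero variance
        raise DegenerateSampleError(
            "zero variance across observers: t statistic is undefined"
        )
    df = n - 1
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df)
    d = mean / sd
    r = effect_r_from_t(t, df)
    return GroupStats(
        n=n, mean=mean, sd=sd, t_stat=t, df=df, p_value=p, cohens_d=d, effect_r=r
    )


def group_test(shifts) -> GroupStats:
    """Paired-t summary of per-observer shifts (SD with n-1 denominator)."""
    x = np.asarray(shifts, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("shifts must be a 1-d sample with n >= 2")
    if np.any(~np.isfinite(x)):
        raise ValueError("shifts must be finite")
    return group_test_from_moments(
        float(np.mean(x)), float(np.std(x, ddof=1)), len(x)
    )


def percent_more_contrast(mean_shift: float) -> int:
    """Convert a log10 PSE shift to "percent more contrast", whole percent.

    ``100 * (10**shift - 1)`` truncated downward to an integer; truncation
    (not rounding) is the convention this analysis reports.
    """
    if not math.isfinite(mean_shift):
        raise ValueError("shift must be finite")
    return int(math.floor(100.0 * (10.0 ** mean_shift - 1.0)))


def slope_change_test(
    fits_separate: list[LogisticFit], fits_combined: list[LogisticFit]
) -> tuple[np.ndarray, GroupStats]:
    """Per-observer slope changes Delta-beta and their paired-t summary.

    Negative mean Delta-beta means the Combined functions are shallower.
    """
    if len(fits_separate) != len(fits_combined):
        raise ValueError("need one Separate and one Combined fit per observer")
    deltas = np.array(
        [fc.beta - fs.beta for fs, fc in zip(fits_separate, fits_combined)]
    )
    return deltas, group_test(deltas)


@dataclass(frozen=True)
class ShiftSummary:
    """Everything reported for one cue comparison."""

    comparison: str
    per_observer_shifts: np.ndarray
    shift_stats: GroupStats
    percent_more_contrast: int
    slope_changes: np.ndarray
    slope_stats: GroupStats

    def to_dict(self) -> dict:
        return {
            "comparison": self.comparison,
            "per_observer_shifts": np.asarray(self.per_observer_shifts).tolist(),
            "shift_stats": self.shift_stats.to_dict(),
            "percent_more_contrast": self.percent_more_contrast,
            "slope_changes": np.asarray(self.slope_changes).tolist(),
            "slope_stats": self.slope_stats.to_dict(),
        }


def summarize_comparison(
    comparison: str,
    fits_separate: list[LogisticFit],
    fits_combined: list[LogisticFit],
) -> ShiftSummary:
    """Full per-comparison summary: shifts, group test, percent, slopes."""
    shifts = np.array(
        [pse_shift(fs, fc) for fs, fc in zip(fits_separate, fits_combined)]
    )
    shift_stats = group_test(shifts)
    slope_changes, slope_stats = slope_change_test(fits_separate, fits_combined)
    return ShiftSummary(
        comparison=comparison,
        per_observer_shifts=shifts,
        shift_stats=shift_stats,
        percent_more_contrast=percent_more_contrast(shift_stats.mean),
        slope_changes=slope_changes,
        slope_stats=slope_stats,
    )
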