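"""Population-doubling accounting and lifespan curves for serially passaged cultures.

Cells grown under chronic telomerase inhibition are counted and re-seeded on a
weekly schedule; the number of population doublings (PD) achieved each week is
``log2(harvested / seeded)`` and the running sum of these is the culture's
cumulative lifespan curve.  During crisis the weekly PD can be negative
(fewer cells harvested than plated) and the cumulative curve plateaus or
declines until the culture is lost.

This module provides the PD arithmetic, cumulative-curve construction, a
crisis-onset detector based on departure from the extrapolated initial growth
rate, and an estimator for the telomere re-elongation rate (bp/day) observed
after an inhibitor is withdrawn.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GrowthRecord",
    "LifespanCurve",
    "weekly_pd",
    "build_curve",
    "detect_crisis",
    "recovery_rate",
]

#: Sentinel weekly-PD value reported when a culture is lost (harvested == 0).
#: Kept finite so cumulative sums remain usable; flagged via ``culture_lost``.
CULTURE_LOSS_PD = float("nan")

_VALID_TREATMENTS = ("CTR", "MIS", "GRN")


@dataclass
class GrowthRecord:
    """One week of a serial-passage growth experiment.

    Attributes
    ----------
    week : int
        Week index (1-based, contiguous within an experiment).
    seeded : int
        Cells plated at the start of the week (> 0).
    harvested : int
        Cells counted at the end of the week (>= 0; 0 marks culture loss).
    treatment : str
        Arm label: ``CTR`` (vehicle), ``MIS`` (mismatched control oligo) or
        ``GRN`` (telomerase inhibitor).
    """

    week: int
    seeded: int
    harvested: int
    treatment: str = "CTR"

    def __post_init__(self) -> None:
        if self.seeded <= 0:
            raise ValueError(f"seeded must be positive, got {self.seeded}")
        if self.harvested < 0:
            raise ValueError(f"harvested must be non-negative, got {self.harvested}")
        if self.treatment not in _VALID_TREATMENTS:
            raise ValueError(
                f"treatment must be one of {_VALID_TREATMENTS}, got {self.treatment!r}"
            )

    @property
    def pd_week(self) -> float:
        """Population doublings achieved this week: log2(harvested/seeded)."""
        return weekly_pd(self.seeded, self.harvested)


@dataclass
class LifespanCurve:
    """Cumulative population-doubling curve of one culture."""

    weeks: np.ndarray
    pd_week: np.ndarray
    cumulative_pd: np.ndarray
    culture_lost: bool = False
    total_pd_at_loss: Optional[float] = None
    crisis_onset_week: Optional[int] = field(default=None)

    def __len__(self) -> int:
        return len(self.weeks)


def weekly_pd(seeded: float, harvested: float) -> float:
    """Population doublings for one growth interval.

    PD = log2(harvested / seeded).  A harvest below the seeding density yields
    a negative PD (crisis-phase decline).  ``harvested == 0`` is a culture
    loss and returns NaN as a sentinel rather than -inf.
    """
    if seeded <= 0:
        raise ValueError(f"seeded must be positive, got {seeded}")
    if harvested < 0:
        raise ValueError(f"harvested must be non-negative, got {harvested}")
    if harvested == 0:
        return CULTURE_LOSS_PD
    return math.log2(harvested / seeded)


def build_curve(records: Sequence[GrowthRecord]) -> LifespanCurve:
    """Assemble weekly records into a cumulative PD curve.

    Weeks must be contiguous (each week exactly one more than the previous).
    If the final record has ``harvested == 0`` the culture is marked lost and
    ``total_pd_at_loss`` is the cumulative PD reached at that point (the NaN
    sentinel week contributes 0 to the running sum).
    """
    if not records:
        raise ValueError("no growth records supplied")
    weeks = np.array([r.week for r in records], dtype=int)
    if np.any(np.diff(weeks) != 1):
        raise ValueError(f"weeks must be contiguous, got {weeks.tolist()}")

    pd_w = np.array([r.pd_week for r in records], dtype=float)
    lost = bool(np.isnan(pd_w).any())
    cumulative = np.cumsum(np.nan_to_num(pd_w, nan=0.0))

    total_at_loss = None
    if lost:
        first_loss = int(np.flatnonzero(np.isnan(pd_w))[0])
        total_at_loss = float(cumulative[first_loss])
    return LifespanCurve(
        weeks=weeks,
        pd_week=pd_w,
        cumulative_pd=cumulative,
        culture_lost=lost,
        total_pd_at_loss=total_at_loss,
    )


def detect_crisis(
    curve: LifespanCurve,
    baseline_weeks: int = 3,
    margin_pd: float = 1.0,
) -> Optional[int]:
    """Find the onset of crisis as departure from the initial growth rate.

    The initial rate is a least-squares line through the first
    ``baseline_weeks`` points of the cumulative-PD curve; crisis onset is the
    first week at which the observed cumulative PD falls below that
    extrapolated line by at least ``margin_pd`` doublings.  Returns None if
    growth never departs from the extrapolation.
    """
    if len(curve) <= baseline_weeks:
        raise ValueError(
            f"curve has {len(curve)} weeks; need more than baseline_weeks={baseline_weeks}"
        )
    w = curve.weeks.astype(float)
    c = curve.cumulative_pd
    slope, intercept = np.polyfit(w[:baseline_weeks], c[:baseline_weeks], 1)
    expected = intercept + slope * w
    gap = expected - c
    below = np.flatnonzero(gap >= margin_pd)
    if below.size == 0:
        return None
    onset = int(curve.weeks[below[0]])
    curve.crisis_onset_week = onset
    return onset


def recovery_rate(
    days: Sequence[float],
    median_sizes_kb: Sequence[float],
    window: tuple[float, float] = (14.0, 21.0),
) -> dict:
    """Telomere re-elongation rate (bp/day) after inhibitor withdrawal.

    Ordinary least-squares slope of median telomere size (converted to bp)
    on day, restricted to ``window`` (inclusive; default the third week after
    drug removal, days 14-21).  Returns the slope with a 95% CI when at least
    3 points fall in the window.
    """
    days = np.asarray(days, dtype=float)
    sizes_bp = np.asarray(median_sizes_kb, dtype=float) * 1000.0
    if days.shape != sizes_bp.shape:
        raise ValueError("days and median_sizes_kb must have equal length")
    lo, hi = window
    mask = (days >= lo) & (days <= hi)
    x, y = days[mask], sizes_bp[mask]
    if x.size < 2:
        raise ValueError(f"need >=2 points in window {window}, got {x.size}")

    res = stats.linregress(x, y)
    slope = float(res.slope)
    ci: Optional[tuple[float, float]] = None
    if x.size >= 3:
        tcrit = stats.t.ppf(0.975, df=x.size - 2)
        half = tcrit * res.stderr
        ci = (slope - half, slope + half)
    return {
        "rate_bp_per_day": slope,
        "ci95_bp_per_day": ci,
        "n_points": int(x.size),
        "window_days": (float(lo), float(hi)),
    }
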