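"""Telomerase-activity quantification from TRAP assays.

The TRAP (Telomeric Repeat Amplification Protocol) assay amplifies telomerase
extension products into a 6-bp periodic ladder, co-amplified with an internal
standard (ITAS) that normalizes for PCR efficiency.  Activity of one lane is
the ratio of integrated ladder signal to integrated ITAS signal.  Between
cell lines, activity is compared via dilution series (activity ratio vs cells
per assay, 50-500): the least-squares slope of that line, with its 95%
confidence interval, measures activity per cell, and a sample line's activity
is expressed as a percent of a reference line's slope (conventionally HeLa).

The module also quantifies C-circle dot blots (an ALT marker): the ratio of
mean signal with vs without the Phi29 polymerase, with a configurable
positivity threshold (the underlying readout is qualitative).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .densitometry import LaneProfile

__all__ = [
    "TrapQuant",
    "DilutionFit",
    "quantify_lane",
    "dilution_series_fit",
    "relative_activity",
    "alt_ratio",
]

#: Default C-circle positivity threshold (fold-enrichment with Phi29).
ALT_THRESHOLD = 5.0
#: Floor applied to dot intensities before ratios, as a fraction of the max.
ALT_INTENSITY_FLOOR = 1e-9


@dataclass
class TrapQuant:
    """Ladder and ITAS signals of one TRAP lane and their ratio."""

    ladder_signal: float
    itas_signal: float

    def __post_init__(self) -> None:
        if self.itas_signal <= 0:
            raise ValueError(
                "ITAS signal must be positive (zero ITAS indicates failed "
                "PCR or loading)"
            )
        if self.ladder_signal < 0:
            raise ValueError("ladder signal must be non-negative")

    @property
    def activity_ratio(self) -> float:
        return self.ladder_signal / self.itas_signal


@dataclass
class DilutionFit:
    """Linear fit of activity ratio on cells per assay."""

    slope: float
    intercept: float
    slope_ci95: Optional[tuple[float, float]]
    slope_se: Optional[float]
    n_points: int


def _integrate_region(profile: LaneProfile, region: tuple[float, float],
                      background: float) -> float:
    lo, hi = region
    if lo >= hi:
        raise ValueError(f"empty region ({lo}, {hi})")
    d, y = profile.distance_mm, profile.intensity
    if lo < d[0] or hi > d[-1]:
        raise ValueError(
            f"region ({lo}, {hi}) mm outside profile span ({d[0]}, {d[-1]}) mm"
        )
    mask = (d >= lo) & (d <= hi)
    return float(np.trapezoid(np.clip(y[mask] - background, 0.0, None), d[mask]))


def quantify_lane(
    profile: LaneProfile,
    ladder_region: tuple[float, float],
    itas_region: tuple[float, float],
) -> TrapQuant:
    """Integrate ladder and ITAS regions of a TRAP lane and form their ratio.

    Regions are (lo, hi) migration-distance intervals in mm and must be
    disjoint.  The global minimum of the trace is subtracted as background
    before integration, so the ratio is invariant to rescaling the profile.
    """
    l_lo, l_hi = ladder_region
    i_lo, i_hi = itas_region
    if l_hi > i_lo and l_lo < i_hi:
        raise ValueError(
            f"ladder region ({l_lo}, {l_hi}) overlaps ITAS region ({i_lo}, {i_hi})"
        )
    background = float(profile.intensity.min())
    ladder = _integrate_region(profile, ladder_region, background)
    itas = _integrate_region(profile, itas_region, background)
    if itas <= 0:
        raise ValueError("zero ITAS signal: failed PCR or loading")
    return TrapQuant(ladder_signal=ladder, itas_signal=itas)


def dilution_series_fit(
    cells_per_assay: Sequence[float],
    ratios: Sequence[float],
) -> DilutionFit:
    """Least-squares line of activity ratio on cell input.

    With >= 3 points the slope's 95% CI is computed from the t distribution
    with n - 2 degrees of freedom; with exactly 2 points only the slope and
    intercept are returned and the CI is flagged unavailable (None).
    """
    x = np.asarray(cells_per_assay, dtype=float)
    y = np.asarray(ratios, dtype=float)
    if x.shape != y.shape:
        raise ValueError("cells_per_assay and ratios must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 points for a slope")
    if np.any(x <= 0):
        raise ValueError("cell counts must be positive")

    res = stats.linregress(x, y)
    slope, intercept = float(res.slope), float(res.intercept)
    if x.size >= 3:
        se = float(res.stderr)
        tcrit = stats.t.ppf(0.975, df=x.size - 2)
        ci = (slope - tcrit * se, slope + tcrit * se)
        return DilutionFit(slope, intercept, ci, se, int(x.size))
    return DilutionFit(slope, intercept, None, None, int(x.size))


def relative_activity(sample: DilutionFit, reference: DilutionFit) -> dict:
    """Telomerase activity of a sample line as a percent of a reference line.

    Percent = 100 * sample.slope / reference.slope.  When both fits carry
    standard errors, a 95% CI for the percent is propagated by the delta
    method for a ratio of independent estimates.
    """
    if reference.slope <= 0:
        raise ValueError("reference slope must be positive")
    pct = 100.0 * sample.slope / reference.slope
    ci = None
    if sample.slope_se is not None and reference.slope_se is not None:
        var = (sample.slope_se / reference.slope) ** 2 + (
            sample.slope * reference.slope_se / reference.slope**2
        ) ** 2
        df = sample.n_points + reference.n_points - 4
        tcrit = stats.t.ppf(0.975, df=max(df, 1))
        half = 100.0 * tcrit * np.sqrt(var)
        ci = (pct - half, pct + half)
    return {"percent": pct, "ci95": ci}


def alt_ratio(
    plus_phi29: Sequence[float],
    minus_phi29: Sequence[float],
    threshold: float = ALT_THRESHOLD,
) -> dict:
    """C-circle dot-blot quantification: Phi29(+) over Phi29(-) signal.

    Ratio of replicate means; a sample is called ALT-positive when the ratio
    meets ``threshold`` (default 5x, a configurable convention — the assay's
    published readout is qualitative).  Intensities below a small fraction of
    the maximum are clamped before the ratio to avoid division blowup.
    """
    plus = np.asarray(plus_phi29, dtype=float)
    minus = np.asarray(minus_phi29, dtype=float)
    if plus.size == 0 or minus.size == 0:
        raise ValueError("replicate sets must be non-empty")
    if np.any(plus < 0) or np.any(minus < 0):
        raise ValueError("dot intensities must be non-negative")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    floor = ALT_INTENSITY_FLOOR * max(plus.max(), minus.max(), 1.0)
    minus_mean = max(float(minus.mean()), floor)
    ratio = float(plus.mean()) / minus_mean
    return {"ratio": ratio, "positive": bool(ratio >= threshold), "threshold": threshold}
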