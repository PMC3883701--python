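"""IC50 estimation for telomerase inhibition dose-response data.

Raw TRAP activity ratios measured at a series of inhibitor doses are first
normalized to the mean of the untreated (zero-dose) replicates, then fitted
by nonlinear least squares to the two-parameter inhibition sigmoid

    percent = D + (100 - D) / (1 + 10**((log10(dose) - log10(IC50)) * 1.59))

where ``D`` is the minimal residual activity (percent floor) and the slope
constant 1.59 is fixed, not fitted.  Doses are in nM and logs are base 10.
Zero-dose observations anchor the normalization only and never enter the
nonlinear fit (their log is undefined).

The fit optimizes (D, log10 IC50) by multi-start least squares over a log-IC50
grid spanning the dose range, so it is deterministic given the data and robust
to local minima.  The 95% CI is reported on log10(IC50) (then exponentiated),
using the asymptotic (Wald) covariance at the optimum with t critical values;
a profile-likelihood interval is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .gelsim import SIGMOID_SLOPE, inhibition_sigmoid

__all__ = ["DoseResponseFit", "normalize", "fit_ic50", "predict"]

#: Fitted IC50 beyond this multiple of the dose range is flagged unreliable.
RELIABLE_RANGE_FACTOR = 100.0


@dataclass
class DoseResponseFit:
    """Result of the two-parameter sigmoid fit."""

    floor_D: float
    log_ic50: float
    ci95_log_ic50: Optional[tuple[float, float]]
    residual_sse: float
    n_obs: int
    reliable: bool = True

    @property
    def ic50_nM(self) -> float:
        return 10.0 ** self.log_ic50

    @property
    def ci95_ic50_nM(self) -> Optional[tuple[float, float]]:
        if self.ci95_log_ic50 is None:
            return None
        lo, hi = self.ci95_log_ic50
        return (10.0 ** lo, 10.0 ** hi)


def normalize(raw: pd.DataFrame) -> pd.DataFrame:
    """Express raw activity ratios as percent of the untreated mean.

    ``raw`` has columns (dose_nM, replicate, raw_ratio) (column
    ``activity_ratio`` is accepted as a synonym).  Returns columns
    (dose_nM, replicate, percent, in_fit): percent = 100 * ratio / mean of
    the zero-dose ratios; zero-dose rows are retained but flagged
    ``in_fit=False``.
    """
    df = raw.copy()
    if "raw_ratio" not in df.columns and "activity_ratio" in df.columns:
        df = df.rename(columns={"activity_ratio": "raw_ratio"})
    required = {"dose_nM", "raw_ratio"}
    if not required.issubset(df.columns):
        raise ValueError(f"dose table needs columns {sorted(required)}")
    zero = df.loc[df["dose_nM"] == 0, "raw_ratio"]
    if zero.empty:
        raise ValueError("need at least one zero-dose replicate to normalize")
    anchor = float(zero.mean())
    if anchor <= 0:
        raise ValueError(f"zero-dose mean ratio must be positive, got {anchor}")
    out = df.copy()
    out["percent"] = 100.0 * out["raw_ratio"] / anchor
    out["in_fit"] = out["dose_nM"] > 0
    return out


def _sse_and_fit(dose, pct, log_ic50_0, fix_floor):
    """Single least-squares start; returns (params, sse)."""
    log_dose = np.log10(dose)

    if fix_floor:
        def resid(theta):
            (lic,) = theta
            return _sigmoid_log(log_dose, 0.0, lic) - pct

        x0 = np.array([log_ic50_0])
        bounds = ([log_ic50_0 - 6], [log_ic50_0 + 6])
    else:
        def resid(theta):
            d, lic = theta
            return _sigmoid_log(log_dose, d, lic) - pct

        x0 = np.array([max(0.0, min(99.0, pct.min())), log_ic50_0])
        bounds = ([0.0, log_ic50_0 - 6], [99.999, log_ic50_0 + 6])

    sol = optimize.least_squares(resid, x0, bounds=bounds, xtol=1e-14, ftol=1e-14,
                                 gtol=1e-14)
    return sol, float(np.sum(sol.fun**2))


def _sigmoid_log(log_dose: np.ndarray, floor_D: float, log_ic50: float) -> np.ndarray:
    return floor_D + (100.0 - floor_D) / (
        1.0 + 10.0 ** ((log_dose - log_ic50) * SIGMOID_SLOPE)
    )


def fit_ic50(
    normalized: pd.DataFrame,
    fix_floor_at_zero: bool = False,
    profile_ci: bool = False,
) -> DoseResponseFit:
    """Fit the two-parameter inhibition sigmoid to normalized data.

    ``normalized`` is the output of :func:`normalize` (columns dose_nM,
    percent; rows with dose 0 are excluded).  Requires >= 3 distinct positive
    doses.  Raises if no start converges; flags the fit unreliable when the
    IC50 lands outside ``RELIABLE_RANGE_FACTOR`` times the dose range.
    """
    df = normalized
    if "percent" not in df.columns:
        raise ValueError("expected a normalized table with a 'percent' column")
    pos = df[df["dose_nM"] > 0]
    dose = pos["dose_nM"].to_numpy(dtype=float)
    pct = pos["percent"].to_numpy(dtype=float)
    if not np.all(np.isfinite(pct)):
        raise ValueError("non-finite percent values")
    if len(np.unique(dose)) < 3:
        raise ValueError("need >= 3 distinct positive doses to fit")

    # multi-start over a log-IC50 grid spanning (and slightly exceeding) the
    # dose range; grid points are screened by their direct SSE so only the
    # most promising starts are polished by the optimizer
    grid = np.linspace(np.log10(dose.min()) - 1.0, np.log10(dose.max()) + 1.0, 9)
    d0 = 0.0 if fix_floor_at_zero else float(np.clip(pct.min(), 0.0, 99.0))
    screen = [
        float(np.sum((_sigmoid_log(np.log10(dose), d0, lic) - pct) ** 2))
        for lic in grid
    ]
    starts = grid[np.argsort(screen)[:3]]
    best, best_sse = None, np.inf
    for lic0 in starts:
        try:
            sol, sse = _sse_and_fit(dose, pct, lic0, fix_floor_at_zero)
        except Exception:
            continue
        if sol.success and sse < best_sse - 1e-12:
            best, best_sse = sol, sse
    if best is None:
        raise RuntimeError(
            "IC50 fit failed to converge from any start on the log-IC50 grid "
            f"[{grid[0]:.2f}, {grid[-1]:.2f}]"
        )

    if fix_floor_at_zero:
        floor_D, log_ic50 = 0.0, float(best.x[0])
        idx_lic = 0
    else:
        floor_D, log_ic50 = float(best.x[0]), float(best.x[1])
        idx_lic = 1

    n = len(pct)
    p = len(best.x)
    ci = None
    if n > p:
        # asymptotic covariance from the Jacobian at the optimum
        J = best.jac
        sigma2 = best_sse / (n - p)
        try:
            cov = sigma2 * np.linalg.inv(J.T @ J)
            se_lic = float(np.sqrt(cov[idx_lic, idx_lic]))
            tcrit = stats.t.ppf(0.975, df=n - p)
            ci = (log_ic50 - tcrit * se_lic, log_ic50 + tcrit * se_lic)
        except np.linalg.LinAlgError:
            ci = None
    if profile_ci and n > p:
        ci = _profile_ci(dose, pct, floor_D, log_ic50, best_sse, n, p,
                         fix_floor_at_zero)

    log_lo = np.log10(dose.min() / RELIABLE_RANGE_FACTOR)
    log_hi = np.log10(dose.max() * RELIABLE_RANGE_FACTOR)
    reliable = bool(log_lo <= log_ic50 <= log_hi)

    return DoseResponseFit(
        floor_D=floor_D,
        log_ic50=log_ic50,
        ci95_log_ic50=ci,
        residual_sse=best_sse,
        n_obs=n,
        reliable=reliable,
    )


def _profile_ci(dose, pct, floor_D, log_ic50, sse_hat, n, p, fix_floor):
    """Profile-likelihood 95% CI on log IC50 (F-test inversion)."""
    log_dose = np.log10(dose)
    fcrit = stats.f.ppf(0.95, 1, n - p)
    target = sse_hat * (1.0 + fcrit / (n - p))

    def profile_sse(lic: float) -> float:
        if fix_floor:
            return float(np.sum((_sigmoid_log(log_dose, 0.0, lic) - pct) ** 2))
        sol = optimize.least_squares(
            lambda th: _sigmoid_log(log_dose, th[0], lic) - pct,
            x0=[floor_D], bounds=([0.0], [99.999]),
        )
        return float(np.sum(sol.fun**2))

    def edge(direction: float) -> float:
        step = 0.05
        x = log_ic50
        for _ in range(400):
            x += direction * step
            if profile_sse(x) >= target:
                return optimize.brentq(
                    lambda t: profile_sse(t) - target, x - direction * step, x
                )
        return x  # open-ended: return the bound reached

    return (edge(-1.0), edge(+1.0))


def predict(fit: DoseResponseFit, dose_nM) -> np.ndarray:
    """Percent residual activity predicted at positive dose(s)."""
    dose = np.asarray(dose_nM, dtype=float)
    if np.any(dose <= 0):
        raise ValueError("dose must be positive (log undefined at 0)")
    out = inhibition_sigmoid(dose, fit.ic50_nM, fit.floor_D)
    return out if out.ndim else float(out)
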