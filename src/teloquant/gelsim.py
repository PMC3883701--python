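"""Synthetic gel and assay data with known ground truth.

Forward models for every measurement the analysis modules quantify:

* TRF Southern-blot lanes — a fragment-size distribution (short bulk
  telomeres, optionally with a biphasic long tail) is rendered into a 1D
  densitometric trace under a semi-log migration model, with hybridization
  signal proportional to abundance x fragment length (a (TTAGGG)n probe binds
  in proportion to repeat content);
* radiolabeled marker lanes with known sizes and migration distances;
* TRAP telomerase-assay lanes — a 6-bp periodic product ladder whose total
  intensity scales with telomerase activity x cell input, plus an internal
  standard (ITAS) band that does not;
* dose-response tables following the two-parameter inhibition sigmoid
  ``percent = D + (100 - D) / (1 + 10**((log10(dose) - log10(IC50)) * 1.59))``;
* weekly growth records with a crisis phase in which proliferation declines
  linearly and can go negative.

All generators are deterministic given a seed.  Noise models: additive
Gaussian on densitometric traces, multiplicative lognormal on cell counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .densitometry import LaneProfile
from .lifespan import GrowthRecord

__all__ = [
    "FragmentSizeDistribution",
    "MigrationModel",
    "TrapLaneSpec",
    "make_distribution",
    "render_lane",
    "render_marker_lane",
    "simulate_trap_lane",
    "simulate_dose_response",
    "simulate_growth",
    "signal_weighted_median_kb",
    "DEFAULT_SIZE_GRID_BP",
    "DEFAULT_MARKER_SIZES_BP",
]

# --- gel geometry defaults (config, not claims about any particular gel) ----

#: Distance grid: 0.1 mm sampling over a 25 cm gel.
DISTANCE_STEP_MM = 0.1
GEL_LENGTH_MM = 250.0

#: Default log-spaced fragment-size support, 100 bp - 23 kb.
DEFAULT_SIZE_GRID_BP = np.unique(
    np.round(np.geomspace(100, 23_000, 1200)).astype(int)
)

#: 1-kb-extension-ladder-like marker set (bp).
DEFAULT_MARKER_SIZES_BP = (
    10_000, 8_000, 6_000, 5_000, 4_000, 3_000, 2_000, 1_500, 1_000, 500,
)

#: Sharp apparent band width for marker lanes (mm).
MARKER_BAND_SD_MM = 0.5


@dataclass
class MigrationModel:
    """Semi-log agarose mobility: distance = a - b * log10(size_kb).

    ``a_mm`` is the migration distance of a 1 kb fragment; ``b_mm_per_decade``
    is the distance separating a tenfold size difference.
    """

    a_mm: float = 60.0
    b_mm_per_decade: float = 40.0

    def __post_init__(self) -> None:
        if self.b_mm_per_decade <= 0:
            raise ValueError("b_mm_per_decade must be positive")

    def distance_mm(self, size_bp) -> np.ndarray:
        size_bp = np.asarray(size_bp, dtype=float)
        if np.any(size_bp <= 0):
            raise ValueError("fragment sizes must be positive")
        return self.a_mm - self.b_mm_per_decade * np.log10(size_bp / 1000.0)


@dataclass
class FragmentSizeDistribution:
    """Relative molecule counts over a grid of fragment sizes (bp)."""

    sizes_bp: np.ndarray
    abundance: np.ndarray

    def __post_init__(self) -> None:
        self.sizes_bp = np.asarray(self.sizes_bp)
        self.abundance = np.asarray(self.abundance, dtype=float)
        if self.sizes_bp.shape != self.abundance.shape:
            raise ValueError("sizes_bp and abundance must have equal length")
        if np.any(np.diff(self.sizes_bp) <= 0):
            raise ValueError("sizes must be strictly increasing")
        if np.any(self.sizes_bp < 100):
            raise ValueError("fragment sizes below 100 bp are not supported")
        if np.any(self.abundance < 0):
            raise ValueError("abundance must be non-negative")
        total = self.abundance.sum()
        if not (np.isfinite(total) and total > 0):
            raise ValueError("abundance must sum to a positive finite value")

    @property
    def signal(self) -> np.ndarray:
        """Hybridization signal weights: abundance x size (repeat content)."""
        return self.abundance * self.sizes_bp.astype(float)


@dataclass
class TrapLaneSpec:
    """Parameters of one TRAP assay lane.

    ``activity`` is relative telomerase activity (fraction of a reference
    line, e.g. HeLa = 1.0); ``n_cells`` the cell-equivalents per assay.
    The product ladder starts at ``ladder_start_bp`` and repeats every
    ``ladder_period_bp`` (6 bp, the telomeric repeat); the internal standard
    (ITAS) band sits below the ladder and is independent of activity.
    """

    activity: float
    n_cells: int
    ladder_start_bp: int = 50
    ladder_period_bp: int = 6
    itas_size_bp: int = 36
    n_ladder_bands: int = 15

    def __post_init__(self) -> None:
        if self.activity < 0:
            raise ValueError("activity must be non-negative")
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        if self.ladder_period_bp <= 0 or self.ladder_start_bp <= 0:
            raise ValueError("ladder geometry must be positive")
        if self.itas_size_bp >= self.ladder_start_bp:
            raise ValueError("ITAS band must sit below the ladder start")

    @property
    def ladder_sizes_bp(self) -> np.ndarray:
        return self.ladder_start_bp + self.ladder_period_bp * np.arange(
            self.n_ladder_bands
        )


# ---------------------------------------------------------------------------
# fragment-size distributions
# ---------------------------------------------------------------------------

def signal_weighted_median_kb(dist: FragmentSizeDistribution) -> float:
    """Signal-weighted median fragment size (kb) of a distribution.

    Uses the midpoint-mass cumulative convention (each grid point carries its
    signal weight; the median is where the interpolated cumulative crosses
    half the total), matching :func:`teloquant.trf.median_size`.
    """
    from .trf import _weighted_median  # shared convention

    return _weighted_median(dist.sizes_bp / 1000.0, dist.signal)


def _lognormal_abundance(grid_bp: np.ndarray, mu_ln: float, sigma_ln: float) -> np.ndarray:
    x = np.log(grid_bp.astype(float))
    return np.exp(-0.5 * ((x - mu_ln) / sigma_ln) ** 2)


def make_distribution(
    median_signal_kb: float,
    spread: float = 0.25,
    long_fraction: float = 0.0,
    long_mode_kb: float = 6.0,
    grid: Optional[np.ndarray] = None,
) -> FragmentSizeDistribution:
    """Construct a fragment-size distribution with a prescribed signal median.

    The bulk is a lognormal in size (sigma ``spread`` on the natural-log
    scale); ``long_fraction`` of the abundance may be placed in a second
    lognormal mode at ``long_mode_kb`` to emulate a biphasic blot (a small
    population of much longer telomeres above the short bulk).  The bulk
    location parameter is tuned numerically so that the signal-weighted
    median (signal = abundance x size) equals ``median_signal_kb`` to within
    1%.

    Raises
    ------
    ValueError
        If the target median lies outside the grid, or tuning cannot reach it
        (e.g. a long tail too heavy for the requested median).
    """
    if grid is None:
        grid = DEFAULT_SIZE_GRID_BP
    grid = np.asarray(grid)
    if spread <= 0:
        raise ValueError("spread must be positive")
    if not (0 <= long_fraction < 1):
        raise ValueError("long_fraction must be in [0, 1)")
    target_bp = median_signal_kb * 1000.0
    if not (grid[0] < target_bp < grid[-1]):
        raise ValueError(
            f"target median {median_signal_kb} kb outside grid "
            f"[{grid[0]}, {grid[-1]}] bp"
        )

    tail = None
    if long_fraction > 0:
        tail = _lognormal_abundance(grid, np.log(long_mode_kb * 1000.0), spread)
        tail = tail / tail.sum()

    def build(mu_ln: float) -> FragmentSizeDistribution:
        bulk = _lognormal_abundance(grid, mu_ln, spread)
        bulk = bulk / bulk.sum()
        ab = (1.0 - long_fraction) * bulk
        if tail is not None:
            ab = ab + long_fraction * tail
        return FragmentSizeDistribution(sizes_bp=grid, abundance=ab)

    def objective(mu_ln: float) -> float:
        return signal_weighted_median_kb(build(mu_ln)) - median_signal_kb

    # the achieved median is not monotone in mu when a long tail is present
    # (a tiny bulk lets the tail dominate the signal), so scan for a sign
    # change before root-finding
    lo = np.log(float(grid[0]))
    hi = np.log(float(grid[-1]))
    mus = np.linspace(lo, hi, 80)
    vals = np.array([objective(m) for m in mus])
    sign_change = np.flatnonzero(np.diff(np.sign(vals)) != 0)
    if sign_change.size == 0 and not np.any(vals == 0):
        reach_lo = median_signal_kb + vals.min()
        reach_hi = median_signal_kb + vals.max()
        raise ValueError(
            f"cannot tune distribution to median {median_signal_kb} kb: "
            f"target outside the achievable range "
            f"[{reach_lo:.2f}, {reach_hi:.2f}] kb for this grid and tail"
        )
    i = int(sign_change[0])
    mu = optimize.brentq(objective, mus[i], mus[i + 1], xtol=1e-10)
    dist = build(mu)
    achieved = signal_weighted_median_kb(dist)
    if abs(achieved - median_signal_kb) > 0.01 * median_signal_kb:
        raise ValueError(
            f"tuning converged to {achieved:.4f} kb, outside 1% of the "
            f"target {median_signal_kb} kb"
        )
    return dist


# ---------------------------------------------------------------------------
# lane rendering
# ---------------------------------------------------------------------------

def _distance_grid(n_samples: int) -> np.ndarray:
    return np.linspace(0.0, GEL_LENGTH_MM, n_samples)


def _gauss(d: np.ndarray, center: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((d - center) / sd) ** 2) / (sd * np.sqrt(2.0 * np.pi))


def render_lane(
    dist: FragmentSizeDistribution,
    mig: MigrationModel = MigrationModel(),
    band_sd_mm: float = 1.5,
    baseline: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_samples: int = 2501,
) -> LaneProfile:
    """Render a fragment-size distribution into a densitometric lane trace.

    Each fragment of size L contributes signal proportional to
    ``abundance(L) * L`` (probe hybridization scales with repeat content),
    centered at the migration distance of L and spread as a Gaussian band of
    sd ``band_sd_mm``.  A constant ``baseline`` and Gaussian noise of sd
    ``noise_sd`` are added; negative noisy intensities are clipped to zero.
    Noiseless traces conserve total signal: the trapezoid integral of
    (trace - baseline) equals the summed signal weights.
    """
    if band_sd_mm <= 0:
        raise ValueError("band_sd_mm must be positive")
    if baseline < 0 or noise_sd < 0:
        raise ValueError("baseline and noise_sd must be non-negative")
    d = _distance_grid(n_samples)
    centers = mig.distance_mm(dist.sizes_bp)
    if np.any(~np.isfinite(centers)) or np.any(centers < 0) or np.any(centers > GEL_LENGTH_MM):
        raise ValueError("migration model places fragments outside the gel")
    weights = dist.signal
    y = np.zeros_like(d)
    # vectorized over fragments in chunks to bound memory
    for i0 in range(0, len(centers), 256):
        c = centers[i0 : i0 + 256, None]
        w = weights[i0 : i0 + 256, None]
        y += (w * np.exp(-0.5 * ((d[None, :] - c) / band_sd_mm) ** 2)).sum(axis=0)
    y /= band_sd_mm * np.sqrt(2.0 * np.pi)
    y += baseline
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    return LaneProfile(distance_mm=d, intensity=np.clip(y, 0.0, None))


def render_marker_lane(
    marker_sizes_bp: Sequence[int],
    mig: MigrationModel = MigrationModel(),
    n_samples: int = 2501,
) -> tuple[LaneProfile, pd.DataFrame]:
    """Render a molecular-weight marker lane and its calibration table.

    Returns a lane trace with one sharp band per marker and the ground-truth
    (size_bp, distance_mm) table to calibrate against.
    """
    sizes = np.asarray(sorted(set(int(s) for s in marker_sizes_bp), reverse=True))
    if sizes.size < 2:
        raise ValueError("need at least 2 distinct marker sizes")
    distances = mig.distance_mm(sizes)
    d = _distance_grid(n_samples)
    y = np.zeros_like(d)
    for c in distances:
        y += _gauss(d, c, MARKER_BAND_SD_MM)
    table = pd.DataFrame({"size_bp": sizes, "distance_mm": distances})
    return LaneProfile(distance_mm=d, intensity=y), table


# ---------------------------------------------------------------------------
# TRAP lanes
# ---------------------------------------------------------------------------

#: Polyacrylamide-gel mobility for the short TRAP products (config default).
TRAP_MIGRATION = MigrationModel(a_mm=40.0, b_mm_per_decade=60.0)
TRAP_BAND_SD_MM = 0.8
#: Per-band geometric intensity decay up the ladder (PCR product falloff).
TRAP_LADDER_DECAY = 0.85
#: Intensity scale: ladder signal per (activity x cell); ITAS fixed.
TRAP_SIGNAL_PER_CELL = 1.0
TRAP_ITAS_SIGNAL = 200.0


def simulate_trap_lane(
    spec: TrapLaneSpec,
    noise_sd: float = 0.0,
    seed: int = 0,
    mig: MigrationModel = TRAP_MIGRATION,
    n_samples: int = 2501,
) -> tuple[LaneProfile, dict]:
    """Render a TRAP lane: telomerase product ladder plus ITAS band.

    Ladder band intensities scale linearly with ``activity * n_cells``; the
    ITAS intensity is fixed.  Returns the lane trace and a dict of
    integration regions ``{"ladder_mm": (lo, hi), "itas_mm": (lo, hi)}``
    covering each feature out to 4 band widths.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    d = _distance_grid(n_samples)
    ladder_sizes = spec.ladder_sizes_bp
    ladder_d = mig.distance_mm(ladder_sizes)
    itas_d = float(mig.distance_mm(spec.itas_size_bp))

    total_ladder = TRAP_SIGNAL_PER_CELL * spec.activity * spec.n_cells
    band_w = TRAP_LADDER_DECAY ** np.arange(spec.n_ladder_bands)
    band_w = band_w / band_w.sum() * total_ladder

    y = np.zeros_like(d)
    for c, w in zip(ladder_d, band_w):
        y += w * _gauss(d, c, TRAP_BAND_SD_MM)
    y += TRAP_ITAS_SIGNAL * _gauss(d, itas_d, TRAP_BAND_SD_MM)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    y = np.clip(y, 0.0, None)

    pad = 4.0 * TRAP_BAND_SD_MM
    # larger products migrate less far: ladder occupies [d(last band), d(first band)]
    ladder_region = (float(ladder_d.min() - pad), float(ladder_d.max() + pad))
    itas_region = (float(itas_d - pad), float(itas_d + pad))
    if ladder_region[1] >= itas_region[0] and ladder_region[0] <= itas_region[1]:
        # overlapping geometry would make the ratio ill-defined
        raise ValueError(
            "ITAS band overlaps the ladder region; adjust TrapLaneSpec geometry"
        )
    return (
        LaneProfile(distance_mm=d, intensity=y),
        {"ladder_mm": ladder_region, "itas_mm": itas_region},
    )


# ---------------------------------------------------------------------------
# dose-response tables
# ---------------------------------------------------------------------------

#: Doses used by the inhibition assay (nM), including the untreated anchor.
DEFAULT_DOSE_GRID_NM = (0.0, 50.0, 100.0, 200.0, 500.0, 1000.0, 2000.0, 4000.0)
#: Raw ladder/ITAS ratio of an untreated sample (arbitrary; normalized away).
UNTREATED_RAW_RATIO = 2.0
#: Fixed slope constant of the two-parameter inhibition sigmoid.
SIGMOID_SLOPE = 1.59


def inhibition_sigmoid(dose_nM, ic50_nM: float, floor_D: float) -> np.ndarray:
    """Percent residual telomerase activity at a positive dose."""
    dose = np.asarray(dose_nM, dtype=float)
    return floor_D + (100.0 - floor_D) / (
        1.0 + 10.0 ** ((np.log10(dose) - np.log10(ic50_nM)) * SIGMOID_SLOPE)
    )


def simulate_dose_response(
    ic50_nM: float,
    floor_D: float = 0.0,
    doses_nM: Sequence[float] = DEFAULT_DOSE_GRID_NM,
    noise_sd: float = 0.0,
    replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a raw dose-response table from the inhibition sigmoid.

    Returns columns (dose_nM, replicate, raw_ratio) where raw_ratio is the
    ladder/ITAS activity ratio before normalization; untreated (dose 0)
    replicates average ``UNTREATED_RAW_RATIO`` before noise, and positive
    doses follow the sigmoid.  Gaussian noise of sd ``noise_sd`` (percent
    units) is added per replicate.
    """
    if ic50_nM <= 0:
        raise ValueError("ic50_nM must be positive")
    if not (0 <= floor_D < 100):
        raise ValueError("floor_D must be in [0, 100)")
    doses = np.asarray(doses_nM, dtype=float)
    if 0.0 not in doses:
        raise ValueError("doses must include 0 (normalization anchor)")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for dose in doses:
        pct = 100.0 if dose == 0 else float(inhibition_sigmoid(dose, ic50_nM, floor_D))
        for rep in range(1, replicates + 1):
            noisy = pct + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            rows.append(
                {
                    "dose_nM": dose,
                    "replicate": rep,
                    "raw_ratio": UNTREATED_RAW_RATIO * noisy / 100.0,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# growth records
# ---------------------------------------------------------------------------

#: Weekly seeding density (cells per dish).
DEFAULT_SEEDED = 300_000


def simulate_growth(
    initial_pd_per_week: float = 3.0,
    crisis_start_week: int = 10,
    decline_per_week: float = 1.0,
    weeks: int = 15,
    seed: int = 0,
    seeded: int = DEFAULT_SEEDED,
    noise_cv: float = 0.0,
    treatment: str = "GRN",
) -> list[GrowthRecord]:
    """Simulate weekly growth records with an optional crisis phase.

    Weekly PD is constant at ``initial_pd_per_week`` before
    ``crisis_start_week`` and then declines linearly by ``decline_per_week``
    each week, unbounded below (a culture in crisis can harvest fewer cells
    than were plated).  Harvested counts are seeded x 2**PD with
    multiplicative lognormal noise of coefficient of variation ``noise_cv``.
    A week whose count falls to zero terminates the record list (culture
    lost).
    """
    if initial_pd_per_week <= 0:
        raise ValueError("initial_pd_per_week must be positive")
    if decline_per_week <= 0:
        raise ValueError("decline_per_week must be positive")
    rng = np.random.default_rng(seed)
    records: list[GrowthRecord] = []
    for week in range(1, weeks + 1):
        pd_true = initial_pd_per_week
        if week >= crisis_start_week:
            pd_true -= decline_per_week * (week - crisis_start_week + 1)
        harvested = seeded * 2.0 ** pd_true
        if noise_cv > 0:
            sigma = np.sqrt(np.log1p(noise_cv**2))
            harvested *= rng.lognormal(-0.5 * sigma**2, sigma)
        harvested_i = int(round(harvested))
        records.append(
            GrowthRecord(
                week=week, seeded=seeded, harvested=harvested_i, treatment=treatment
            )
        )
        if harvested_i == 0:
            break
    return records


def growth_records_to_frame(records: Sequence[GrowthRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "week": [r.week for r in records],
            "seeded": [r.seeded for r in records],
            "harvested": [r.harvested for r in records],
            "treatment": [r.treatment for r in records],
        }
    )
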