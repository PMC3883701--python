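# Methods

## TRF lane model and size calibration

A digested genomic DNA sample run on an agarose gel leaves a smear of
telomere restriction fragments. The forward model (`gelsim`) represents the
sample as relative molecule counts (abundance) over a log-spaced size grid
(100 bp – 23 kb, 1200 points). Hybridization signal of a fragment of length
*L* is `abundance(L) · L`: a telomeric-repeat probe binds in proportion to
repeat content, which is what makes the 1/size correction of the median
meaningful downstream.

Migration follows the semi-log mobility approximation
`d = a − b·log₁₀(L_kb)` with defaults `a = 60 mm` (distance of a 1 kb
fragment) and `b = 40 mm` per tenfold size change on a 250 mm gel sampled at
0.1 mm. These geometry constants are configuration, not claims about any
particular gel rig. Each fragment's signal is spread as a unit-integral
Gaussian band (default sd 1.5 mm), so a noiseless lane conserves total
signal exactly (checked to 1e-6 relative in the suite). Noise is additive
Gaussian on traces and multiplicative lognormal on cell counts — the
simplest models that support the CI tests.

Calibration (`densitometry.fit_calibration`) supports two functional forms:
a least-squares semi-log line, and the default monotone piecewise-linear
interpolant in (distance, log₁₀ size) with linear extrapolation, which
tolerates real gel nonlinearity. Extrapolation beyond the marker span is
allowed up to 10% of the span (with a warning); beyond that, profile samples
are trimmed. The default marker set is a 1 kb-extension-ladder-like series
(0.5–10 kb).

Replotting intensity against size (`remap_profile`) is a pure relabeling of
the x-axis — no Jacobian reweighting — matching the replot-then-integrate
procedure the statistics are defined on. Total intensity is therefore
conserved sample-by-sample exactly.

## Median telomere length

The median is the size at which cumulative signal reaches half its total.
On a discrete trace this needs a convention: `teloquant` uses the
midpoint-mass (Hazen / type-5 weighted percentile) cumulative
`C_i = Σ_{j<i} w_j + w_i/2`, locating the half-total crossing by linear
interpolation between consecutive `(size_i, C_i)` points. This convention is
symmetric — a uniform profile on sizes {1,2,3,4} kb yields exactly 2.5 kb —
and is free of the half-sample bias of the step-cumulative alternative.
Ties on a flat cumulative segment resolve to the segment midpoint.

The corrected median applies weights `intensity/size` (size in kb; the
constant factor cancels) before locating the median, converting the
signal-weighted distribution to a molecule-weighted one. On noiseless
synthetic lanes the corrected median equals the molecule-count median of the
generating distribution to within grid resolution — the central scientific
property of the module — and is never larger than the raw median.

The analysis window defaults to 1–23 kb, excluding sub-marker smear; no
sub-telomeric DNA subtraction is attempted (no operational procedure exists
for it in the assay as modeled). Medians are reported in kb.

## TRAP quantification

Lane activity is the ratio of background-subtracted trapezoid integrals over
the ladder and ITAS regions (regions in mm are explicit inputs; the
background is the global trace minimum, making the ratio invariant to global
rescaling). Dilution-series comparison regresses activity ratio on cells per
assay by unweighted OLS with a free intercept (a through-origin option is
not needed for slope comparison); the 95% CI uses the t distribution with
n−2 df. Relative activity is 100·(sample slope)/(reference slope) with a
delta-method CI for the ratio of independent slopes.

The synthetic TRAP lane uses a polyacrylamide-scale migration model
(`a = 40`, `b = 60`), a 15-band ladder starting at 50 bp with 6 bp period and
a 0.85 per-band geometric intensity decay, and an ITAS at 36 bp. Geometry is
configurable; the linearity of ladder signal in activity × cells is the
property the quantification relies on, and it holds by construction.

The C-circle ratio is mean(+Φ29)/mean(−Φ29) with a 5× positivity threshold —
an explicit configuration default, since the underlying assay readout is
qualitative. Denominators are floored at 1e-9 of the maximum signal.

## IC50 fitting

The inhibition sigmoid has two free parameters, the residual-activity floor
`D ∈ [0, 100)` and log₁₀ IC50; the slope constant 1.59 is fixed as part of
the model. Doses are nM; zero-dose observations define the 100% anchor
during normalization and are excluded from the fit (their log is undefined).
Fitting uses `scipy.optimize.least_squares` with multi-start over a log-IC50
grid spanning the dose range ± one decade; starts are screened by direct SSE
so only the three most promising are polished. The fit is deterministic
given the data. A fitted IC50 more than 100× outside the dose range is
flagged unreliable (e.g. for data showing no inhibition).

The default CI is asymptotic (Wald) from the Jacobian at the optimum with t
critical values (n − p df), exponentiated for reporting on the nM scale; a
profile-likelihood interval (F-test inversion) is available behind a flag.
Replicates enter the fit pooled, not averaged (a mean-mode can be emulated
by pre-averaging the table).

**Coverage caveat.** The Wald CI attains nominal 95% coverage when the
residuals are independent (verified by simulation at 2% noise, 1000
replicates, in the suite). Normalizing against a *noisy* zero-dose anchor
makes all points share the anchor's error, which the CI does not model;
coverage in that regime drops a few points below nominal. This is a property
of the assay design, not of the optimizer.

## Lifespan accounting

Weekly PD is `log₂(harvested/seeded)`; a zero harvest is a culture loss and
is reported as a NaN sentinel (not −∞), with total lifespan given as the
cumulative PD at the loss week. Crisis onset is the first week the
cumulative curve falls at least `margin_pd` (default 1 PD) below the line
fitted to the first `baseline_weeks` (default 3) — an explicit operational
stand-in for the visual extrapolation-gap convention, recovered to within
one week on simulated crises. The re-elongation rate is an OLS slope of
median size (bp) on day, default window days 14–21 (re-elongation is not
expected until the third week after drug removal).

## What the generator does and does not emulate

The generator reproduces the statistical structure the estimators assume:
signal ∝ length, semi-log migration, Gaussian band spread and trace noise,
linear TRAP response, the exact inhibition sigmoid, lognormal count noise.
It does not model 2D gel artifacts (smiling, lane bleed), saturation,
radioactive decay, PCR per-band processivity bias, or sub-telomeric DNA
content. Passing roundtrip tests therefore demonstrates correctness of the
quantification given these assumptions, not robustness to every artifact of
scanned blots; the image-extraction path is exercised by rasterizing
rendered lanes.

## Numerical choices and problem sizes

* Distribution tuning: the bulk lognormal location is found by scanning 80
  candidate values for a sign change and polishing with Brent's method
  (xtol 1e-10); the achieved signal median must be within 1% of target or
  the call fails with the achievable range. The median-vs-location objective
  is non-monotone when a biphasic tail is present, hence the scan.
* Calibration inverse round-trips to 1e-9 relative (closed form for the
  semi-log kind; knot-exact for the interpolant).
* Rolling-min background is a morphological opening (minimum then maximum
  filter), which makes repeated subtraction a no-op.
* Simulation sizes in tests: 1000 replicates for CI-coverage checks (dose
  fits take ~12 s total), 1000 random profiles for the median-ordering
  property, 2501-sample lanes. The full suite runs in well under a minute.

## Known limitations

* Median estimates inherit the calibration's extrapolation limits; signal
  migrating beyond the marker span ± 10% is trimmed, which can bias medians
  of distributions much wider than the marker range.
* The corrected median treats all signal as telomeric; sub-telomeric
  contamination is not subtracted.
* The dilution-series delta-method CI assumes independent sample and
  reference fits and is approximate for small n.
* Crisis detection assumes an initially linear cumulative curve; cultures
  already in decline at week 1 have no valid baseline.
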