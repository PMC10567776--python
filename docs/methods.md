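# Methods

This note documents the models, numerical choices and limitations behind
`phenofuse`, in the spirit of a model-description chapter: what is
computed, under which assumptions, and what the synthetic experiments do
and do not demonstrate.

## Time grid

All annual series live on a fixed grid of 122 three-day windows. Window
*k* (0-based) covers days of year 3k+1 … 3k+3; the last window absorbs day
365 (and 366 in leap years). Series values are indexed by the window's
nominal centre day (DOY 2, 5, …, 365), which is also the time variable
*t* of the warping and logistic models. Anchoring windows at DOY 1 makes
the grid deterministic and independent of observation density.

## Compositing and screening

Vegetation indices are computed per observation — EVI2 =
2.5(NIR−Red)/(NIR+2.4·Red+1), NDVI = (NIR−Red)/(NIR+Red), NDWI =
(NIR−SWIR1)/(NIR+SWIR1) — and then composited, so the QA screen acts at
observation level. Only `high`-quality observations contribute; multiple
observations in a window are averaged (deterministic and noise-damping; a
single observation is taken as-is). The NIR/SWIR1 band pair for NDWI
follows its role here as a moisture/contamination flag.

Three rules then convert suspect steps into gaps:

1. EVI2 > 0.9 · NDVI at the step;
2. EVI2 > 1.1 × the non-gap EVI2 values within the preceding **and**
   succeeding 10 composite steps (one month each side). By default the
   step must exceed 110% of *all* available values on both sides
   (`spike_rule="all"`); the at-least-one-per-side reading is available as
   `spike_rule="any"`. The rule is skipped when either side has no
   non-gap value, which makes it conservative at the series edges.
3. NDVI < NDWI at the step.

Rules 1 and 3 are per-step. Rule 2 depends on which neighbors survive, so
it is iterated to a fixed point inside `apply_fill_rules`; the whole
operation is therefore idempotent, and removing input observations can
only ever create gaps, never remove them.

## Camera GCC donors

Frames are partitioned into 10×10 near-equal rectangular blocks
(remainder rows/columns go to the last block row/column), GCC =
mean(G)/(mean(R)+mean(G)+mean(B)) per block, ingesting imagery from 09:00
to 17:00 local time. Within each 3-day window the composite takes the
90th percentile using the (n+1)p plotting-position convention (linear
interpolation between order statistics; `numpy` method `"weibull"`), the
convention pinned down by the package's unit tests. Windows without
imagery are linearly interpolated from neighboring composites (nearest
value at the series ends) so every donor is gap-free — the shape matcher
requires continuous donors. Donor series keep (site, grid-cell)
provenance but are used irrespective of camera location.

## Shape matching and fusion

The donor is resampled onto the satellite grid by linear interpolation at
T = λ(t + β); warped queries outside the donor's sampled domain are
dropped, never extrapolated. λ takes five values (0.90–1.10, step 0.05)
and β twenty-one (−30 … +30 days, step 3), giving 105 warps per donor.
For each warp, (a, b) come from geometric mean functional regression:
|a| = sd(y)/sd(x) with the sign of the correlation, b through the means.
GMFR is symmetric in x and y, which suits a scaling between two measured
greenness quantities with no natural regressor/response asymmetry.

Candidates need at least 8 overlapping non-gap pairs and non-degenerate
variance. Scoring uses MSD = mean squared deviation between observed and
predicted EVI2; the significance of Pearson R uses the t-transform with
n−2 degrees of freedom. Selection filters by R > 0.6 and p ≤ 0.02 and
ranks by MSD (ties: higher R, then the donor earliest in the
sorted-by-identifier order, making the result invariant to collection
order). MSD is computed over all non-gap steps, not only the growing
season. Fusion replaces gaps with a·GCC(λ(t+β))+b; observed values are
never altered. Gaps the warped donor cannot cover (edge steps mapped
outside its domain) remain marked and are reported.

## Phenology detection

1. **Background.** `EVI2_b` is the mean of values strictly below the 10th
   percentile, inverted-CDF convention (the ⌈0.1 n⌉-th order statistic);
   with heavy ties, the mean of the smallest decile by count. The
   background is computed on the *smoothed* series: applied to raw noisy
   values, the lowest-decile mean is biased low by the order statistics
   of the noise (≈ −1.75 σ over a flat dormant tail), and because the
   background is held fixed during fitting this drags the model floor
   down and spreads all four dates outward by several days. Smoothing
   first removes most of that selection bias.
2. **Smoothing.** Moving median (3 steps) → moving average (3 steps) →
   Savitzky–Golay (5 steps, order 2), edges handled by shrinking windows
   (polynomial-fit edges for the SG stage). The median stage removes
   single-step spikes entirely; a pure logistic passes through with
   ≤ 0.01 EVI2 distortion.
3. **Cycle delimitation.** Slopes are least-squares line fits over a
   5-step (15-day) centered window. A peak is a transition from a
   sustained (≥2-step) rising run to a sustained falling run. Candidate
   peaks closer than half the minimum cycle amplitude to the intervening
   trough are merged (noise wiggles on one season's plateau otherwise
   split it into spurious cycles); peaks under the minimum amplitude
   (default 0.1 EVI2 above background, configurable) are dropped; at most
   three cycles are kept (largest amplitudes), reported chronologically,
   each split into greenup and senescence phases at its peak.
4. **Fitting.** Both logistic forms are fitted per phase with the
   background held fixed, the sign of *b* set by the phase direction, and
   bounded trust-region least squares started from three deterministic
   midpoint-crossing initializations plus three seeded jittered restarts.
   The stress form must keep its amplitude c + d·t positive over the
   segment, and is preferred only when it beats the favorable SSE by more
   than 10% — it nests the favorable form, so on noisy data it is almost
   always marginally lower without that margin, and the marginal winners
   occasionally degenerate into ramp-logistics with meaningless
   curvature.
5. **Dates.** dK/dt is evaluated on a 0.1-day grid, analytically for the
   favorable form (closed-form f′, f″, f‴ of the logistic) and by
   4th-order central finite differences (h = 0.05 day) for the stress
   form. Greenup and maturity are the first and last local maxima of
   dK/dt in a greenup phase; senescence and dormancy the first and last
   local minima in a senescence phase (a falling curve mirrors a rising
   one, flipping dK/dt's sign). Extrema below 1% of the strongest value
   of the same sign are ignored — dK/dt decays to zero in the dormant
   tails where rounding noise produces meaningless wiggles. The
   evaluation domain extends 15 days beyond each segment end (clipped to
   the year): segment boundaries derive from the smoothed argmax, a noisy
   peak estimate, and a fitted bend can sit marginally outside them.

Within a cycle the construction guarantees greenup ≤ maturity ≤
senescence ≤ dormancy whenever all four are found.

**Cycle slots.** The 12-value output record holds (greenup, maturity,
senescence, dormancy) × slots 1–3. One cycle → slot 2. Two cycles → the
larger-amplitude (main) cycle in slot 2, the other chronologically in
slot 1 or 3. Three cycles → slots 1, 2, 3 chronologically, so a main
cycle preceded by two smaller ones lands in slot 3. Unused slots and
undetected dates encode as nodata.

## Products

Both files are multiband int16 TIFF, nodata 32767, written with
`tifffile`: `HLS-PhenoCam.AYYYY.SiteID.Tile.LSP-EVI2.tif` (122 bands,
EVI2 × 10000, valid codes −10000…10000, rounding half-away-from-zero so
negative EVI2 codes symmetrically, out-of-range codes clipped with a
warning) and `…LSP-Date.tif` (12 bands, DOY). Synthetic products carry a
nominal UTM-like 30 m grid in a JSON ImageDescription tag; band
descriptions are this package's own, not claimed identical to any
archive's internal strings.

## Synthetic scenes

The generator emulates: double-logistic seasonal truth curves (1–3
cycles; defaults draw mid-latitude single seasons — greenup inflection
DOY 120–150, senescence inflection DOY 255–285, amplitude 0.3–0.5 EVI2,
background 0.06–0.12, logistic rates 0.07–0.12 d⁻¹); additive Gaussian
observation noise (default sd 0.02 EVI2); clustered gaps drawn as
geometric-length runs (mean 4 composite steps = 12 days, emulating
persistent cloud cover) trimmed/extended at run edges to hit the target
gap fraction exactly; and donor GCC series tied to the EVI2 truth by the
(a, b, λ, β) scaling family, mapped into a typical camera GCC range
(0.34–0.44), alongside flat, white-noise and 80-day-shifted decoy donors.
Daily reflectance observations are produced by inverting the EVI2 formula
at fixed red reflectance 0.05 with constant green (0.08) and SWIR1
(0.25), so NDVI and NDWI stay in ranges where the screening rules are
quiet on clean data; cloudy days get depressed values and a `cloud` flag.

Truth transition dates come from a dense-grid (0.1-day) *numeric*
curvature change-rate oracle applied to the generating curve — repeated
`np.gradient`, with padded sampling because triple differencing corrupts
grid edges — never from the fitting path under test.

Two constructions are used deliberately. For factor-recovery experiments
the pixel's EVI2 truth is built *from the donor* through the exact same
linear-interpolation warp the matcher uses, so recovery of (λ, β) is
exact and (a, b) are reproduced to machine precision — this isolates the
search and regression. For end-to-end experiments the truth curve is
primary and the donor is sampled from it analytically, so matching incurs
realistic (small) interpolation error.

What passing these experiments does **not** show: robustness to
non-Gaussian or seasonally varying noise, donors whose shape genuinely
differs from the target pixel (species mix, understory), snow-contaminated
backgrounds, multi-year carry-over, or georeferencing fidelity — real
HLS/PhenoCam archives are outside the test loop.

## Problem sizes and determinism

The shipped experiments use 100 pixels for factor recovery, 50 parameter
sets for the oracle comparison and 200 pixels for end-to-end accuracy —
sizes at which the measured quantities are stable across seeds while a
full run stays under a couple of minutes on one CPU. All randomness flows
from a single seed through `numpy` `SeedSequence` children; the CLI is
byte-deterministic for a fixed seed.

## Known limitations

- The β search is bounded at ±30 days; donors with larger seasonal offset
  are matched, if at all, through the shifted-decoy failure mode (low R)
  rather than corrected.
- Donor interpolation is linear; a 3-day donor grid under-resolves bends
  sharper than ~0.2 d⁻¹.
- The stress form's derivatives are numeric; its dates carry the finite-
  difference tolerance (well under the 0.1-day date grid).
- Slot assignment beyond three cycles is undefined; extra cycles are
  dropped by amplitude rank.
- `detect_phenometrics` linearly fills short residual gaps (unwarpable
  edge steps) before smoothing; long unfused stretches should instead be
  treated as no-match pixels upstream.
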