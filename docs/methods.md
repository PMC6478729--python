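# Methods

`sahelveg` implements a pipeline for partitioning dryland vegetation
production into its herbaceous and woody-foliage components from seasonal
satellite metrics, and for relating trends and periodicities in the two
components to a decomposition of daily rainfall into core wet-season and
early/late rain. This note records the models, the parameter choices, the
numerical conventions, and what the synthetic test bed does and does not
establish.

## 1. Rainfall decomposition (`rainseason`)

The Sahel has a single summer monsoon. Annual grasses and forbs can only
use rain falling inside an uninterrupted core wet season — they germinate
with the first sustained rains, are damaged by within-season dry spells,
and wilt photoperiodically at the season's end — whereas woody plants also
exploit early and late rains. The module therefore splits the 1 May –
31 October rainfall sum (`annual`) of each site-year into `rainfall_C`
(core season) and `rainfall_EL = annual − rainfall_C`; November–April is
excluded entirely and the water stores are re-initialised at zero every
1 May.

Two clamped running stores act as evapotranspiration surrogates,
`CR-d(t) = max(0, CR-d(t−1) + rain(t) − d)` with drawdowns d = 5 (onset
logic) and d = 3 (dry spells). The four season dates and the five
dry-spell window conditions are implemented exactly as parameterised in
`RuleParams` (defaults: 12 mm inclusive for the onset day, 12 mm exclusive
for the last-rain day, 5-day sums strictly above 20 mm, dry-spell windows
6/12/18/24/30 days against 0/6/9/12/15 mm, cutoff 15 August). Points the
published wording leaves open, and the conventions chosen here:

* **"Summed CR-3 balance"** is read as the sum of the daily CR-3 *store
  values* over the window — the store is the only defined balance
  quantity. The alternative reading (sum of daily `rain − 3` increments)
  is available via `RuleParams(balance_mode="increment")`.
* **Dry-spell extent.** Every sliding window satisfying a condition is a
  detection; overlapping same-rule windows are merged into an envelope,
  envelopes from different rules that overlap form a cluster, and the
  longest envelope prevails (ties: earlier start, then the condition with
  the longer base window, so a 30-day zero run is reported as the 30-day
  condition). Envelopes can extend a day or two into positive-store days
  when a low-sum window straddles the transition; this is a direct
  consequence of the window formulation.
* **Core end.** When a dry spell starts between 15 August and the last
  rain, the season ends the day before the spell begins
  (`end_convention="day_before_spell"`); ending at the last rain that
  precedes the spell is available as `"last_rain"`. The end date is never
  placed before 15 August.
* **Germination check.** "Ten days after the first rain with CR-5
  positive" is implemented as a check on day 10 with a fall-forward to the
  first later positive day, still before 15 August.
* **5-day window endpoints.** A window summing above 20 mm may begin or
  end on rainless days; the reported onset/last-rain date is the first or
  last day *with rain* inside the window.

If any required date cannot be established the year is flagged,
`rainfall_C = 0` and all rain is early/late. Conservation
(`rainfall_C + rainfall_EL = annual`) holds identically for every input;
the test suite verifies it on 10,000 random years and checks the full
rule system date-for-date against an independently coded straight-line
reference on a library of constructed years.

A fixed-window variant (`decompose_fixed_window`, default day-of-year
204–244, the regional mean core season) supports large-area application
where running the full rule system per pixel is unnecessary.

## 2. Percentile metrics (`phenology`)

Intra-annual vegetation-index series (optical indices or vegetation
optical depth, 10-day to monthly cadence) are reduced per calendar year to
the 90th percentile `p90` (wet-season state: herbaceous plus woody
foliage) and a dry-season percentile `p_dry` (woody foliage only): the
30th percentile by default, the 10th for low-frequency L-band VOD whose
weak herbaceous sensitivity pushes p30 into the wet season. The L-band
flag is explicit configuration, never inferred. Percentiles use linear
interpolation between closest order statistics; a year needs at least 8
observations (roughly 70% of a 10-day cadence season) or its metrics are
missing. Site averaging is the unweighted mean over sites per year with
the contributing count reported. The L-VOD pre-step aggregates near-daily
data to 10-day block medians followed by a locally weighted second-order
polynomial smoother (tricube weights, 5-block span; exact on quadratic
input).

## 3. Calibration and partition (`calibration`)

Two independent ordinary least squares fits on site-averaged annual
values,

    AGH + WPF = p90   × slope_t + offset_t
    WPF       = p_dry × slope_w + offset_w
    AGH       = (AGH + WPF) − WPF,

where AGH is above-ground herbaceous mass and WPF woody plant foliage
mass (kg ha⁻¹). The partition rests on contrasting phenology: woody
foliage persists into the dry season, herbaceous mass does not. Fit
diagnostics are the Pearson r and the RMSE in raw kg ha⁻¹. Negative mass
estimates are floored at zero and flagged (`clamped`); conservation
`agh + wpf = total` holds wherever the floor is not binding. Calibration
requires at least three paired years and a non-degenerate metric.

## 4. Trends and periodicity (`trends`)

* Trends: OLS against calendar year, two-sided t test on the slope
  (p < 0.05 downstream), sample-(n−1) z-scores for cross-variable
  comparison, Theil–Sen deliberately out of scope.
* Slope equality: pooled regression with a group indicator and
  year-by-group interaction; the interaction coefficient is the slope
  difference and its t test the p value. With zero residual variance
  (perfect fits) the p value degenerates and is set to 1 for a zero
  difference, 0 otherwise.
* Periodicity ("1st sinusoidal term"): the series is linearly detrended,
  the periodogram is evaluated at the Fourier frequencies k = 1 … n/2,
  and the maximum-power component — *not* the record-length fundamental,
  which could never produce a ~5-yr cycle in a 30-yr record — sets the
  period n/k. Amplitude and phase come from a least-squares sin/cos fit
  at that frequency. Significance is a permutation test: years are
  shuffled (1000 permutations by default, seeded), the maximum
  periodogram power is recomputed, and the add-one p value reported. The
  test's empirical size at α = 0.05 on white noise is checked to lie in
  0.05 ± 0.02. Because a discrete sinusoid is not exactly orthogonal to a
  linear term, recovery of a pure sinusoid is near-exact rather than
  machine-exact.

## 5. Regional aggregation (`regional`)

Equal-area pixels are assumed (default 625 km² for a 25 km grid; the
published area statistics are exact multiples of 625 km²). Totals:
`Σ mass[kg/ha] × area[km²] × 100 / 10¹²` Pg over the region mask (e.g.
the 150–600 mm mean-annual-rainfall belt; the mask is an input, never
inferred). Significant-trend areas count pixels at raw p < alpha per
slope sign — no multiple-testing correction, matching common practice for
published trend maps; a correction can be layered on by the caller. The
rainfall comparison mask is the strict inequality
`slope(rainfall_EL) > slope(rainfall_C)`.

## 6. Synthetic scenes (`synthetic`)

The generator emulates the sandy-Ferlo study conditions: nine pastoral
sites observed annually 1987–2016 in a 328 mm mean-rainfall monsoonal
rangeland with mean AGH ≈ 939 and mean WPF ≈ 362 kg ha⁻¹.

**Rainfall.** A core window (day-of-year 204–244 by default, matching the
regional mean season) carries 80% of the annual total as Bernoulli wet
days (p = 0.8) with gamma event sizes (shape 0.8); the remaining 20%
falls as discrete events in the early and late shoulders (early events
mean 7 mm, shape 1.2 — occasionally heavy enough to trigger the
first-rain clause, which is exactly the onset ambiguity the rule system
must face; late events mean 3.5 mm, shape 2.5 — small sporadic showers,
as late-season rain is). Core and shoulder totals drift at +0.7 and
+2.1 mm yr⁻¹. Expected annual totals and shares are calibrated
analytically, so annual sums fluctuate with realistic interannual
variability (CV ≈ 20%) around the configured means. The true split
(`rainfall_C`/`rainfall_EL` at the generator's window) conserves the
May–October sum exactly.

**Field biomass.**

    AGH = 3.58 [kg/ha/mm] × rainfall_C × (1 + a·sin(2πt/5 + φ)) + ε
    WPF = 2.5  [kg/ha/mm] × rainfall_EL + 198 + 11.75·(t − mid) + ε

The herbaceous rain-use efficiency 3.58 reproduces mean AGH = 939 at the
mean core rainfall (262.4 mm) and implies an injected AGH trend of
3.58 × 0.7 ≈ +2.5 kg ha⁻¹ yr⁻¹. The woody model combines an early/late
rain response with a slow stand-recovery drift (drought legacy); the
coefficients reproduce mean WPF = 362 and a total WPF trend of
2.5 × 2.1 + 11.75 = +17 kg ha⁻¹ yr⁻¹. The 5-yr cycle has amplitude
200 kg ha⁻¹ and phase φ = −3π/10 — the phase at which a 5-yr sinusoid is
orthogonal to a linear term on a 30-yr record, so the cycle does not
alias into the AGH trend and the injected trend is exactly what the trend
stage should recover. Noise is Gaussian (90/35 kg ha⁻¹) truncated at
zero. These defaults imply a mean total of ≈ 1300 kg ha⁻¹, a mean
herbaceous share of ≈ 73% and a share trend of ≈ −0.9% yr⁻¹.

**Satellite observations.** A linear observation model
`value = 1.5e-1 + 2e-4 × (WPF + g(doy)·AGH) + ε` (σ = 0.01) at 10-day
cadence, where the herbaceous greenness profile g ramps up over DOY
185–200, is 1 through DOY 255 and wilts to 0 by DOY 285; woody foliage
contributes year-round. With zero noise, p90 equals the wet-season
plateau and p30 the dry-season plateau exactly, so the calibration stage
recovers slope 1/2e-4 = 5000 and offset −750 to machine precision
(verified), and the full noise-free pipeline reproduces truth AGH/WPF
series, trends and the 5-yr cycle exactly.

One global seed is split into per-stage/site/year substreams
(`SeedSequence` spawn keys), so identical configuration gives
bit-identical scenes and any stage can be regenerated alone.

**What the generator does not emulate:** spatial autocorrelation between
sites, a bell-shaped seasonal rainfall profile (the core is a boxcar),
sensor-specific artefacts (orbital drift, compositing, soil background),
and any non-rainfall driver of biomass (fire, grazing, CO₂). Passing
closed-loop tests therefore demonstrates the correctness of the
algorithms under the stated causal structure, not the validity of that
structure for any particular sensor or region.

**A known, deliberate behaviour:** because growing early rains keep the
CR-5 store primed, the rule-detected onset drifts slightly earlier over a
record with increasing early rain, leaking part of the early/late trend
into rule-based `rainfall_C` (the detected window responds to the
changing distribution — the fixed-window variant, which recovers the
injected +0.7/+2.1 mm yr⁻¹ exactly, is the appropriate tool for trend
attribution and is what the regional analysis uses).

## 7. Problem sizes and runtimes

The test suite and the acceptance script generate everything they
consume. Sizes were chosen to keep Monte-Carlo error well below the
assertion tolerances: 24 replicate 30-yr nine-site scenes for field-trend
recovery (standard error of the mean AGH slope ≈ 0.65 kg ha⁻¹ yr⁻¹), 50
(script) / 100 (tests) replicate scenes for calibration recovery, 10,000
(tests) / 2,000 (script) random years for conservation, 500 white-noise
replicates × 1000 permutations for the permutation test's size, and
1000 permutations for reported p values. A single decomposition runs in
≈ 1 ms, a full scene in ≈ 0.7 s.

## 8. Known limitations

* The rule system is calendar-bound (1 May, 15 Aug, 31 Oct) and suited to
  single-monsoon regimes in the northern-hemisphere summer; it is not
  applicable unchanged to bimodal or southern-hemisphere seasons.
* Calibration is a single global linear model; no spatially varying or
  nonlinear calibration, and uncertainty is summarised by RMSE only.
* Trend inference ignores serial correlation; the permutation test
  assumes exchangeable years under the null.
* Gridded operations work on in-memory arrays; raster file I/O
  (GeoTIFF/NetCDF) is out of scope, CSV is the interchange format.
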