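# Methods

This note records the models, conventions and open design choices behind
`noisepop`, in the spirit of a model-documentation page: what is computed,
under which assumptions, and what the synthetic tests do and do not
demonstrate about real monitoring data.

## Decibel arithmetic and cumulative metrics

All level arithmetic happens in the energy domain `E = 10^(L/10)` in double
precision with no intermediate rounding; a metric is always
`10*log10(<energy statistic>)`. This makes every cumulative metric exactly
reproducible by a per-second loop, which the test suite exploits: the
vectorised implementations are compared against an independently written
brute-force loop on 1000 random gapped series and agree to better than
1e-9 dB.

Period conventions: the day is partitioned half-open as day [07:00, 19:00),
evening [19:00, 22:00), night [22:00, 07:00), classified in *local civil
time* obtained from the fixed UTC offset stored on each series (clock-time
penalties are a property of the local clock, so daylight-saving transitions
are resolved by whatever offset the series carries, never recomputed).
Ldn applies +10 dB to night seconds; Lden additionally +5 dB to evening
seconds; Lnight is the unpenalised night average. Because penalties are
nonnegative, `Lden >= Ldn >= Leq24` holds on every input, and adding a
constant c dB to every sample shifts every metric by exactly c; both are
asserted as properties.

Missing seconds are absent from the timestamp vector, never zero-filled
(0 dB is a level, not "no data"). Metrics are computed over the seconds
present; a coverage fraction rides along and a warning fires below 90 %
coverage by default, because monitoring campaigns often record only during
active operations. A configurable silence floor (default 0 dB) stands in for
-inf when synthesizing quiet periods, avoiding log-domain singularities.

L95 — the residual-sound estimator — uses the deterministic nearest-rank
percentile (sorted ascending, element `ceil(0.05 n)`), matching its
sort-based oracle exactly rather than an interpolated quantile.

Ldnmr, the monthly energy average used for sporadic special-use airspace, is
implemented as a pure energy mean of monthly Ldn values with a pluggable
per-month onset-rate penalty hook that defaults to zero: the magnitude of
the military onset-rate adjustment is defined in service-specific technical
documents, not in the open literature, so the package ships the neutral
default and logs that no adjustment was applied.

Occupational dose: `dose% = sum_t dt / T_allowed(L_t) * 100` with
`T_allowed(L) = Tc * 2^((Lc-L)/ER)`; OSHA uses Lc = 90 dBA, ER = 5 dB and a
90 dBA integration cutoff, NIOSH Lc = 85 dBA, ER = 3 dB, cutoff 80 dBA, both
with an 8-h criterion duration. The time-weighted average is back-computed
from the dose over a reference duration, 24 h by default (the residential
"around-the-clock exposure" convention): `TWA = Lc + ER*log2(dose/100 *
Tc/Tref)`. Dose is exactly 100 % for criterion-level exposure of criterion
duration regardless of the reference duration.

## Event detection

The detector follows standard aircraft-noise monitoring practice:

1. **Smoothing.** A 10-s *centred* moving energy average (trailing alignment
   available by config; centred was chosen because it does not bias event
   boundaries late). Partial windows are used at edges; data gaps bound the
   window, and no value is invented for missing seconds.
2. **Adaptive threshold.** Per second: `max(L95(+/-30 min) + 15 dB, 50 dB)`.
   The 50 dB floor is by construction baseline ambient (35 dB) + margin
   (15 dB); the margin reflects the convention that aircraft maxima should
   measure at least 15 dB above residual sound. The alternative reading
   `max(L95, 50)` is available via `threshold_mode="l95_or_floor"` — the
   chosen default keeps the two clauses of the construction mutually
   consistent (at L95 = 35 both branches give 50). The rolling L95 is exact:
   a sorted sliding window updated sample by sample, not a block
   approximation.
3. **Hysteresis.** An event starts when the smoothed level exceeds the
   threshold and terminates once it has stayed below for 5 consecutive
   seconds; the termination clock runs on the smoothed signal (it is the
   detection signal). Any data gap terminates an event unconditionally — a
   gap carries no evidence of continuity.
4. **Validity.** Detections whose *raw* 1-s maximum is below the local
   residual + 15 dB are dropped.
5. **Subdivision.** Detections containing multiple smoothed peaks separated
   by a dip of at least 6 dB prominence (scipy `find_peaks` semantics,
   configurable) are split at the minimum between adjacent peaks, so the
   children partition the parent span and their summed LE energy equals the
   parent's.

Event metrics are always computed from the raw series — smoothing attenuates
true maxima — with LE the energy sum of in-event 1-s levels (1-s reference),
so a single-second event has LE = Lmax and longer events have LE >= Lmax.
Event boundaries are reported at the first/last second the smoothed level
exceeded the threshold: reproducible and faithful to the detection
semantics, at the cost of clipping low-level onset/decay tails.

## Exposure-response registry

Curve coefficients are data, not code: a YAML registry validated at load
time (schema, responses within [0, 100], nondecreasing on a 0.1 dB grid,
with load errors naming the offending curve). Outside the declared domain,
the standard capping rule applies: zero below, the domain-top response
above. Annoyance curves other than FICON are defined to 75 dB Ldn; the
sleep curves to 65 dB Lnight — populations beyond those levels are exposed
to levels outside the range of the underlying surveys, and the cap is a
deliberate (conservative) floor on what the true response there might be.

Curves whose sources define them on Lden (ISO, WHO, Yokoshima) are evaluated
on Ldn by the pipeline, the standard US practice where no evening penalty is
modelled; this slightly understates responses and is logged at registry
load. FICON, ISO and the two WHO curves are verbatim transcriptions of
published coefficient sets. The NES, Yokoshima and Smith entries are
monotone logistic/quadratic fits through widely quoted summary points of the
published curves, because the primary coefficient tables could not be
bundled; their registry `source` fields say so, and the qualitative
structure they must reproduce — Yokoshima above WHO above FICON throughout
55–75 dB, the roughly four-fold NES/FICON gap at typical exposures, Smith
slightly above WHO for sleep — is asserted by test with a failure message
pointing back at the transcription.

The learning-delay rule is a step function: (0, 0) months below 55 dB Ldn,
then (1+n, 1+2n) months where n is the number of *completed* 5-dB increments
above 55 — the flooring is the only reading consistent with a 60–63 dB
exposure mapping to 2–3 months. Because an annual-average-day level assumes
365 days of flying while schools are occupied about 180 days, an optional
school-year adjustment adds `10*log10(365/180)` (+3.07 dB) to concentrate
the annual energy into the school year; the sign is configurable
(`concentrate`/`dilute`/`none`) since either convention appears in practice,
and reports carry the adjusted and unadjusted levels side by side, with the
unadjusted level the default.

## Dasymetric population mapping

Blocks are distributed at 30 m using developed, non-transportation land
cover as the ancillary layer. Choices, in order of the invariants they
protect:

- **Cell-centre assignment** of cells to blocks (first block in block-id
  order wins a boundary tie): deterministic and simple; area-weighted
  splitting is noted as future work.
- **Equal split** of a block's population among its masked cells (no
  impervious-fraction weighting — the sources give no weights; a weighting
  hook exists).
- **Uniform fallback** over all of a block's cells when it has no masked
  cell, and nearest-representative-point placement when a sliver block
  contains no cell centre at all: population mass is *never* dropped, so the
  raster total equals the block total to machine precision (asserted at
  1e-6 relative over 100 random fixtures).
- Fractional persons are kept end-to-end; rounding to integers happens only
  when report tables are formatted.

Contour rasterization assigns each cell centre the highest-level contour
containing it (lower-bound-inclusive 1-dB bins); centres exactly on a
boundary go to the higher contour, which never understates exposure. All
geometry must be in one projected CRS in metres and all grids must share
their transform exactly — there is no silent reprojection or resampling.

Overlapping tribal regions are summarised independently of the counties
that contain them; study totals are computed over the whole raster, which
equals the sum over the mutually exclusive county regions only. Region
percentages use total regional population as the denominator.

## Impact accounting and scenarios

Outcome estimation is per-cell: `response(level)/100 * population`, summed
per region, with below-domain cells contributing zero. It follows that for
every curve, affected persons never exceed the persons exposed at the
curve's domain-low threshold; this and regional additivity are asserted.
School exposure is point-sampled from the containing cell, without
interpolation — the surfaces are 1-dB step data and interpolation would
fabricate precision. Schools within 5 dB below the 55 dB threshold are
flagged as near-threshold.

The operations-scaling sweep shifts every surface by `10*log10(k)` dB for a
scale factor k of total operations. Under energy-additive cumulative metrics
this is the *exact* consequence of multiplying every event count by k while
holding the fleet mix, tracks and diurnal pattern fixed; it is a
demonstrative surrogate for re-running a full propagation model with a
re-designed schedule, and results are labelled accordingly. k = 1 adds
literally 0.0 dB, so the baseline is reproduced bit for bit; outcomes are
nondecreasing in k because every estimator is nondecreasing in level.

## Synthetic data: what it emulates, what it does not

The generator produces every input with known ground truth.

- **SPL series**: Gaussian dB jitter (default sd 1.5 dB) around a constant
  ambient, plus overflight events with a triangular-in-dB envelope (default
  onset 2.5 dB/s, decay 1 dB/s — fast rise, slower fall), energy-summed with
  the background. The triangular envelope is a two-parameter idealisation
  that is analytically integrable, so ground-truth LE and Lmax come from
  direct summation. Injected peaks in the recovery studies are drawn
  20–40 dB above the 35 dB ambient; measured military overflights typically
  peak 50–85 dB above ambient, so this is conservative while still
  satisfying the 15 dB-above-residual validity bound with margin.
- **Operations schedule**: events pick day/evening/night with probabilities
  0.70/0.20/0.10 and weekdays with mix 0.914/0.071/0.014
  (Mon–Thu/Fri/weekend; the printed mix sums to 99.9 % and is renormalised),
  matching a military training tempo; session windows default to
  11:30–23:30, 30 min–3 h.
- **Noise surfaces**: point sources with reference SEL 100 dB at 300 m,
  spreading exponent 2 and 3 dB/km absorption on the default world —
  parameters chosen so a 6 x 6 km, 200 x 200-cell world spans from below
  every health threshold to above 90 dB Ldn near the sources, with the
  hearing-risk (70 dBA Leq24) area confined to the immediate airfield
  surroundings. Each operation deposits one SEL per source; night operations
  carry the +10 dB penalty into the Ldn accumulation. Receiver-cell
  distances are floored at half a cell width. Doubling every operation count
  raises every surface by exactly 3.01 dB, which independently validates the
  scenario surrogate.
- **Census**: Voronoi blocks with log-normal populations rescaled to an
  exact total (default 50,000), an urban cluster of blocks at 60 % developed
  cover versus 8 % rural, a transport cross, two counties, one overlapping
  tribal region and five schools.

Not emulated: realistic jet spectra, Doppler, terrain shielding or weather-
dependent propagation; correlated ambient (wind, surf, traffic); census
undercount or diurnal population movement. Passing the synthetic recovery
tests therefore demonstrates the *accounting machinery* is exact and the
detector is reliable under idealised signal shapes — not that detection
performance transfers to heavy-tailed real ambients, which is why the
detector's margin, prominence and threshold mode remain configurable.

## Problem sizes and numerical tolerances

Default verification sizes: 1000 random series (600–2400 s) for the metric
oracle study, 200 seeded replicates for event recovery, 100 random block
fixtures for mass conservation, and a 200 x 200-cell world for end-to-end
recovery — sizes at which every check is exact (1e-9 dB; 1e-6 relative on
person counts) rather than statistical. Ties are broken deterministically
throughout (nearest-rank percentiles, first-wins block assignment,
higher-contour boundaries), and rerunning any pipeline with the same config
and seed reproduces every output file byte for byte.

## Known limitations

- Point estimates only: the confidence bands published around the
  exposure-response curves are not propagated.
- The three approximately transcribed curves (NES, Yokoshima, Smith) carry
  transcription uncertainty of order 1–2 percentage points at a given level.
- The scenario surrogate cannot represent changes in *where* or *when*
  operations occur, only how many there are.
- Indoor levels, speech interference and cardiometabolic/psychological
  outcomes are out of scope.
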