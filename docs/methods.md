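# Methods

## Scope and data model

The package analyses a single-site indoor record of air temperature (°C)
and relative humidity (%) sampled on a regular sub-hourly grid (15 minutes
by default), as produced by a consumer data logger. Readings are
timezone-aware throughout: loggers typically record in GMT and the analysis
is performed in local clock time (GMT+2 by default), because the exposure
questions — when is it hot, when do people sleep and work — are local-clock
questions. Timestamps without an explicit UTC offset are rejected rather
than guessed.

The canonical in-memory container is a pandas `DataFrame` indexed by
timezone-aware timestamps with columns `air_temp_c`, `rel_humidity_pct`
and optionally `dew_point_c`. Input plausibility gates (−40…60 °C,
0…100 %, dew point ≤ air temperature) are hard errors in the computational
layer — a logger fault should surface, not be clipped away — while the CSV
reader excludes invalid rows, reports their file line numbers, and treats
more than 10 % invalid rows as a wrong-dialect error.

## Humidex

Humidex is computed in its humidity-driven form,

    Humidex = T + (5/9)·(e − 10),  e = 6.112·10^(7.5T/(237.7+T))·H/100,

i.e. the Magnus saturation vapour pressure scaled by relative humidity.
The same Magnus constants (6.112 hPa, 7.5, 237.7 °C) are used by the
dew-point ↔ relative-humidity conversions so that either moisture variable
can drive the pipeline without internal inconsistency. Useful structural
facts, all enforced by tests: Humidex is strictly increasing in both
arguments, equals `T` exactly at a vapour pressure of 10 hPa, and collapses
to `T − 50/9` in dry air.

## Heat Index

The Heat Index is the NWS 16-term polynomial regression in temperature
(°F) and relative humidity (%), plus its closing +0.5 °F constant. Input
°C is converted to °F internally; the output is returned both in °F and as
the exact °C re-conversion. The coefficient vector is data
(`indices.HEAT_INDEX_COEFFICIENTS`), not hard-coded arithmetic, for two
reasons:

* Published transcriptions of this equation are error-prone. The typeset
  variant this package was built against contains three defects relative to
  the canonical NWS vector — the constant (16.023 for 16.923), the T²R²
  coefficient (1.01202×10⁻⁵ for 1.02102×10⁻⁵, transposed digits) and a
  fatal sign-of-exponent error in the T³R term (10⁶ for 10⁻⁶) that makes a
  literal transcription produce values around 10¹³ °F. The canonical vector
  is the default; the as-printed vector is retained as
  `HEAT_INDEX_COEFFICIENTS_AS_PRINTED`, documented and tested as
  numerically unusable, purely for provenance.
* Keeping coefficients as data lets the independent 9-term Rothfusz
  regression in the test suite act as arbiter of any future edits.

On the agreement between the two published fits: the often-quoted ±1.3 °F
accuracy of the Rothfusz 9-term regression holds against the tabulated
apparent-temperature data both fits descend from. Outside that table — in
particular the simultaneously hot *and* saturated corner (towards 110 °F at
100 % RH) — the two polynomials are both extrapolating and diverge from
each other by many °F. The tests therefore pin their agreement at an
interior reference point (90 °F, 50 %: 96.05 vs 94.60 °F) rather than over
an arbitrary rectangle. A `HeatIndexExtrapolationWarning` is emitted
whenever the index is evaluated below 80 °F, which indoor residential
series routinely are at night; the pipeline computes the value anyway (for
comparison against the categorical thresholds, all of which sit above
80 °F) but flags the extrapolation.

## Classification schemes

A scheme is an ordered list of bands, each with a lower bound (inclusive),
an integer severity level and guidance text; a value classifies into the
last band whose bound it reaches, so edges are lower-inclusive /
upper-exclusive and classification is a total, monotone function of the
value. Thresholds live in a bundled YAML file, not in code.

The two Humidex schemes follow the OHCOW Humidex-Based Heat Response Plan
ladder: level 0 no heat stress, 1 water as needed, 2 alert notice + extra
water, 3 warning notice + symptom awareness, 4 work with 15 min relief per
hour + cool (10–15 °C) water ≥240 ml/20 min, 5 and 6 with 30 and 45 min
relief per hour, 7 only medically supervised activity. The exact numeric
boundaries in the source study are available only as a typeset table, and
the canonical OHCOW bounds contradict two of the four worked
classifications printed in its text. The bundled bounds are therefore a
**constrained transcription**: the closest ladder satisfying all four
worked examples (33.82 → level 1 acclimatised / level 2 unacclimatised;
42.26 → level 3 / level 6; 24.50 → level 0 / level 0), with the
unacclimatised thresholds everywhere at or below the acclimatised ones so
that the unacclimatised level is never the less severe. Loading the bundled
file re-verifies the four anchors; a transcription edit that breaks them
fails at load time, not at analysis time. The NWS Heat Index categories are
the standard 80/90/103/125 °F boundaries expressed on the °C scale of the
re-converted index.

## Exposure summaries

* Time-of-day bins: morning 06:00–10:59, midday 11:00–13:59, afternoon
  14:00–17:59, night 18:00–05:59 (local clock; night spans midnight). The
  four bins partition every minute of the day; a reading is attributed to
  the calendar time at which it was taken, not to a "shift date".
* Statistics use the sample (n−1) standard deviation. Extrema report the
  value and *all* timestamps attaining it (multi-way ties are real in
  logger data and occur in the motivating record).
* Per-level proportions are plain percentages of the observed reading
  count; missing grid intervals are not imputed — imputation would
  manufacture exposure. Excluded-row counts are carried through to the
  report.
* Exceedance (`% of readings at level ≥ L`) is provided because "level 4
  or more" is the natural trigger for mandated work-rest cycles.

## Roster overlay

Shifts are half-open intervals `[start, end)` with a role label; overlaps
within a role are rejected, durations above 36 h fail a sanity gate. For
bin attribution each shift is cut at every bin boundary it crosses
(including midnight) and each segment's duration credited to its bin, so
bin hours sum to shift hours exactly. Reading membership in a shift is
start-inclusive / end-exclusive, which makes consecutive shifts compose
without double-counting; on-duty and off-duty incidence tables partition
the series.

## Synthetic generator

The generator emulates the statistical structure the analysis assumes, so
every stage is testable without the unreleased study data:

* **Temperature**: a single diurnal harmonic peaking at `diurnal_peak_hour`
  (default 17.5, matching an observed late-afternoon maximum), plus a
  stationary AR(1) process (`ar1_coefficient`, default 0.9 at 15-minute
  resolution) and an independent Gaussian day-level offset (default SD
  1.2 °C) representing synoptic day-to-day variability. The composite is
  linearly rescaled to the exact target sample mean and SD (defaults
  28.96 °C and 2.49 °C, the published study marginals).
* **Relative humidity**: a mixture of the (negated, standardised)
  temperature signal and an independent AR(1) — weighted to give Pearson
  correlation `temp_rh_correlation` (default −0.6) — plus Poisson-timed
  evening storm events (default 0.3/day, onset uniform in 15:00–22:00)
  each adding an exponentially decaying boost (default 15 % points, 2.5 h
  time constant). The composite is rescaled to the target marginals
  (defaults 47.24 % and 7.63 %) and clipped into (0, 100]. Implementing the
  anticorrelation through the shared diurnal signal, rather than
  joint-normal sampling, mimics the physical mechanism — daytime heating
  depresses RH — and reproduces nocturnal humidity maxima.
* **Randomness**: one root seed, split into three documented child streams
  (temperature, humidity, storms) via `numpy`'s generator spawning, so a
  config is a bit-reproducible fixture.

The default window is the ~34-day early-summer study period
(2023-11-26 16:00 → 2023-12-30 08:45 UTC+2, 3236 grid readings).
With the default calibration the mean Humidex of a generated month lands
within a few hundredths of the published dataset mean (33.82 °C) — a
consequence of two nearly cancelling effects the generator reproduces: the
convexity of saturation vapour pressure in T raises the mean Humidex, while
the negative T–RH covariance lowers it.

What the generator does **not** emulate: logger gaps and faults (the
generated grid is exactly regular; the real record has a handful of missing
intervals), multi-day heatwave persistence beyond AR(1)+day offsets,
humidity saturation plateaus during long rain, and any building-physics
response. Passing calibration tests therefore demonstrates the pipeline's
correctness and the plausibility of its summaries, not a claim about any
particular building.

`estimate_params` inverts the generator's identifiable parameters: marginal
means/SDs directly, the diurnal amplitude and peak hour by a one-harmonic
least-squares fit of temperature on clock time, the AR(1) coefficient as
the lag-1 autocorrelation of the harmonic residuals, and the T–RH Pearson
correlation. It requires ≥2 days of data (one day cannot separate the
harmonic from the day offset). Note the recovered amplitude describes the
*output* series; because the generator rescales to target marginals, it
will not in general equal the configured pre-scaling amplitude.

## Numerical and design choices

* Classification uses `numpy.searchsorted` over the band bounds;
  band-edge values classify upward (lower-inclusive), a stated convention
  since the source material never specifies edge handling, overridable by
  supplying a custom scheme file.
* JSON reports exclude the output directory from the echoed config and
  contain no wall-clock fields, so identical config + seed reproduces a
  byte-identical report; wall-clock and library versions go to the run log.
* CSV round-trips are lossless: floats are written as shortest
  round-trip reprs and parsed with pandas' `round_trip` converter.
* Problem sizes in the test suite are chosen for tight feedback: the
  calibration and parameter-recovery checks use the 34-day default window
  and twenty 10-day replicates respectively, which already pin the means
  to ±0.2 °C.

## Known limitations

* The Humidex band boundaries are a constrained transcription (above);
  analyses hinging on values near an interior band edge (±0.5 °C) should
  treat the assigned level with corresponding caution.
* The Heat Index is extrapolated below 80 °F rather than reported as
  missing; the warning is the user's hook to mask those readings if they
  prefer the NWS convention of not defining the index there.
* Exposure is environmental, not personal: no clothing, exertion,
  radiation or air-movement terms (Humidex and Heat Index are shade,
  light-wind indices by construction).
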