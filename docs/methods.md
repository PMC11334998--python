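# Methods

This note documents the models behind each stage, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the package's known limitations.

## Beat detection from carrier-interruption audio

The transmitter signal is a continuous carrier tone gated off for a few
milliseconds by each cardiac muscle potential.  Detection therefore
looks for *dips*, not peaks:

- **Envelope**: moving RMS, 2 ms window.  Shorter windows track the
  15 ms interruptions sharply; the window must span ≥2 samples.
- **Threshold**: 0.5 × a rolling median of the envelope (5 s scale,
  computed blockwise at 0.5 s resolution for speed).  A relative
  threshold makes detection invariant to receiver gain and slow carrier
  fading; this is asserted as a scale-invariance property test.
- **Event time**: the onset of each sub-threshold run, because the
  interruption begins at the beat.  On noise-free synthetic audio this
  recovers scheduled beat times to a fraction of a millisecond.
- **Refractory merge**: events closer than 40 ms are merged keeping the
  deeper dip.  40 ms caps detectable rates at 1500 b.p.m., safely above
  the ~900 b.p.m. flight maximum of a small bat.  Setting the
  refractory above the true inter-beat interval aliases the count to
  half — a documented failure mode with a test.
- **Aggregation**: heart rate per half-open 1-min window is
  60 / median(accepted inter-beat intervals); intervals whose implied
  rate is outside [10, 1100] b.p.m. are rejected, and the accepted
  fraction becomes the window's quality score.  The median tolerates
  isolated missed beats (one dropped beat creates a doubled interval
  that would bias a mean).  Windows with no accepted interval are
  gap-flagged; manual counts can be spliced in (`manual_override`),
  with later annotations winning on overlap.

The detector is envelope-generic rather than matched-filter: the
interruption morphology varies between transmitter/receiver
combinations, and no waveform template is assumed.

## Open-flow respirometry

The forward model (in `synth`) is a well-mixed chamber of volume V
(default 800 ml) pulled at excurrent flow F (default 150 ml/min):

    dF_x/dt = (flow_in · F_in,x − flow_ex · F_x + S_x) / V

with S_O2 = −V̇O₂ and S_CO2 = +RER·V̇O₂, and
flow_in = flow_ex + V̇O₂ − V̇CO₂ (total balance at constant pressure).
The washout time constant is V/F = 5.33 min, so a step change is 95%
expressed after 16 min — asserted against the closed-form first-order
response.  The analyzer sees chambers through a multiplexer (default
dwell 120 s, baseline channel first), with the CO₂ signal delayed by a
configurable transit lag, additive drift on either gas, water-vapour
dilution F_wet = F_dry·(BP−WVP)/BP, and Gaussian analyzer noise.

The inversion chain:

1. **Split and discard**: the first 30 s after each channel switch are
   dropped (analyzer cell still flushing the previous channel).
2. **Drift correction**: a cubic smoothing spline
   (`scipy.interpolate.make_smoothing_spline`, λ by generalized
   cross-validation) through the baseline channel's deviation from the
   nominal incurrent composition (O₂ 0.2095, CO₂ 0.0004) is subtracted
   from all channels.  At least two baseline visits are required or the
   drift is unidentifiable.
3. **Lag alignment**: the CO₂ lag is the arg-max of the
   cross-correlation between −ΔF_O2 and +ΔF_CO2 within ±60 s.  On a
   multiplexed trace the synchronized switch transients dominate and
   the estimated lag is ~0 (harmless: segment means at quasi-steady
   state are lag-insensitive); on continuous single-chamber traces an
   injected 8 s lag is recovered exactly.  Flat series return lag 0
   with a warning; estimates saturating at the window edge warn.
4. **Dry correction**: F_dry = F·BP/(BP−WVP), homogeneous of degree
   zero in the two pressures.
5. **Nitrogen balance** (pull mode, excurrent-metered):

       flow_in = flow_ex · (1 − FeO₂ − FeCO₂) / (1 − FiO₂ − FiCO₂)
       V̇O₂  = flow_in · FiO₂  − flow_ex · FeO₂
       V̇CO₂ = flow_ex · FeCO₂ − flow_in · FiCO₂

   Incurrent fractions are interpolated from the corrected baseline
   channel, not assumed constants.  This algebra is exact for the
   forward model above: the end-to-end oracle recovers any
   piecewise-constant V̇O₂ schedule within 1% at steady state, and the
   result is independent of chamber volume (volume shapes only the
   transient).  Note that the steady-state O₂ depletion is
   V̇O₂·(1 − (1−RER)·FiO₂)/flow, not exactly V̇O₂/flow — the ~3%
   flow correction matters at the 1% recovery tolerance.
6. **Units and energy**: V̇O₂ is standardized by the mean of body mass
   before and after the experiment (ml O₂ g⁻¹ h⁻¹) and converted with
   the caloric equivalent of oxygen, 20.083 J per ml O₂.

Negative computed V̇O₂ beyond a small tolerance is flagged, never
silently clipped.  Transients are retained but identifiable by time
since switch; no instantaneous (Z-) transformation is applied.  Push
mode and stop-flow systems are out of scope.  STP correction is assumed
embodied in the mass-flow-controller readings.

## Heart-rate → VO₂ calibration

Per individual, OLS of ln(V̇O₂) on ln(HR) — natural logs throughout, so
the slope is the elasticity of metabolism with respect to heart rate
(b ≈ 1.1 means a 10% rise in HR costs ~11% more oxygen).  Mass-specific
V̇O₂ enters the regression; body mass is re-multiplied at prediction.
Requirements: ≥3 pairs, strictly positive values, ≥2 distinct rates.
Predictions outside the calibrated HR span are returned but flagged as
extrapolation (field flight rates routinely exceed laboratory rates).
Validation is a pooled coefficient of determination on held-out pairs.
The per-individual OLS is deliberate; no hierarchical pooling across
individuals is attempted.

The generator's default shared power law (a = −4.99, b = 1.09 on the
mass-specific scale, with between-individual scatter 0.10/0.03) was
anchored by least squares to the canonical phase-level pairings of
heart rate and energy expenditure for this study system (torpor
~26 b.p.m. ↔ ~0.12 kJ/h, spring daytime 74 ↔ 0.47, summer daytime
252 ↔ 1.42, flight ~730 ↔ ~5 kJ/h at 27.3 g); a single power law cannot
hit all anchors exactly, and the compromise fit reproduces each to
within ~15%.

## Day-phases, torpor classification, DEE

- A **bat-day** runs sunrise to sunrise (NOAA solar geometry at the
  roost coordinates; default 47.67° N, 9.18° E), so each night belongs
  to exactly one bat-day.  **Daytime** is sunrise→emergence (first
  flight after sunset), **flight** comes from a log or is auto-detected
  as ≥500 b.p.m. sustained ≥3 min, **nighttime** is the remaining
  roosting time.  Flights shorter than 3 min keep their phase minutes
  but are excluded from flight summaries.  Recordings before the first
  flight of a deployment are dropped (post-handling behaviour).
- **States**: heart rate is smoothed with a 5-min rolling median;
  minutes below 100 b.p.m. are torpid, above 150 b.p.m. resting, and
  minutes between thresholds or changing faster than 10 b.p.m./min are
  transitional (entry when heading into torpor, arousal when leaving,
  named from the neighbouring stable states).  Stable bouts shorter
  than 10 min are demoted to transitional; gaps split bouts.  The
  100/150 hysteresis pair sits far from both the torpid (26 ± 9) and
  resting (200–400) regimes, which is why per-minute recall and
  precision against generator truth exceed 0.99.  These thresholds
  replace the visual inspection a human scorer would do; all four
  parameters are configurable.
- **Means** are two-stage: within bat-day first, then across days, so
  long days do not outweigh short ones.  Daily contributions with under
  30 observed minutes in a category are dropped — a six-minute sliver
  of a trailing day must not carry the weight of a full day.  Relative
  time torpid uses roosting minutes as the denominator.
- **DEE**: measured energy is the time-integral of the kJ/h series over
  observed minutes; each phase's gap minutes are filled at that phase's
  mean observed rate for the same bat-day, and DEE is the sum across
  phases (energy conservation asserted to 10⁻⁹ kJ).  Exclusions:
  gap fraction >35%; any phase with positive duration entirely gapped
  (its mean rate is undefined); partial first/last days under 65%
  coverage.  The fill rule is unbiased under missing-completely-at-
  random gaps — verified by simulation: the across-replicate mean DEE
  at 20% gaps stays within 5% of the no-gap integral — but individual
  gappy days can deviate more when a gap lands on a torpor bout versus
  an arousal spike.
- **Group summaries**: percent-of-DEE per phase and time-budget
  fractions are computed per bat-day, then averaged; percent changes
  between groups are reported at integer precision.

## Prey equivalents

`insects_needed` divides DEE by assimilated energy per item
(efficiency × gross energy, default 0.75 × 1.86 kJ for a June beetle)
and rounds to nearest — rounding to nearest rather than ceiling keeps
the count and the seasonal difference mutually consistent.
`minutes_fueled` applies the same assimilation convention in the other
direction (60·η·E/rate), so minutes × rate always equals assimilated
energy per item exactly.  With one fixed convention not every
published minute figure for this kind of arithmetic can be reproduced
simultaneously (some are computed on gross energy); consistency is
preferred over matching every printed value, and η = 1 removes
assimilation from all outputs as a limit check.

## The synthetic study and its limits

`run_pipeline` simulates 4 spring + 4 summer bats for 3 days each
(16 retained bat-days after the partial-day exclusions), 10% recording
gaps, and per-individual calibrations around the shared power law.
Generator conditions: spring profiles torpid ~84% of daytime and ~22%
of nighttime roosting with brief midday arousals (torpor HR 26 ± 9
b.p.m.), summer profiles never torpid (daytime 252 ± 49, clipped to the
200–400 band's surroundings), flights at 600–900 b.p.m. (1–2 per spring
night totalling ~59 min; 1–5 per summer night totalling ~105 min),
torpor entry/arousal as exponential ramps (time constant 20 min,
truncated at 30 min).  Ambient temperature is a sinusoidal diel cycle
(spring mean 13.5 °C, summer 18.5 °C) exported as a covariate only.

What the generator does *not* emulate: radio propagation and receiver
electronics (dropout is a flat random deletion, not interference
bursts), individual behavioural idiosyncrasies beyond calibration
scatter, weather-driven arousal timing, and any coupling of torpor
depth to ambient temperature.  Passing tests therefore demonstrate that
the chain inverts its own forward models and obeys its filters — not
that the thresholds are optimal for any particular field dataset.
Group-level DEE means vary noticeably between seeds (spring ≈ 24–30
kJ/day, summer ≈ 43–49 kJ/day, change ≈ +45–80%) because 8 bat-days per
group is a small sample — the same order of sampling noise a field
study of this size carries.

Simulation sizes throughout (60 s audio clips, 60–120 min gas traces,
72 h profiles, 200 replicate calibrations) were chosen as the smallest
sizes at which the Monte-Carlo error is comfortably below each check's
tolerance.

## Numerical choices

- Chamber ODEs: explicit Euler at 1 s steps (τ = 320 s, so the scheme
  is far inside its stability/accuracy region); chambers start at the
  steady state of their schedule's initial level.
- Rolling medians: blockwise (0.5 s blocks at audio rate, 5-sample
  windows at minute rate) — exact rolling medians at audio rate are
  quadratic in window length for no accuracy benefit here.
- Seeds: every generator takes an explicit seed; the pipeline derives
  per-bat seeds from the run seed by fixed affine maps (kept below
  2³¹), making output tables byte-identical across reruns.
- Timestamps are ISO-8601 UTC throughout; solar events are computed in
  UTC once at segmentation.
- Degenerate inputs fail loudly: empty traces, all-silent audio,
  rank-deficient calibration designs, dwell ≤ discard, WVP ≥ BP, and
  unknown season labels all raise with specific messages.

## Known limitations

- The lag estimator is uninformative on multiplexed traces (switch
  transients are synchronous across gases); it is intended for
  continuous segments.
- `classify_states` on a full series labels flight minutes "resting";
  the phase mask applied in `annotate_minutes` removes them, so state
  labels are only meaningful within roosting phases.
- Sunrise-to-sunrise bat-days are 1437–1443 min depending on season;
  budget partitions are exact for the actual day length, not a nominal
  1440.
- No inferential statistics (mixed models, post-hoc contrasts) are
  provided; exported CSVs are meant to feed standard statistical
  tooling.
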