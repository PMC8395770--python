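# Methods

## The translation pipeline

The package converts one graded exercise test (GXT) into first-session
treadmill prescriptions in four steps.

1. **Target heart rate.** For resting HR `hr_rest` (standing, pre-test) and
   maximal HR `hr_max` (the observed test-end value), the target at reserve
   fraction *f* is `THR = hr_rest + f·(hr_max − hr_rest)`. Defaults
   *f* = 0.6, 0.7, 0.8 — surrogates for easy, moderate and hard training.

2. **Crossing location.** Stage-end HR measurements are regularized to be
   non-decreasing by cumulative maximum (a maximal test's HR trend is
   monotone; dips are treated as measurement noise) and the *first* crossing
   of the THR is found by linear interpolation in time. The workload
   attributed to the crossing is the belt state in effect at that instant —
   piecewise-constant per stage, with a crossing exactly on a stage boundary
   belonging to the completed stage, since the measurement made there
   reflects that stage. RPE is linearly interpolated at the crossing time
   (the field reports it at 0.5-unit resolution; the full-precision value is
   kept internally and files store full precision).

3. **MET cost and translation.** The workload's oxygen cost comes from the
   conventional treadmill equations (walking `0.1·s + 1.8·s·g + 3.5`,
   running `0.2·s + 0.9·s·g + 3.5`, speed in m/min, grade fractional). The
   training intensity is `0.72 × GXT METs`; 0.70–0.75 is the sanctioned
   range, 0.72 the default.

4. **Back-solving.** Both equations are linear, so the inverse problems are
   closed-form. Candidate speeds are the GXT's own stage speeds plus the
   conventional 1.34 m/s walk and 2.68 m/s run; speeds in 1.79–2.23 m/s are
   excluded (neither gait is comfortable there), and the flattest feasible
   candidate (smallest |grade|, ties to the slower speed) is prescribed.
   Sessions default to 5 min warm-up at 1.33 m/s / 20 min work / 5 min
   cool-down.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| translation factor | 0.72 (dimensionless) | sustained-to-incremental MET ratio |
| HRR fractions | 0.6, 0.7, 0.8 | prescribed intensity levels |
| avoided band | 1.79–2.23 m/s | walk/run transition speeds never prescribed |
| walking validity | ≤ 107 m/min | warn (or raise in strict mode) beyond it |
| running validity | ≥ 134 m/min | `jogging=True` acknowledges slow running |
| grade limits | −20% to +30% | treadmill mechanical range |
| agreement bands | ±10 bpm, ±1 RPE | closed intervals in all proportions |

## Numerical conventions

- Internal units: speed m/min (1 mph = 26.8224 m/min, 1 m/s = 60 m/min),
  grade as a fraction. Files store grade in percent and declare speed units
  via header suffix (`speed_m_s`, `speed_mph`, …).
- Inverse solvers reproduce the forward equations to 1e−9; a required grade
  outside the treadmill range raises an infeasibility error carrying the
  unclamped value.
- Costs at speeds inside the avoided band (legal in GXT protocols) use the
  walking equation up to 2.0 m/s and the running equation above, with a
  warning; the band midpoint is a neutral split where the literature is
  silent.
- MET values *displayed* at one decimal are computed from VO₂ first rounded
  to the conventional 0.1 mL·kg⁻¹·min⁻¹ reporting precision
  (`display_mets`); exact conversion (`mets`) is used everywhere internally.
  This matches how published MET tables are derived from reported VO₂.
- Validity-range enforcement warns by default and raises only in strict
  mode, because applying the walking equation slightly beyond its nominal
  range is common practice.

## Agreement statistics

A bout is summarized by the mean of its 15-, 20- and 25-min HR/RPE samples
(flagged incomplete when a window sample is missing). Predicted vs achieved
comparisons report, per intensity: means ± SD, a paired t-test (zero
variance of differences is flagged degenerate rather than tested), Pearson
r, within-band proportions, and Bland–Altman bias with 1.96·SD limits of
agreement. Sign conventions are fixed and printed in every report header:
paired difference = predicted − achieved; Bland–Altman bias =
mean(achieved − predicted). Because "repeated measures ANOVA" admits both a
per-intensity and a two-way reading, both are available: per-intensity
paired t-tests, and a two-way within-subject decomposition
(measurement × intensity) with Tukey HSD across cell means; neither is
asserted as the canonical analysis.

## The synthetic generator

Each synthetic subject has an affine internal-load model: HR rises linearly
with MET demand from `hr_rest` at 1 MET to `hr_max` at capacity `max_mets`,
and RPE rises linearly with %HRR from 6 to 20. Cardiovascular drift is a
single sustained-load equivalence factor κ: holding M METs for many minutes
produces the internal load the incremental test showed at M/κ METs. When
the translation factor equals κ, the pipeline closes exactly (up to stage
resolution); when translation is skipped, sustained HR overshoots the
target at every intensity — the phenomenon the model corrects.

Cohort defaults emulate healthy young adults: hr_rest uniform 60–80 bpm,
hr_max uniform 180–194 bpm, capacity uniform 11.5–15.2 METs (a VO₂max span
of roughly 40–53 mL·kg⁻¹·min⁻¹), κ = 0.72, measurement noise additive
i.i.d. Gaussian (SD 5 bpm for HR, 0.5 for RPE), clipped to physiologic
bounds. All randomness descends from one seed via spawned child seeds, so
cohorts, tests and bouts are bit-reproducible. A maximal test ends at the
first stage demanding full capacity, and the HR recorded there *is*
`hr_max` — in this design the reserve is defined by the observed test-end
value, which also guarantees every %HRR target is locatable. Two editable
stage schedules ship with the package: a Balke type (1.34 m/s constant,
+2% per 2 min; the default) and a 1-min modified-Bruce-type ramp built by
linear interpolation of the classic 3-min anchors (a synthetic convention,
not an authoritative protocol definition).

### What the generator does and does not capture

It reproduces the statistical skeleton the model assumes — monotone HR
growth during the test, a stable steady state in minutes 15–25 of a bout,
drift as a single multiplicative factor. It does **not** model drift
kinetics (time constants, thermoregulation), VO₂ kinetics, day-to-day
biological variation, or the true curvilinear Borg–%HRR relation (the
affine RPE map puts ~14.4 at 60%HRR, higher than the ~12 typical of real
cohorts). The warm-up ramp is a linear placeholder. Passing closed-loop
tests therefore demonstrates internal consistency of the pipeline, not
field accuracy in humans.

### Parameter recovery

`recover_kappa` inverts each bout's achieved steady HR on the subject's own
GXT HR-vs-METs curve (piecewise-linear, first occurrence of each HR level)
and estimates κ as work METs / recovered METs. Noise-free recovery is exact
to 1e−6; at 5-bpm noise the mean estimate over 100 seeded 20-subject
cohorts stays within 0.02 of the true 0.72.

## Known limitations and open choices

- **Stage quantization bounds closed-loop accuracy.** The prescribed
  workload inherits the MET cost of the whole stage in which the THR was
  crossed, so even noise-free achieved HR exceeds the THR by up to one
  stage's HR increment (~4–9 bpm for the default schedules). With 5-bpm
  measurement noise on top, the simulated within-±10 bpm proportion
  averages ≈ 0.86 — the right magnitude, but individual 20-subject runs
  fall below 0.85 roughly half the time. Finer stage schedules reduce the
  quantization term; noisier first-crossing detection partially offsets the
  gain.
- The walking/running equation split inside the avoided band, the linear
  RPE interpolation, and the boundary-stage attribution are conventions
  chosen where standard practice is silent; each is localized behind one
  function and tested, so alternatives are easy to swap in.
- Submaximal tests (protocol ceiling below capacity) are flagged, not
  rejected; extrapolating `hr_max` from submaximal data is out of scope.
- Cycle/arm ergometry, stepping equations, measured spirometric VO₂ and
  ventilatory-threshold detection are out of scope.

## Problem sizes

Default experiment size is 20 subjects × 3 intensities, the scale at which
the agreement statistics are reported; statistical tests in the suite use
100 seeded replicates of that cohort. These sizes were chosen to match the
reported study design while keeping every simulation comfortably
reproducible on a laptop.
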