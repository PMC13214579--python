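# Methods

`damsleep` analyses *Drosophila* Activity Monitor (DAM) recordings —
per-fly infrared beam-crossing counts at 1-min resolution — for sleep
architecture, sleep pressure/depth, and circadian rhythmicity, and ships
a generative simulator whose virtual flies have exactly the statistical
structure the estimators assume. This note documents the models, the
conventions, the numerical choices, and what the synthetic tests do and
do not establish about real recordings.

## Data model and conventions

A recording is a contiguous sequence of half-open bins `[t, t + Δ)`.
Zeitgeber time (ZT) is hours since lights-on under the entraining
schedule; day phase is ZT ∈ [0, 12), night is [12, 24) for the standard
12 h:12 h light/dark (LD) cycle. After release into constant darkness
(DD) the light flag is 0 everywhere but ZT keeps advancing on the
entrained phase, so day/night attribution stays defined.

Light annotation always comes from the configured schedule, never from
the monitor's light-sensor column (kept as advisory metadata): the DD
phase needs a schedule-based clock regardless, and sensors glitch.

Rows with a bad status code are dropped and the hole is recorded as an
explicit gap. Analyses that assume a contiguous timeline (sleep scoring,
periodograms, day folding) refuse windows containing a gap rather than
imputing counts — silent imputation would bias bout lengths toward
longer sleep.

**Death censoring.** Flies are checked for a terminal run of
zero-activity bins; a run of ≥ 24 h (configurable `death_lookback_hours`)
marks the fly dead at the run start. The pipeline excludes dead flies
from every summary outright rather than truncating them, matching the
practice of omitting flies that die during monitoring. 24 h is the
coarsest resolution a daily visual check supports; a series ending in
activity is never truncated.

## Sleep metrics

Sleep is the standard fly definition: a maximal run of ≥ 5 consecutive
minutes with zero counts. Scoring requires 1-min bins — the definition
is meaningless at coarser binning, so coarser input is a hard error.

Per-phase metrics are averaged over complete LD days (partial first/last
days are dropped):

* **Episodes** are attributed to the phase in which the bout *starts*;
  bout **minutes** are split across phases at the ZT12/ZT24 boundaries.
  Episode counts stay integral and minutes are conserved; consequently
  `mean_bout × episodes = total minutes` holds exactly only when no
  bout straddles a boundary.
* **Latency** is minutes from each light transition to the onset of the
  first bout starting at-or-after it within the same half-day. A phase
  with no sleep contributes 720 min and a censored flag; dropping such
  phases would bias fragmented sleepers toward low latencies. The
  censored-excluded average is also emitted
  (`latency_uncensored_min`); the censored-included value is the
  default.
* **P(Doze)** = P(next minute inactive | this minute active) and
  **P(Wake)** = P(next minute active | this minute inactive) are pooled
  within phase: transition counts are summed across all analysed days
  before dividing, which is unbiased when days contribute unequal
  active-minute counts (a per-day average is available by passing
  single-day windows). Minute pairs straddling a phase boundary are
  excluded from both phases, so a lights-on startle cannot leak into
  night statistics. Zero denominators yield NaN with the flag semantics
  of "undefined", never 0.
* The **sleep time-course** marks a minute asleep iff it belongs to a
  scored bout — the first four minutes of any immobility run count as
  awake, a strict reading of the 5-min rule.
* **Eduction** (daily activity profile) folds each fly's complete LD
  days at 24 h on a 30-min ZT grid, averages within fly across days,
  then reports mean ± SEM across flies (SEM 0 for a single fly).

## Chi-square periodogram

For each candidate period `P` (in bins) the DD window is truncated to
`K = ⌊N_total/P⌋` complete cycles (`N = K·P`) and folded into `P`
columns with means `M_h` and grand mean `M̄`:

    Qp = K · N · Σ_h (M_h − M̄)² / Σ_i (X_i − M̄)²

Under the null Qp is asymptotically χ² with `P − 1` df. This
normalisation is chosen so a perfectly `P`-periodic series attains
`Qp = N` — the ceiling that anchors **robustness** `Qp/N ∈ [0, 1]`
(reported as a fraction). **Power** is the height of the peak Qp above
the per-period χ² significance line at `alpha`; the **period** is the
test period maximising that excess, reported only for rhythmic flies.
Zero-variance windows are flagged degenerate: arrhythmic, power and
robustness missing.

Defaults: 30-min analysis bins, test periods 16–32 h in one-bin (0.5 h)
steps, `alpha = 0.05`, DD window = the first 7 complete DD days after
skipping 24 h post-transition (masking transients decay within a day).

**The binary rhythmicity call.** The per-period χ² line controls the
type-I error of *one* period. The call, however, scans ~33 periods; on
flat-profile null flies the uncorrected max-over-grid call is positive
about 70% of the time (grid multiplicity compounded by the behavioral
autocorrelation of bout structure), which would make the rhythmic /
arrhythmic outcome uninformative. The default call therefore compares
the peak Qp against a Šidák family-wise threshold across the test-period
grid (per-period level `1 − (1−α)^{1/m}`). Measured on simulated flies
this gives a 3% false-call rate on flat profiles with a 100% detection
rate at realistic rhythm strength. The uncorrected per-period line is
retained for the periodogram display, the power definition, and null
calibration, and the classical uncorrected call is available via
`classify_rhythmicity(..., correct_multiplicity=False)`.

**Morning anticipation** is the percentage of the activity in the 6 h
before lights-on that falls in the final 3 h (counts summed over
analysed LD days; 50% = no anticipation, NaN when the window is empty).
It is computed per fly for group tests; a group-eduction-based variant
(`anticipation_from_eduction`) is also provided.

**Actograms** are day × bin rasters at 10-min bins; the double-plot
concatenates day *d* with day *d+1* per row (right half of the last row
zero-padded), with a parallel lights-on mask for shading.

## Group statistics

* **Fisher's exact test** (two-sided, point-probability rule) for
  rhythmic/arrhythmic contingency tables within each age stratum, via
  `scipy.stats.fisher_exact`; the tests keep an independent
  full-enumeration oracle.
* **Stratified 2×2**: Cochran–Mantel–Haenszel chi-square without
  continuity correction plus the Mantel–Haenszel common odds ratio
  (statsmodels `StratifiedTable`); degenerate strata are skipped with a
  warning.
* **Two-way ANOVA** (genotype × age) with Type II sums of squares —
  appropriate for unbalanced group sizes without missing cells — and
  Tukey HSD over the four cell means (statsmodels).
* **Repeated-measures ANOVA** with day/night phase as the within-fly
  factor is computed by the sum/difference decomposition, exact for a
  two-level within factor: between-fly effects are the factorial ANOVA
  on each fly's phase mean; within-fly effects the factorial ANOVA on
  each fly's day−night difference, with the phase main effect as the
  sum-coded intercept test. Two within levels mean sphericity holds
  trivially. Sums of squares are rescaled to the observation metric
  (×2 between, ×½ within); F and p are unaffected. Flies missing a
  phase are dropped with a warning.
* **Šidák adjustment** `1 − (1 − p)^m` for anticipation-score
  comparisons. Significance is starred at 0.05/0.01/0.001/0.0001.

## Synthetic flies

The generator is deliberately the *measurement model*: a fly is a
two-state (active/inactive) Markov chain at 1-min steps with transition
probabilities `p_doze(ZT)` and `p_wake(ZT)`, so the P(Doze)/P(Wake)
estimators perform exact parameter recovery rather than an
approximation. Profiles are cosine-modulated around a mesor on the
fly's *endogenous* clock, which tracks the entrained clock until DD
release and then free-runs at `tau`. Counts in active minutes are
`max(1, Poisson(λ(ZT)))` — the floor keeps the observed active/inactive
state identical to the latent state — with Gaussian morning/evening
activity peaks, an optional night-activity multiplier, a forced
startle burst at light transitions, and a per-day death hazard that
zeroes counts from a random minute of the death day. Arrhythmic flies
get flat profiles (mesor everywhere): an unambiguous ground truth for
the binary rhythmicity call, rather than noise injection.

Default parameters were chosen once as field-realistic: day/night
P(Doze) ≈ 0.15/0.30 and P(Wake) ≈ 0.15/0.06 give a stationary night
sleep fraction of ~0.83 and daily sleep totals in the usual several-
hundred-minute range; λ levels give tens of beam crosses per active
bout. The four-group scenario (`scenario_c9ftd_study`) encodes the
C9orf72-FTD study's effect directions: night activity ×1.8 and night
P(Wake) ×1.5–1.6 in the pathogenic genotype, P(Doze) mesor dropping
from 0.225 to 0.14 in aged pathogenic flies, and DD arrhythmic
fractions of 0.30/0.33 (pathogenic) versus 0.07 (control) — which,
under the family-wise rhythmicity call, reproduce observed rhythmic
percentages near the published 69/93% split. Per-fly random streams are
derived from `SeedSequence(master, spawn_key=(monitor, channel))`, so
reproducibility is independent of iteration order and monitor files are
byte-identical across reruns.

**What the simulator does not emulate:** multi-beam position, within-
minute burstiness, inter-fly correlation (shared incubator artefacts),
gradual senescence, masking beyond a fixed startle, and non-Markovian
bout-length distributions (real bout lengths are heavier-tailed).
Passing recovery tests therefore certifies the *estimators and
pipeline plumbing*, not the adequacy of the two-state model for any
particular real dataset.

## Problem sizes and determinism

The test suite and the acceptance script use: 10⁴ random sequences for
the bout-scoring oracle; 200 two-day simulations for P(Doze)/P(Wake)
recovery (≥ 95% within 3 binomial SE); 1000 white-noise replicates for
per-period periodogram calibration (20-day windows, band 0.05 ± 0.02);
50 seeds per τ ∈ {20, 24, 28} h for period recovery within one 0.5-h
bin; and a full simulate→analyze run with 32 flies per group, 5 LD + 8
DD days, for the end-to-end effect-direction checks. All randomness is
seeded; pipeline outputs are byte-stable under a fixed seed and
configuration.

## Known limitations

* Per-stratum Fisher tests on rhythmic proportions have only ~50–60%
  power at the study's own effect size and n ≈ 30/group; the stratified
  CMH test is the adequately powered consistency check and is what the
  end-to-end test asserts.
* The χ² periodogram's null is asymptotic; at few cycles (K ≤ 7) the
  per-period test is mildly conservative, and behavioral
  autocorrelation inflates Qp slightly. Calibration is therefore
  checked on 20-cycle windows.
* The "power of rhythm" definition (peak Qp minus the significance
  line) is one of several in circulation; published power/robustness
  group means are not comparable across implementations and are not
  treated as reference values.
* Latency averages include censored phases at 720 min by default;
  studies differ here, and both variants are emitted.
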