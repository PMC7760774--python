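# Methods

## The measurement model

The package treats the athlete as carrying four latent quantities:
critical speed CS (m/s), above-CS distance capacity D' (m), maximal
oxygen uptake VO2max (mL/kg/min) and the gas exchange threshold
GET (mL/kg/min). Two field/laboratory tests measure them:

**3-minute all-out test.** A 1-Hz GPS speed trace of a maximal 3-min
run. S150s is the arithmetic mean of the samples in [0, 150) s, CS the
mean over [150, 180) s (half-open windows; 30 samples for CS), and
D' = 150·(S150s − CS). Recordings may run a few seconds long; samples
past the 180-s mark are dropped, anchored at the start of the effort.
Irregular timestamps are linearly interpolated onto a 1-Hz grid and
gaps over 2 s are rejected. A negative D' is never silently accepted —
it flags a pacing-suspect effort.

**Graded exercise test.** Gas exchange at 1 Hz through rest (2 min),
walking warm-up (5 min), an individualized ramp (5 mph start, 3% grade,
per-minute speed increments chosen so the test lasts 8–12 min), active
recovery (10 min) and a square-wave verification bout at 105% of peak
ramp speed. Processing:

- 15-s consecutive bin averages; VO2max = the best adjacent-bin pair
  mean (ties to the earlier pair), timestamped at the later bin's end.
- GET by v-slope: a continuous two-segment least-squares fit of VCO2 on
  VO2 scanned over every admissible joint (≥ 3 points per segment,
  upper−lower slope ≥ 0.10); the GET is the VO2 at the joint. Two
  noise-control details: VCO2 is lightly smoothed (centered 3-bin mean,
  endpoints raw), and when binned VO2 is linear in time (R² ≥ 0.95, as
  in any steady ramp) the VO2 axis is replaced by that trend, removing
  errors-in-variables coupling between the axes. A fully free
  two-segment fit was tried first and rejected: under bin noise it
  chases edge splits and can intersect outside the data span.
- The metabolic response lags the belt by ~1 min, so the speed evoking
  a gas value is the protocol speed four 15-s samples earlier, with
  speed interpolated in quarter stages (increment/4 per sample);
  lookups before ramp onset clamp to the start speed with a flag. The
  time evoking the GET is located by inverting the linear-in-time VO2
  trend over the post-lag, pre-plateau bins (a linear-interpolation
  rule; the first-noisy-bin-crossing alternative is biased early).
- Treadmill-to-flat conversion equates the running metabolic demand
  `demand = 3.5 + 0.2·S + 0.9·S·G` (S in m/min, G fractional grade) at
  both inclines, giving `flat = S·(1 + 4.5·G)`; with the 3% ramp grade
  this is a 13.5% speed inflation. This documented equivalence is a
  stand-in convention — any alternative conversion can be substituted
  at the `flat_equivalent` boundary.
- 50%Δ is the exact mean of the flat-equivalent speeds at GET and at
  VO2max.

**Quality screens.** A 3MT is rejected for pacing when
|CS − 50%Δ| / 50%Δ ≥ 3.5% (the boundary fails; the denominator is the
GXT-derived reference, a choice this package fixes since the rule's
denominator is ambiguous). A GXT is rejected when ramp and verification
VO2max differ by more than 3% (inclusive acceptance). Dual violators
are counted once with reason "both". Retest loops are out of scope:
a failed screen excludes the visit.

**Prediction model.** Forward-stepwise OLS with CS forced first (it is
the hypothesis variable) and sex (F=0, M=1) entering at p < 0.05; with
two candidates, removal testing is a no-op. SEE uses the n−k−1
denominator. Standardized betas use sample SDs. The paired t between
observed and fitted values of the same fit is identically zero — the
package surfaces it because it is a standard reporting convention, not
evidence.

**Reliability statistics.** Typical error TE = SD(diffs)/√2; CV% by the
log method by default (100·(exp(TE_ln)−1)), linear (100·TE/grand mean)
selectable — published sources rarely state which convention produced a
printed CV, so neither is asserted against one; ICC(3,1) (two-way
mixed, consistency, single measure) from the ANOVA decomposition; 95%
CI for TE from the chi-square interval on the difference variance. The
SEE↔TE bridge `te = see·√((n−k−1)/(n−1))/√2` reconciles a regression
SEE with the within-pair TE scale; at SEE 3.34, n 25, k 2 it gives
2.26 mL/kg/min, with chi-square CI (1.77, 3.15).

## The synthetic cohort generator

The generator emulates the cohort structure the pipeline was built for:
~68% male, pooled CS 3.56 ± 0.55 m/s, D' ~ N(208.5, 54.3²) m truncated
above 50 m, VO2max generated from the linear model
`8.449·CS + 4.387·sex + 14.683 + N(0, 3.34²)`, GET at 65% of VO2max,
and a pooled CS–VO2max Pearson r of 0.819.

**Calibration, not assertion.** Only pooled CS moments and the pooled r
are public; sex-specific CS distributions are not. The generator
therefore solves for the male–female CS mean gap (equal within-sex SDs,
pooled mean/SD preserved by construction) whose simulated population
(n = 10⁵, fixed sub-seed, bisection) reproduces r = 0.819 ± 0.01. The
calibrated gap (~0.44 m/s) is a modelling choice, not a cohort fact.

**All-out profile.** Noiseless speed decays exponentially from a sprint
start to an exact CS plateau at 150 s:
`speed(t) = CS + A·(e^(−t/τ) − E)/(1 − E)`, E = e^(−150/τ), τ = 35 s by
default, with A solved so the above-CS distance over [0, 150] equals D'
exactly. Each 1-Hz sample is the profile's mean over its second — what
a GPS distance-per-second sample measures — so the noiseless round trip
through the extractor returns CS and D' exactly, giving a clean oracle.
Athletes whose D' would demand a sprint start above 12 m/s at the
default τ get a stretched decay (a flatter, more evenly spent effort);
combinations infeasible even for a linear decay (S0 = CS + D'/75) are
rejected. Additive white GPS noise, SD 0.05 m/s per sample, clipped at
zero; the 30-sample CS window makes results insensitive to it.

**Speed–VO2 economy.** Each athlete carries a linear flat-speed→VO2
line anchored at (speed@GET, GET) and (speed@VO2max, VO2max), with the
midpoint of those two speeds at CS·(1+ε), ε ~ N(0.008, 0.005²), and a
speed reserve of 30% of the midpoint. This is what makes 50%Δ agree
with CS for honest efforts (the +0.8% offset reproduces the ~3.59 vs
3.56 m/s cohort-level difference) — the pacing screen then passes
honest athletes and trips injected violators. The ramp renders VO2 as
the athlete-line demand of the belt speed one minute earlier (capped at
VO2max; the ramp ends one sample after the lagged demand reaches
VO2max, so demand at the peak belt speed slightly exceeds it), VCO2 as
a piecewise-linear function of VO2 with slopes 0.85/1.15 around the
GET, and the verification plateau at VO2max·(1+η), η ~ N(0, 0.008²).
Injected violators: paced 3MTs end 8% above the athlete's 50%Δ
(conserving 60% of D'); blown verifications plateau +5% high. Both
margins clear their thresholds by ~3 SD of extraction noise, so
injected violations are detected essentially always.

**Measurement noise.** Gas bins carry white noise of SD 0.25 mL/kg/min
per 15-s average (applied at 1 Hz with SD·√15). This default is the
level at which the full render-and-extract loop localizes the GET to
±1.5 mL/kg/min (95%) — the precision the 3.5%/3% decision rules
presuppose; at 0.5 the v-slope kink is only weakly identified (error SD
~1.7, near the information limit set by the 0.30 slope gap) and the
pacing screen would reject ~5% of honest athletes, and a deterministic
9+3 exclusion fixture could not exist. Conversely, 0.5 is the setting
that best matches the ramp-vs-verification consistency of real
cart data (TE ≈ 0.45 mL/kg/min); users studying screen behaviour under
realistic noise should raise `gas_noise_sd` accordingly.

**What the generator does not emulate.** Breath-by-breath kinetics
(on-transient time constants, the VO2 slow component), heart rate,
day-to-day biological variation, wind/temperature, GPS position error
structure (only white speed noise), and retesting behaviour. Passing
tests therefore demonstrate that the *processing chain* is correct and
that the *statistical structure* (coefficients, SEE, pooled r, QC
bookkeeping) is recovered — not that the screens would behave
identically on real breath-by-breath data.

## Numerical and design choices

- Window convention: half-open [0,150)/[150,180); the closed
  alternative shifts results by <0.1%.
- Seeding: every consumer draws from `SeedSequence([seed, tag, ...])`
  sub-streams; identical config+seed gives byte-identical outputs, and
  per-athlete renders are independent of cohort size or order.
- Truncations: CS > 1.0 m/s, D' > 50 m — generator policy preventing
  non-physical athletes.
- v-slope constants (min segment 3, slope gap 0.10) are configurable
  arguments; no single canonical threshold exists in practice.
- Degenerate inputs are errors with diagnostics, not silent results:
  zero between-subject variance (ICC), zero-variance differences
  (paired t), single-sex cohorts (sex step skipped with a note),
  rank-deficient designs, infeasible CS/D'/τ, ramps exceeding 26 min.
- Problem sizes: recovery experiments use n = 50,000 (coefficients,
  SEE) and n = 10,000 (correlation); at those sizes Monte-Carlo error
  is an order of magnitude below the acceptance bands (coefficient SE
  ≈ 0.027 at n = 50,000).

## Known limitations

- The calibrated sex gap and the speed-reserve fraction are modelling
  choices; real cohorts may pair the same pooled moments with different
  sex-specific structure.
- The metabolic-demand conversion is a documented equivalence, not the
  (unpublished) regression conversion some laboratories use.
- GET detection accuracy degrades quickly with bin noise (information
  limit, not implementation); at realistic cart noise the pacing screen
  has a measurable honest-athlete failure rate, which mirrors field
  experience with 3MT screening.
- The stepwise procedure is exactly forward entry over two candidates;
  with larger candidate sets entry/removal order would matter and is
  not implemented.
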