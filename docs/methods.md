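# Methods

This note documents the models, numerical choices and synthetic-data design
behind the package, and what the passing test suite does and does not
establish about real athlete data.

## Monitoring model

### Weekly biomechanical profile

One athlete-week is summarized by 17 variables in a fixed, versioned column
order: 7 on-court (total impact load, step count, average intensity, and
signed asymmetry for the low/moderate/high intensity bins plus all bins
pooled) and 10 CMJ (jump height, countermovement depth, time to takeoff,
peak relative braking and propulsive power, RSImod, and signed asymmetry of
peak braking force, peak propulsive force, average braking RFD, peak landing
force). Metrics are computed per trial (CMJ) or per session (on-court) and
averaged per week *after* reduction; weekly averaging is therefore
unweighted over sessions, so a 2-session week and a 3-session week are
comparable. RSImod is averaged as the mean of per-trial JH/TTT ratios, not
recomputed from averaged numerator and denominator — each trial's ratio is
the physiologically meaningful quantity, and the ratio-of-means differs from
it whenever trials vary.

The analysis matrix retains only athlete-weeks with all 17 variables
present (complete-case filter). Questionnaire responses never gate this
filter; they are carried alongside with their own missingness.

### CMJ feature extraction

All quantities derive from the summed vertical GRF and standard force-plate
conventions:

* **Onset**: first sample where |F − mg| exceeds 5·SD of the quiet-standing
  window (first 0.4 s) sustained for ≥ 50 ms. A 0.01 N floor on the
  threshold keeps the rule defined for noise-free synthetic traces whose
  quiet-window SD is exactly zero.
* **Velocity/displacement**: trapezoidal integration of F/m − g from onset
  (g = 9.81 m/s²). No filtering is applied to synthetic traces; a low-pass
  hook is the natural insertion point for real, noisy data.
* **Braking phase**: from the minimum (most negative) velocity sample to the
  first zero crossing of velocity; **propulsion** from there to takeoff.
* **Takeoff/touchdown**: 30 N flight threshold.
* **Jump height**: v²/2g with takeoff velocity from impulse integration; a
  flight-time estimate g·t²/8 serves as an independent cross-check (the two
  agree within ~0.3% on noise-free traces; the suite enforces 3%).
* **Asymmetry index**: 100·(right − left)/((right + left)/2), negative =
  left-dominant, bounded in [−200, 200]. A max-referenced variant is
  available via `asymmetry_method="max"`. Average braking RFD per limb uses
  the endpoint forces of the braking phase divided by its duration.

On a 1000 Hz grid the braking-end sample can carry a residual velocity of up
to a(t*)·Δt (≈ 0.005–0.01 m/s for realistic jumps); tests assert the sign
change across the boundary and a 0.02 m/s bound rather than an unattainable
sub-millimetre-per-second residual.

### PCA

Ordinary PCA by SVD of the column-standardized training matrix
(population-SD standardization, so training columns have SD exactly 1).
Components are retained until cumulative explained variance ≥ 90% (scree
elbow and eigenvalue > 0.7 counts are reported as diagnostics only). Since
SVD signs are arbitrary, each component is flipped so its largest-|loading|
coefficient is positive, making fits reproducible. Projection always uses
the frozen training mean/SD/loadings; the default training split is the
first season with a pooled option (`pca_train_split="pooled"`), since a
monitoring deployment trains on history and scores the current season.
Constant columns are rejected by name rather than silently standardized to
NaN.

### Reliability and red-flagging

From a subjects × weeks baseline matrix (default: the first five preseason
weeks of the applied season, complete cases only):

* **ICC(2,1)** — two-way random effects, absolute agreement, single measure,
  from the ANOVA mean squares:
  (MS_subj − MS_err) / (MS_subj + (k−1)·MS_err + k·(MS_week − MS_err)/n).
  Negative estimates are clipped to 0 with a warning; a zero-variance matrix
  has no defined ICC. This is the standard form for test–retest weeks where
  "week" is a random facet.
* **SEM** = SD_baseline·√(1 − ICC) with SD_baseline the pooled SD of all
  baseline values (default), or √MS_err (`sem_method="ms_err"`); both are
  estimators of the within-subject error SD and agree closely in simulation.
* **MDC95** = 1.96·√2·SEM — the 95% bound for the difference between *two
  single measurements*.

The MDC is a cohort-level quantity; the flag bounds are subject-specific:
baseline mean ± MDC95 per athlete. A week is red when |value − baseline
mean| > MDC95, yellow when within 20% below the threshold (the margin is
configurable; "nearing the threshold" is inherently a judgment call), green
otherwise. Two calibration facts follow from the construction and are
enforced in the suite: (i) against a *single-measurement* reference the
stationary red rate is the nominal 5%; (ii) against the 5-week baseline
*mean* the reference noise shrinks by √(1.2/2), making the operational
false-red rate ≈ 1% — the scheme is deliberately conservative — while a
sustained shift of 2·MDC95 is still flagged in ≥ 95% of weeks (100% in the
noise-free limit). Baselines whose mean pain exceeds a configurable level
(default 4/10) trigger a warning that the athlete's "normative" window may
be confounded; no automatic remedy is applied.

### Repeated-measures correlation

r_rm is computed from within-subject-centred series: with Sxx, Syy, Sxy the
centred sums, the common slope is Sxy/Sxx, SS_measure = Sxy²/Sxx,
SS_error = Syy − SS_measure, r_rm = sign(Sxy)·√(SS_measure/(SS_measure +
SS_error)), df = n_obs − n_subjects − 1, p from F(1, df). The 95% CI uses
the Fisher z-transform with the effective sample size implied by df
(SE = 1/√(df − 1)). Missing weeks are handled pairwise per metric pair;
subjects with fewer than two complete pairs are dropped with a warning. The
screen reports Benjamini–Hochberg adjusted p-values alongside unadjusted
ones but never filters on them. Associations are in-phase only; a `lag`
parameter exists (default 0) for sensitivity checks, not for formal
cross-correlation analysis.

The implementation is validated against an explicit dummy-coded
least-squares oracle (equality to 1e-10) and against `pingouin.rm_corr`.

## Synthetic cohort generator

The generator emulates the study conditions end to end: 16 athletes by
default, two 28-week seasons partitioned offseason (4 w) → preseason (8 w) →
regular season (16 w), one 3-jump CMJ session + 2–3 on-court sessions + one
questionnaire per week. Marginal targets follow the cohort descriptives
(body mass 73 ± 11 kg; jump height 0.24 ± 0.05 m; depth −0.28 ± 0.04 m;
time to takeoff 0.84 ± 0.11 s; ~6,000 steps and ~72,000 g load per session
at ~12 g mean intensity; signed asymmetry SDs chosen so the cohort mean
|asymmetry| per channel matches the reported magnitudes under a half-normal
model). Questionnaire compliance is independent Bernoulli per scale per week
with athlete-level rates centred on the reported season-one compliance
(pain 49%, sleep 55%, academic workload 67%, feeling 80%); biomechanical
collection is Bernoulli per source per week at 0.66 each, reproducing the
~44% joint complete-case yield.

### Trace template

The centre-of-mass acceleration is a sequence of half-cosine pulses: quiet
standing → negative unweighting pulse (35% of movement time) → positive
braking pulse (30%) cancelling 90% of the downward velocity → positive
propulsion pulse (35%) → free flight → landing pulse → quiet standing. The
unweighting amplitude is solved (Brent's method on the analytic
double-integral) so the displacement minimum equals the planted depth; the
other amplitudes follow in closed form from the velocity constraints. Two
consequences are intentional: the force profile is bimodal (as real CMJ
traces often are), and the zero-velocity crossing lands on the early rise of
the propulsion pulse, where force is well below the propulsive peak — this
keeps the braking-phase and propulsive-phase asymmetry channels from
interacting. Movement spans one extra sample so the detection conventions
(onset = first deviating sample, takeoff = first airborne sample) recover
the planted time to takeoff within half a sample period. A feasibility floor
ttt ≥ √(|depth|/0.42) rejects depth/speed combinations that would need the
plates to pull downward (unweighting acceleration > g).

The left/right split applies a share 0.5 ± h(t)/2 to the total force:
constant h in the propulsion and landing windows (planting those channels
exactly at the per-limb force peaks), and *linear in time* across the
braking phase, with endpoints solved from a 2×2 linear system so that both
the peak braking force asymmetry and the endpoint-based RFD asymmetry equal
their planted values. A constant share cannot plant those two channels
independently — the RFD index is then algebraically identical to the force
index — which is why the braking share varies within the phase.

### Impact streams

Magnitudes are sampled exactly (inverse CDF) from a lognormal with median
≈ 8.2 g and log-SD 0.85, truncated to [1, 200] g; this right-skew populates
the three intensity bins in realistic proportion and reproduces the ~12 g
mean intensity. Feet alternate with a 0.9 switch probability. Planted
per-bin asymmetry is realized by scaling each event by 1 ± h_bin/2 according
to its foot, *clipped to the event's original bin* so the plant is not
distorted by events migrating across bin boundaries (unclipped scaling
biases the recovered high-bin index by several points; the residual clipping
bias is under one point). The per-session asymmetry index is noisy — the
binomial foot split within a bin and the heavy-tailed magnitudes give a
per-session SD of several points at 6,000 steps — so recovery tests average
over many sessions and the symmetric-generation test uses ~10⁶ steps.

### Perturbations and baseline integrity

Planted perturbation episodes (default: two athletes, 4 weeks, −12-point
high-bin shift, +8-point CMJ braking shift, +4 pain, ×0.75 load) begin only
in the regular season of the final season, leaving the designated 5-week
preseason baseline window unperturbed. During that window biomechanical
collection is forced complete — a deliberate idealization of a team
scheduling its baseline testing — since MDC bounds require complete
baselines. Questionnaire compliance is *not* forced, so psychological-metric
baselines are often unavailable for some athletes, as in practice.

### What the generator does not emulate

Raw accelerometer waveforms (events are emitted pre-detected, as the
manufacturer software does), trace noise and filtering artifacts (noise is
available but defaults to zero), game-versus-practice differences, seasonal
trends and detraining, menstrual-cycle effects, and correlated missingness
(compliance is independent across scales and weeks). Passing round-trip
tests therefore validate the *extractors and statistics*, not the
hardware-specific pre-processing a real deployment would need.

## Problem sizes and determinism

Defaults were chosen so a full two-season, 16-athlete synthetic pipeline
(~1,800 traces, ~10⁷ impact events) completes in well under a minute on one
CPU; the simulation-based calibration checks use 200–500 replicates, which
puts Monte-Carlo error comfortably inside the asserted tolerances. All
randomness flows from numpy `SeedSequence` spawning, so identical seeds give
byte-identical outputs; output files embed the config hash (excluding output
paths) and seed. The serialized PCA model is versioned YAML; all interchange
formats are commented CSV.

## Known limitations

* ICC(2,1) is mildly biased downward at n = 16 subjects (mean ≈ 0.885 for a
  planted 0.90 variance ratio); the suite's ±0.03 tolerance covers this.
* The rmcorr CI is the Fisher-z approximation, adequate at the df (> 100)
  this design produces but crude for very small cohorts.
* Flagging against a baseline *mean* is conservative relative to the nominal
  5% MDC error rate by construction (see above); users wanting nominal
  calibration should treat MDC95 as a bound on week-to-week *changes*.
* The asymmetry-index denominators make indices unstable when per-limb
  values approach zero (e.g. RFD in very shallow jumps); the generator's
  template keeps braking-end forces well above body weight to stay in the
  stable regime.
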