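# Methods

## The paradigm

The rotating-cylinder stimulus presents dots translating horizontally with
sinusoidal speed profiles inside a rectangular aperture. Projected this
way, two counter-moving dot sheets are perceived as the front and back of
a transparent cylinder rotating in depth. With no depth cue the front/back
assignment — hence the rotation direction — is ambiguous, and perception
alternates spontaneously (the *bi-stable* task). Adding an occlusion cue
that places one sheet in front disambiguates the stimulus; physically
swapping which sheet occludes produces unambiguous direction reversals
(the *real-switch* task), used to screen out observers who cannot report
rotation direction reliably.

Each experimental session is one real-switch block followed by five
bi-stable blocks, every block 120 s. Participants report the front
surface's rotation direction with left/right keys, starting with an
immediate report of the initial percept.

## Stimulus model

Dot positions are the orthographic projection of uniform circular motion:
`x(t) = R·sin(ωt + φ₀)` with `R = width/2 = 3.5°` and `ω` the rotation
speed (90°/s, i.e. π/2 rad/s; period 4 s). This is the standard SFM
cylinder construction and realizes the defining speed profile — maximal at
the aperture midline, zero at the edges. The two sheets are phase-offset by
π; vertical positions are uniform over the 10° height and fixed per dot
within a session. Frame rate defaults to 60 Hz. Nothing is rendered;
trajectories are exported as tidy coordinate tables.

The real-switch schedule places 11 reversals at intervals drawn from
{9, 11, 13} s. Eleven intervals at the mean (11 s) would exceed the 120 s
block, so random schedules are rejection-sampled under the feasibility
constraint; a fixed canonical schedule (intervals
9,11,13,9,11,13,9,11,9,9,9; last switch at 113 s) stands in for the single
timing shared by all observers. The first interval is drawn from the same
set as the rest; directions alternate from an initial leftward rotation.

`recover_rotation_speed` inverts the projection: folded phase
`arcsin(x/R)` is unwrapped by tracking fold points (sign changes of its
derivative) and regressed against time. For noiseless sinusoidal samples
this recovers ω to machine precision, so the 1% check on the generated
stimulus is a genuine end-to-end consistency test of the generator, not a
tolerance absorbing an approximation.

## Synthetic observers

No raw participant data are distributed, so a generative observer stands
in for them. Its purpose is to reproduce the statistical structure the
analysis pipeline assumes, not the neural dynamics of rivalry:

* **Dominance durations** follow a gamma renewal process — the standard
  phenomenological description of bi-stable alternation. Default shape 3.5
  gives a duration CV of 1/√3.5 ≈ 0.53, typical of psychophysical reports.
  The first report occurs after a gamma-distributed latency (mean 1.5 s,
  shape 4); subsequent reports alternate direction at renewal epochs until
  the block ends.
* **Real-switch responses**: each physical reversal is answered with
  probability 1 − miss at a lognormal reaction time (median 0.9 s,
  σ = 0.35 log-units), reporting the wrong direction with probability
  0.02; spontaneous reversal reports arrive as a 0.01 Hz Poisson stream.
  Per-group miss probabilities (0.18 / 0.21 / 0.25 for controls /
  relatives / PwPP) were chosen so that the 7-of-11 inclusion rule passes
  roughly 83% / 81% / 71% of sessions, the pattern reported for the three
  groups in this paradigm.
* **Cohort structure** lives on the log₁₀ switch-rate scale, the scale on
  which the analysis operates. Controls center at −0.82 (0.15 Hz) with
  within-group SD 0.35; PwPP sit `d`·SD higher (default d = 0.58, a medium
  effect) and relatives halfway. The published record for this paradigm
  gives only box plots for these quantities, so the location and spread
  are field-typical choices, labeled approximate and fully configurable.
  The within-group SD splits into a stable subject trait and session
  noise with trait share r = ICC/(2 − ICC), so that the average-measures
  consistency ICC over two sessions, ICC(3,k=2) = 2r/(1+r), hits the 0.88
  target. A small per-block drift (−0.02 log₁₀ units per block) emulates
  the practice effect visible as a block-order main effect.
* **Covariates** (BPRS, SPQ, BACS, SGI, BPRS-D, SPQ-CP; GABA, glutamate,
  glutamine) are Gaussian-copula coupled to the subject's latent trait.
  The Spearman targets refer to correlations with *measured* rates, which
  session noise attenuates; the latent Pearson coupling is therefore
  2·sin(πρ/6) (the Spearman-to-Pearson map for bivariate normals)
  inflated by the analytic attenuation factor
  √(Var(group+trait)/Var(group+trait+session noise)). Finite-block
  measurement noise (~0.001 variance on the log₁₀ scale against ~0.13
  total) is ignored; Monte Carlo recovery at n = 200/group confirms the
  targets within ±0.01. Marginals are single global mean/SD transforms of
  the latent per scale — plausible numbers, not per-group clinical
  distributions — because group-dependent marginals would distort the
  pooled rank-correlation targets. Consequently the synthetic covariates
  carry group information only through their coupling to switch rate;
  analyses that depend on group-specific symptom distributions (e.g.
  between-group covariate contrasts) are outside what the generator
  emulates.

Determinism: one master seed; every subject × session × block stream and
each latent table derives its generator from a seed-sequence spawn key, so
any subset regenerates identically regardless of generation order.

A vectorized count-level path (`generate_cohort_rates`) samples per-block
switch counts directly from the same renewal law (epochs within the block
after the latency) without materializing events; its distribution is
unit-tested against the event-level simulator. Monte Carlo suites (2000
null cohorts for Type-I calibration, 100 replicates for parameter
recovery) use this path; everything else exercises the event-level
pipeline.

### What passing tests do and do not show

The generator reproduces renewal-style alternation, scheduled responses
with misses/errors, stable traits across sessions, and monotone
covariate–rate coupling. It does **not** reproduce serial dependence
between successive percept durations, reaction-time drift, blinks or
response lapses mid-block, non-gamma duration tails, or medication
effects (the benzodiazepine flag is a label only). Green tests therefore
validate the *pipeline's* correctness and calibration, not any claim
about real observers.

## Scoring conventions

* Only direction **changes** count as switches; the initial report is not
  a switch and same-direction repeats are ignored everywhere.
* The final dominance interval is truncated by the block end; it is kept
  (flagged censored) so that pre-response time + completed durations +
  censored tail = 120 s exactly, but excluded from duration statistics
  because its length is truncation-biased.
* Zero-switch blocks: the rate is stored as 0 Hz; only the log₁₀ transform
  substitutes 0.5 switches/120 s, per block, before any averaging. The
  subject-level rate is the mean of per-block log₁₀ rates (log-then-mean),
  keeping the replacement rule per-block as stated.
* Real-switch matching is greedy in time order: each physical switch is
  credited by the earliest unconsumed response with the correct post-switch
  direction and latency in [0, 4) s. Responses are consumed once; since
  eligibility windows are intervals ordered along the timeline, greedy
  matching attains the exhaustive-matching optimum (verified against an
  augmenting-path oracle on random instances). Anticipatory responses are
  never credited. Both the mean RT of credited responses and the mean
  latency of first matching reports regardless of window are emitted, so
  either reaction-time summary convention can be reported.
* Inclusion: credited responses ≥ 7 of 11 (accuracy ≥ 63.6%). The
  threshold is expressed in credited counts, which resolves the printed
  63.4%/63.6% rounding discrepancy in the source material in favor of the
  methods definition.

## Statistics

Omnibus group differences use tie-corrected Kruskal–Wallis on per-subject
mean log₁₀ rates (session 1, included subjects only — repeat sessions
violate independence; per-subject means rather than per-block values for
the same reason). Post-hoc pairwise tests are two-group Kruskal–Wallis
statistics (chi-square, 1 df), Bonferroni-corrected over the 3 pairs.
Duration distributions are compared by two-sample KS tests on durations
pooled across included participants within group (asymptotic p by default;
an exact option exists); the report carries both the pooled-n and the
subject counts, since printed D statistics in this literature subscript
subject counts while the effective n is the pooled responses.
Reliability is ICC(3,k): two-way mixed, consistency, average measures,
(BMS − EMS)/BMS, computed via pingouin and cross-checked against the
ANOVA decomposition; the battery reports it on both Hz and log₁₀ scales.
Cohen's d uses the pooled-SD formula on log₁₀ rates (a raw-Hz flag is a
one-liner away via the metrics table). The block-order effect is a
one-way repeated-measures ANOVA (statsmodels AnovaRM), no sphericity
correction by default. Clinical correlations are tie-aware Spearman with
Bonferroni m = 6 (the scale family); metabolite correlations use m = 3
within the pooled family and within each group's family. Constant inputs
flag the correlation as undefined instead of raising.

## Numerical and degenerate-input choices

* Time is seconds from block onset (floats); directions are the strings
  `left`/`right` referring to the front surface, avoiding sign-convention
  bugs.
* A block with no responses is legal: no intervals, 0 switches, log₁₀ rate
  from the replacement rule.
* ICC and the RM-ANOVA drop incomplete rows and record the count; the
  contingency test refuses zero marginals; KS refuses empty samples;
  Kruskal–Wallis refuses groups with n < 2.
* Histogram durations outside the bin range are clipped into the end bins
  so per-group proportions always sum to 1.
* Monte Carlo problem sizes: 2000 replicates at the study's group sizes
  (40/43/65) for Type-I calibration, 100 replicates at 200/group for
  calibration recovery, 1000–1500 blocks for renewal consistency — sizes
  at which binomial/SEM tolerances are decisive for the properties under
  test.

## Known limitations

* The generator's calibration constants for rate location/spread are
  approximate by necessity (see above); published omnibus statistics that
  depend on the actual raw data (specific X² and F values) are not
  reproduction targets.
* KS p values at pooled-duration sample sizes are effectively zero under
  any group difference; interpret D, not p, when comparing to published
  values.
* The repeated-measures ANOVA models block only; the group × block
  interaction can be added by extending the long-format frame but is not
  part of the default battery.
* MRS quantification, rendering/display timing, and clinical instrument
  administration are out of scope: metabolites and symptom scores enter
  only as numeric covariate tables.
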