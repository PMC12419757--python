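# Methods

## The engagement model

engagekit operationalises user engagement with a session-structured mHealth
app as two complementary quantities per participant over a fixed observation
window (default 28 days):

1. an **engagement index**, the arithmetic mean of five subindices each
   normalised to 0–100: click depth, loyalty, recency, feedback and
   interaction (an adaptation of the web-analytics visitor-engagement index;
   the original framework's "brand" and "duration" subindices are
   deliberately not implemented);
2. **engagement time**, the cumulative in-window session duration in
   minutes.

The index is designed to *rank* participants within a cohort, not to be
compared across apps: the interaction subindex is normalised by cohort
maxima, so its scale depends on who else is in the cohort.

### Conventions and degenerate inputs

- The observation window is half-open, `[enrollment, enrollment + W)`.
  Sessions must start inside it; durations running past the boundary are
  truncated there. Post-window usage is excluded from all metrics.
- Calendar days are counted from each participant's enrollment date;
  a session spanning midnight belongs to its start day.
- Overlapping sessions of one participant are merged before summing
  engagement time, so concurrent records cannot double-count wall-clock
  time.
- Recency uses gaps between *distinct calendar visit days* (not raw
  inter-session deltas — multiple same-day sessions do not inflate
  recency), and is capped at 100. A participant with a single visit day has
  no gap; the implemented fallback scores them `100 / W`, extending the
  reciprocal-gap idea to the least-recent possible pattern. Both the
  distinct-day convention and the fallback are package decisions where the
  framework is silent; the day-count anchor is exposed as a parameter.
- "Questions" in the interaction subindex pools public and private
  questions into one count (the reward tariff still distinguishes them:
  100 points per record/rating/comment, 1000 per private question, 2000 per
  public question); an unpooled variant is available via
  ``pool_questions=False``.
- The click-depth threshold (default 4 page views) is a parameter: the app's
  shortest meaningful task flow (home → input → date selection →
  completion) renders four pages.
- An interaction category whose cohort maximum is 0 contributes a ratio of
  0 for everyone rather than 0/0.
- Participants without a post-intervention survey or without any session
  are excluded from index scoring and flagged in the validation report; no
  imputation is performed.
- Quartiles use linear interpolation, under which the monotone-transport
  identity holds for odd cohorts: the median loyalty equals loyalty
  evaluated at the median session count.

### Statistics

Group comparisons use the Mann-Whitney U test (two categories) and the
tie-corrected Kruskal-Wallis H test (three or more); associations use
Spearman's ρ with mid-ranks. All tests are two-sided. The Mann-Whitney z is
the normal approximation with tie-corrected variance and a continuity
correction; the primary U reported is the first group's pair-count statistic
(#pairs a>b + ½ ties), with the min-U convention of mainstream packages
(which makes their printed z always ≤ 0) available as ``u_min``.
Normality diagnostics combine a one-sample Kolmogorov-Smirnov test against a
normal with the sample's mean/SD and bias-corrected sample skewness; a
variable is flagged normal only if the KS test is non-significant *and*
|skewness| ≤ 1. No multiple-testing adjustment is applied by default — the
characteristic-wise comparisons are reported as a family of unadjusted
tests, noted in the result metadata — but Holm or Benjamini-Hochberg
adjustment can be switched on for reuse.

## The synthetic cohort generator

No usage logs of this kind are publicly deposited, so the generator is a
first-class, tested component that emulates the *structure* the analysis
assumes rather than any particular dataset.

Reference calibration (``default_config()``): 261 participants, 28-day
window, characteristic marginals equal to the published cohort composition
(e.g. self-help participation 32.2%, 90.8% in the medication-sustaining care
stage), enrollment staggered uniformly over 120 days so the calendar
active-user curve is nontrivial.

Mechanism, per participant (one RNG stream per participant derived from
``(seed, index)``, so enlarging a cohort never perturbs existing
participants):

| quantity | distribution | default | rationale |
|---|---|---|---|
| daily-login probability | Beta(mean·κ, (1−mean)·κ), fixed over the window | mean 0.55, κ = 3 | latent propensity held fixed produces the wide, overdispersed session-count spread (median ≈ 28, IQR roughly 17–40) |
| self-help effect | additive shift of the Beta mean | +0.08 | reproduces a few-point median index advantage for self-help participants; set to 0 for null simulations |
| sessions per login day | 1 + Poisson(λ) | λ = 0.8 | every login day has ≥ 1 session |
| page views per session | 1 + NegBin(r, mean m) | m = 10, r = 1.5 | ≈ 83% of sessions reach 4 page views, matching a high click-depth cohort |
| session duration (min) | lognormal(σ) × per-participant lognormal multiplier (σ_p) | median 0.6, σ = 1.0, σ_p = 0.9 | the participant-level multiplier creates the "super-user" heavy right tail of cumulative engagement time (sample skewness ≫ 1) |
| interaction counts | NegBin(r₀) with mean ∝ rate × propensity | r₀ = 0.4; e.g. comments 1, ratings 2, public questions 0.3 over the window | strong overdispersion lets a few prolific users dominate the cohort maxima, pushing the median interaction subindex near zero |
| survey total | 20 + 80·Beta(4.5, 1.5), rounded, decomposed exactly into twenty 1–5 items | — | left-skewed totals with median ≈ 83, inside the 20–100 instrument range |
| survey dropout | Bernoulli | 0 | set > 0 to emulate post-survey non-completers |

These distribution families are stand-ins: the kind of system that produces
such logs does not publish its session-count or duration laws, so families
were chosen for shape (bounded overdispersed counts; heavy-tailed positive
durations) and calibrated once to the reference cohort's printed summary
scale. Consequently the generator reproduces *qualitative* features — the
left-skewed index, the strongly right-skewed time, a near-zero-median
interaction subindex, wide between-participant spread — and is **not**
expected to match any real cohort's exact medians. Passing tests demonstrate
correctness of the metrics and honest operating characteristics of the
tests under this structure; they do not validate the generator against real
behaviour (no churn dynamics, push-notification effects, weekday/weekend
cycles, or multi-device usage are modelled).

## Operating characteristics and problem sizes

The simulation suite checks, at cohort size 261 (84 vs 177 in the self-help
split, the reference composition):

- **type-I error**: with the effect set to 0, the engagement-index
  comparison by self-help rejects at ≈ the nominal α = 0.05 (200 null
  replicates, binomial 95% band);
- **power monotonicity**: over the effect grid (0.02, 0.06, 0.12) on the
  login-propensity mean, power increases strictly (≈ 0.08 / 0.31 / 0.91 at
  200 replicates each);
- **shape**: a 500-participant default cohort shows engagement-time
  skewness > 1 and engagement-index skewness < 0 (sign-level check).

Replicate counts and cohort sizes were chosen as the smallest giving stable
binomial error bands for these checks.

## Known limitations

- The recency single-visit fallback and the distinct-day gap convention are
  choices, not framework prescriptions; both are parameters.
- Interaction maxima are computed over the analyzable set (surveyed, ≥ 1
  session); scoring a new cohort against a fitted scorer raises if a count
  exceeds the fitted maximum rather than extrapolating.
- The whole window is treated as a single period for recency; no
  per-period decomposition is implemented.
- Exact-permutation p-values are not provided; the normal/χ² approximations
  are used as in mainstream statistical packages.
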