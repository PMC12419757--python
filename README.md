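# engagekit

Engagement analytics for mobile-health (mHealth) app usage logs.

When a health app is trialled — here, a self-care app for people living with
HIV used over a 28-day window — "did people engage?" has no single answer:
login counts miss depth, time-on-app misses experience. engagekit implements
a composite **engagement index** that averages five normalised subindices,
each capturing a different facet of engagement, alongside cumulative
**engagement time** as a complementary metric, and provides the rank-based
statistics used to compare engagement across participant subgroups.

For participant *i* with sessions *S_i*:

- **click depth** `CD_i = 100 · #{s ∈ S_i : pages(s) ≥ 4} / |S_i|` — share of
  sessions with meaningful exploration (≥ 4 page views);
- **loyalty** `L_i = 100 · (1 − 1/|S_i|)` — 0 for one-time visitors,
  approaching 100 for frequent ones;
- **recency** `R_i = 100 · min(1, 1 / mean gap)` where *gap* is the number of
  days between consecutive distinct visit days;
- **feedback** `F_i` — the post-intervention 20-item usability survey total
  (Health-ITUES, range 20–100) read as a percent of its 100-point maximum;
- **interaction** `I_i = 100 · ⅓ (c_i/max c + q_i/max q + r_i/max r)` —
  comments, questions and ratings normalised by their cohort maxima.

The composite is `EI_i = (CD_i + L_i + R_i + F_i + I_i) / 5 ∈ [0, 100]`.
Engagement time is the cumulative session duration in minutes inside the
window. Group comparisons use Mann-Whitney U (two groups) and Kruskal-Wallis
H (three or more); associations use Spearman's ρ — engagement outcomes are
strongly skewed, so rank methods are used throughout.

Because real usage logs of this kind are rarely shareable, the package ships
a seeded synthetic cohort generator that emulates the study-like structure
(28-day windows, overdispersed session counts, heavy-right-tailed durations,
left-skewed survey totals, an injectable self-help engagement effect), so
the whole pipeline is testable end to end without any data download.

## Worked example

```python
from engagekit import (default_config, generate_cohort, score_cohort,
                       compare_by_characteristics, spearman)
from engagekit.stats import median_iqr

cohort = generate_cohort(default_config(), seed=1)   # 261 participants, 28 days
summaries = score_cohort(cohort)                     # one row per analyzable participant

mi = median_iqr(summaries["engagement_index"])
mt = median_iqr(summaries["engagement_time_min"])
print(f"engagement index: median {mi.median:.1f}% (IQR {mi.q1:.1f}-{mi.q3:.1f})")
print(f"engagement time:  median {mt.median:.1f} min (IQR {mt.q1:.1f}-{mt.q3:.1f})")
corr = spearman(summaries["engagement_index"], summaries["engagement_time_min"])
print(f"Spearman rho = {corr.rho:.3f} (p = {corr.p_value:.2e}, n = {corr.n})")
```

prints

```
engagement index: median 65.5% (IQR 60.2-70.4)
engagement time:  median 23.4 min (IQR 12.2-52.6)
Spearman rho = 0.421 (p = 1.43e-12, n = 260)
```

One simulated participant had no sessions, so 260 of 261 are analyzable. The
index distribution is left-skewed (most participants engage substantially; a
tail of low engagers pulls the mean down) while engagement time is strongly
right-skewed (a few "super users" accumulate hours). The positive rank
correlation says the two metrics agree while capturing different things.
Group comparisons follow the same API:

```python
res = [r for r in compare_by_characteristics(summaries, cohort.profiles)
       if r.characteristic == "self_help" and r.metric == "engagement_index"][0]
print(f"U = {res.u:.1f}, z = {res.statistic:.2f}, p = {res.p_value:.4f}")
# U = 9471.0, z = 3.57, p = 0.0004  (the default config injects a self-help effect)
```

The scorer is a scikit-learn estimator (`EngagementIndexScorer`): `fit`
learns the cohort interaction maxima over the analyzable set, `transform`
emits the per-participant summary table, and `get_params`/`set_params`/
`clone` work as usual.

## Command line

```bash
engagekit all --seed 5 --out-dir run/
```

runs simulate → validate → score → analyze → report, writing the
per-participant summary CSV, the daily-active-user curve, distribution
diagnostics, the engagement-index/time correlation, and a per-characteristic
comparison table (CSV + Markdown, IQR shown as bounds or width via
`--report-style`). Each stage is also its own subcommand
(`simulate`, `score`, `analyze`, `report`) over CSV/JSONL artifacts.
Outputs are byte-identical across repeated runs with the same seed.

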