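# Methods

This note records the models, conventions and numerical choices behind
`navfair`, in the order the pipeline runs them.

## Time and labelling conventions

Days are integer indices with day 0 the Monday of week 0; day `7w` is the
Monday of week `w`. The modelling table keeps one row per active patient
per Monday. The target of the row at Monday `7w` is the patient's
encounter count in the half-open window `[7w, 7w+7)`; an encounter falling
exactly on the next Monday belongs to the next week. Utilization-history
features use only days strictly before the row's Monday, so no feature
overlaps its own target window. Trailing rows whose target window is not
fully covered by the data are dropped, mirroring the removal of the last
patient-weeks from a finite extract.

A patient is active from their first navigator interaction through 90 days
after their last one. Distribution runs at a weekly cadence: patients whose
first active Monday is week `w` are assigned that Monday, and the week-`w`
panel loads (their first scored week) include them.

## Synthetic cohort generator

The generator stands in for a three-year navigation-program EHR extract and
is the package's definition of the study conditions.

**Arrivals.** Each specialty receives Poisson weekly arrivals; the default
roster is three 3-navigator specialties at 20.1 patients/week and two
2-navigator specialties at 13.4 patients/week — 13 navigators in all, and
roughly 13,000 patients over the default 150 weeks.

**Encounters.** Each patient's contact follows a scheduled-visit renewal
process rather than a memoryless stream: after each encounter the gap to
the next is gamma-distributed with mean `7 / rate` days (shape 20, i.e.
fairly regular appointments), rounded to whole days with a 1-day minimum —
which also enforces at most one encounter per patient per day, the
definition of the `enct` proxy. The enrollment day always carries the
intake contact. Encounters stop at the end of a navigation episode
(gamma-distributed length, mean 10 weeks, shape 2, capped at 52 weeks) and
an early-episode multiplier `1 + 1.5·exp(-t/4wk)` front-loads intensity.
A hard truncation rule drops encounters beyond 15 in any consecutive
30-day window from enrollment.

**Heterogeneity.** Base weekly visit rates are zero-inflated gamma: 9% of
patients are in an *engaged* phase with rates drawn from Gamma(shape 2,
mean 0.5/week, capped at 2.5/week); the rest need little beyond intake
(0.012/week). Engagement corresponds to the upper tail of a standard-normal
latent driver `z`, so intake covariates correlated with `z` genuinely
predict near-term workload — the premise of the prediction model. This
mixture, the episode/tail structure, and the renewal cadence jointly
reproduce the target monthly profile.

**Calibration.** The free parameters (engaged fraction, rate distribution,
episode length, phase boost) were calibrated once against the published
monthly workload profile — mean 0.5 and SD 1.1 encounters/patient/month,
median 0, CV 220%, range 0–15 — and then frozen. At default settings and
≥ 10,000 simulated patient-months the generator yields mean ≈ 0.51,
SD ≈ 1.10, CV ≈ 214%, median 0, max 15, stable across seeds.

**Skewness.** The published skewness of 1.36 equals exactly
`3·(mean − median)/SD = 3·0.5/1.1` — Pearson's second (median) skewness
coefficient. A third-moment skewness of 1.36 is not attainable *jointly*
with mean 0.5 and SD 1.1 by any distribution on the nonnegative axis: by
the Markov–Krein lower principal representation the minimum moment
skewness under those two constraints is ≈ 1.74 (attained by a two-point
law), and any realistic count model with a tail to 15 sits far higher.
`monthly_workload_stats` therefore reports `skew` as Pearson's median
skewness (≈ 1.40 at default calibration) and also exposes the adjusted
Fisher–Pearson moment skewness as `moment_skew` (≈ 5–6) for transparency.

**Covariates.** Age, ADI (1–100 percentile), RUCC (1–9), sex, a
six-category insurance plan (emitted as raw EHR-style plan strings), and a
specialty-specific cancer subtype are noisy monotone functions of the
latent driver (ADI loading 0.8, RUCC 0.45, age 0.3; subtype and insurance
probabilities tilted by severity). ADI/RUCC carry realistic missingness for
the imputation stage. `feature_signal_strength` scales every loading; at
exactly 0 the generator switches to a degenerate memoryless mode — one
shared constant rate, no episode structure — in which, conditional on being
active, the next-week count is independent of *all* history, including
utilization features, so no regressor can beat the mean baseline. The
calibration guarantees above apply at the default strength 1 only.

**What the generator does not emulate.** Real demographics tables, real
zip-code geocoding, seasonal and secular volume trends, navigator-initiated
contact patterns, and any dependence of a patient's encounters on which
navigator holds them. Passing tests therefore demonstrate correctness of
the pipeline and the qualitative policy comparison under these stylized
dynamics, not clinical performance on real panels.

## Preprocessing

Features with ≥ 80% nulls are dropped. Insurance plans collapse to six
categories via a shipped keyword table (first match wins; BC/BS keywords
are checked before generic commercial carriers; missing or unmatched plans
become *Others*). Missing ADI/RUCC values are imputed with the
*training-set* mean only; the 80/20 split is by patient, so every row of a
patient lands on one side. Nine-digit ADIs averaged within a five-digit zip
are supported as a standalone helper. The workload-proxy evaluator scores
four candidates (`notct`, `notct2`, `enct`, `dur` — the daily first-to-last
EHR-touch span in hours) by the Pearson correlation between monthly per-day
averages and monthly panel size per navigator; constant series yield an
undefined (NaN) correlation rather than a rank.

## Clustering

Hand-implemented k-prototypes (no suitable maintained implementation is
available in the environment): squared Euclidean distance on standardized
numerics plus `gamma ×` mismatch counts on categoricals, alternating
assignment and mean/mode updates until assignments stabilize. `gamma`
defaults to half the mean variance of the standardized numerics (0.5).
Initialization is k-means++-style seeding under the mixed distance, with
the best of 5 restarts kept; empty clusters are re-seeded from the point
farthest from its centroid; assignment ties break to the lowest cluster
index. `select_k` applies the max-distance-to-chord elbow rule on the
*log* cost curve — on the raw scale the chord lands mid-decline whenever
planted structure collapses the cost by orders of magnitude. The pipeline
default is k = 7; days-since-diagnosis is excluded from clustering inputs.

## Prediction

The regressor sees demographics, ADI/RUCC, date and utilization-trend
features plus the cluster id; days since last navigator interaction and
days since cancer diagnosis are excluded by design. Hyperparameters come
from a 15-combination random search (boosted trees: depth 2–8, learning
rate 0.01–0.3 log-uniform, 50–500 trees, subsample 0.6–1; random forest:
100–500 trees, depth 4–16, min-leaf 1–8; neural network: 1–2 layers, 8–64
units, weight decay 1e-5–1e-2 — these spaces are package choices) scored by
3-fold cross-validation with folds split by patient; ties go to the first
sampled combination. Raw predictions are clipped at zero. For large
training tables the clustering stage fits on a 50,000-row subsample (every
row is still assigned a cluster). The shipped default trains only the
boosted-tree family plus a predict-the-mean baseline; the other families
sit behind the same interface for comparison runs.

## Distribution

Given existing predicted loads `e_j` and new-patient predicted workloads
`w_p`, minimizing the unfairness of final loads is linearized as
`min Σ d_j` with `d_j ≥ L_j − F`, `d_j ≥ F − L_j`, `F` constant, and binary
assignment variables; HiGHS solves instances up to 12 new patients exactly
(configurable), with the LPT greedy — heaviest patient to the currently
lightest navigator, ties to the lowest index — beyond that. The objective
carries an epsilon-weighted secondary term (minimize the maximum
per-navigator count of that week's new patients) purely to select among
equally fair optima: zero-workload patients otherwise land arbitrarily,
and under the never-transfer constraint an arbitrary pile-up persists for
the patient's whole tenure. The epsilon (1e-6 × problem scale) cannot
trade against the primary objective beyond solver tolerance. The oracle
(future-informed) policy runs the identical solver on realized workloads.

## Simulation

All policies replay identical realized encounter streams — the workload
proxy is patient-driven, so assignment changes who carries a load, never
the load itself. The random baseline reports, for each week, the mean
unfairness over 10,000 conditional re-draws of that week's new assignments
around a single committed random trajectory (one extra draw evolves the
panel); a switch to fewer, fully independent trajectories is a one-line
change in the calling code. Weekly unfairness is always scored on actual
workloads; the 95% CIs use the 1.98 formula with n = weeks. The headline
comparison trains on the 80% training patients and simulates the 20%
held-out patients over 150 weeks; the policy-ordering check
(oracle ≤ prediction-informed ≤ random) runs on twenty 40-week
two-specialty cohorts, asserting the aggregate and reporting per-seed
violations. Default problem sizes (150 weeks, five specialties, 10,000
repetitions, 15-combination tuning) run end to end in a few minutes on a
single CPU.

## Known limitations

Weekly myopic optimization with only new patients as the lever cannot
remove the unfairness floor set by integer indivisibility of encounters
and by panel drift; the oracle policy quantifies that floor. The
future-informed oracle is only guaranteed to beat the prediction policy
in aggregate — a realized-workload optimizer can lose on individual
cohorts by chasing one-week noise into persistent placements. Percent
reductions depend on the simulated arrival volume (the held-out partition
carries ~20% of the configured rates); they are reproducible for a fixed
seed but vary by a few points across seeds.
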