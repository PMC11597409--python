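# Methods

This note documents the models, conventions and design choices behind the
package, in the order the pipeline runs them.

## Data model and file conventions

All tables are comma-separated UTF-8 with ISO-8601 dates. Set-valued fields
are packed into one CSV field: semicolons between items, pipes inside
structured items (tenures, alpha tenures). The three inputs are

- `scans.csv` — one row per instantaneous scan: `scan_id, date, time,
  group_id, focal_id, activity, neighbors_5m` (semicolon-joined ids of the
  adult females within 5 m; an empty field is an empty set);
- `agonistic.csv` — `date, group_id, winner_id, loser_id, behaviour
  (displacement|avoidance), sex_class`;
- `demography.csv` — one row per individual: `id, sex, birth_date, tenures,
  offspring_births, alpha_tenures`.

Validation is strict: unknown ids, non-resident participants, focals listed
among their own neighbours, overlapping tenures and malformed enums are
errors reported with line numbers. A `lax` mode downgrades referential
errors to warnings because real field data contain unidentified
individuals. Adulthood is age ≥ 10 years. An offspring is a *dependent
infant* while younger than 12 months (365 days). Absence from
`neighbors_5m` means "not recorded within 5 m", not a confirmed distance —
partial visibility in dense vegetation cannot be distinguished from genuine
absence, and the analysis does not attempt to.

## Synthetic data generator

The generator reproduces the statistical structure the analysis assumes,
with effect sizes that are known exactly, so estimator behaviour can be
measured rather than asserted.

**Observation design (defaults).** Three groups followed for eight years;
2–7 adult females per group; focal follows per female-year drawn from
N(100, 50²) scaled by her residency fraction; 2–6 scans per focal at
10-minute spacing. These match the scale of the motivating field design
(groups of 2–7 females, roughly 80–160 focals per female-year).

**Demography (defaults).** Per female-year: birth probability 0.2 (a
realized inter-birth interval around five years), emigration 0.06 (vetoed
when a group would fall below two females; half of emigrants re-join
another group after 30–200 days — secondary dispersal), immigration 0.06
per resident female (entry date uniform within the year; vetoed when the
group is at the top of the configured female range, so simulated groups
stay within the observed 2–7). Alpha-male turnover 0.1 per group-year
(the incoming male takes the top latent rank); subordinate males drift in
and out at 0.2 per group-year so that weaned-adult group size varies
independently of female number — without that variation `group_size` is an
exact linear function of `female_number` and the group dummies, and the
collinearity screen (correctly) halts. Initial females are natal adults;
simulated infants are tracked as birth dates on their mothers, not as
individuals, so no mother–adult-daughter co-residence can arise within a
simulated study.

**Proximity process.** For each scan of focal *a*, each co-resident adult
female *b* enters the neighbour set independently with probability

    logit p = beta0 + affinity_ab + beta_rank_avg * meanrank_ab
              + beta_both_infant * 1[both have infant < 1 y on scan date]
              + beta_one_infant  * 1[exactly one does]
              + beta_immigrant   * 1[either is within 1 y of an immigration entry]
              + u_a + u_b + w_year

with `beta0 = −2.4` (baseline rate ≈ 0.08, the magnitude of observed
dyadic strengths), static dyad affinities (sd 0.5), female intercepts
(sd 0.3) and calendar-year intercepts (sd 0.2) shared across groups — the
same structure as the fitted models' random effects. Default injected
effects follow the directions the motivating analysis reports:
`beta_rank_avg = +0.5`, `beta_both_infant = +1.0`, `beta_immigrant = −1.0`,
`beta_one_infant = 0`. Because proximity is generated focal-centrically,
the symmetry of the dyadic index is an emergent property of the tallying,
not imposed per scan. The infant indicator uses age < 12 months *on the
scan date*, whereas the covariate module flags a female-year only when that
state held for > 183 days of the year — a deliberate mismatch that acts as
a realistic misclassification stress test. Latent dominance ranks are
drawn once per female from N(0, 1.5²); females whose first tenure is an
immigration enter below the current group minimum, consistent with
bottom-entry in the rating system.

**Agonistic process.** Per same-sex co-resident dyad-year, a Poisson number
of dated events (mean 20, scaled by co-residency) whose winner is the
higher-latent individual with probability logistic(latent_i − latent_j).

All realized latent quantities are persisted (`truth.csv`) for recovery
tests. Identical scenario + seed yields byte-identical outputs.

What the generator does **not** emulate: spatially explicit movement,
observation-condition biases (visibility, habituation), seasonality,
male–female association beyond alpha identity, infant mortality, and
kinship. Tests passing on this generator therefore show that the pipeline
recovers the effects *its models assume*; they cannot show robustness to
field artefacts outside that structure.

## Dominance

Elo ratings per group and sex: start 1000, k = 100, classic base-10
expected-score curve with scale 400 (the most widely documented
convention; at this event volume the curve shape is dominated by k).
Events are sorted internally by (date, group, sex, winner, loser,
behaviour), so any input permutation gives the same result; same-day
membership changes are applied before that day's contests. Founders start
at 1000; an individual entering a hierarchy that already has rated members
starts at the *current minimum among active members* (bottom entry; the
alternative fixed-1000 entry is not offered because it contradicts the
bottom-entry convention). Ratings are defined from group entry, carried
forward between interactions, truncated at exit; a female who returns to a
group resumes her previous rating there, while a transfer to a *different*
group starts a fresh trajectory at that hierarchy's bottom.

Yearly scores average daily ratings over the individual's *active days*
only (no imputation before entry or after exit). Female scores are min–max
standardized to [0, 1] per group-year (1 = highest); a single female, or a
tie across the whole group, maps to 0.5 with a warning. The dyadic rank
predictor is the mean of the two members' standardized ranks. The male
with the highest yearly mean is the alpha; a lone male is alpha by
default; ties break by earlier group entry, then id — determinism over
elegance. Male and female hierarchies are fully separate (separate
1000-point scales per group).

## Association networks

One network per group × window. Windows are half-open `[start, end)`;
calendar windows span Jan 1–Jan 1. Nodes are adult females resident at
least one day of the window (a `min_focals_per_window` option can exclude
under-sampled females; default 0). `N_a` counts scans with *a* as focal;
`N_ab` counts scans — from either member's focals — with the pair within
5 m; dyadic strength is `N_ab / (N_a + N_b)`, undefined (dropped, with a
warning) when the denominator is zero. Node strength defaults to the
weighted degree over incident dyadic strengths; the alternative reading of
an individual rate ("times observed within 5 m of any female, per own
scan") is available as `node_strength=raw_rate`.

## Covariates and model tables

Annual resolution, calendar years:

- **dependent infant** — some offspring was under 12 months on strictly
  more than 183 days of the year (">6 months" read strictly);
- **new immigrant** — the first *scored* year of an immigration tenure:
  the entry year when entry is on or before 1 July, otherwise the next
  year; the skipped partial entry year is excluded from scoring entirely
  (her first score covers her first full association period);
- **last year** — an emigration (not death/censoring) occurs in the
  following calendar year;
- **new alpha male** — alpha identity differs from the previous year;
  undefined in a group's first observed year (rows dropped);
- **tenure** — years since the current tenure's entry, at mid-year;
- **female number / group size** — adult females / weaned adults of both
  sexes resident a majority (> 182 days) of the year. Simulated demography
  contains no weaned immatures, so group size equals the adult count
  there; with field data that lists immatures, the same majority rule
  counts them once they are weaned.

The individual-year and dyad-year tables join strengths, ranks and flags on
(group, year, id(s)); rows with any undefined ingredient (no focal scans,
no rank, unknown previous alpha, unscored immigrant year) are dropped and
logged, and dyad rows require both members to be scored, so per group-year
the dyad count is C(scored females, 2).

## Event-centred windows

For each second-birth event (a dyad whose two infants' dependency periods
overlap; anchor = the later birth) and each immigration (anchor = entry
date), association is recomputed in five contiguous 365-day windows,
offsets −2…+2 (births) or 0…+4 (immigrations), with the offset-0 window
*starting* at the anchor — the event date replaces the 31-December boundary
of the calendar pipeline, and anchoring a window on 1 January of a non-leap
year reproduces the calendar network exactly. Leap days are ignored
(fixed-length windows keep offsets comparable). Second-birth events have
exactly one focal dyad; immigration events have none (the immigrant pairs
with every resident), and the immigrant's identity is carried instead.

Three missing-data rules keep the series free of mechanical artefacts,
each diagnosed on null simulations (all effects zero) where any systematic
offset pattern must be spurious:

1. windows not fully inside the group's observed scan period are missing —
   partial coverage deflates the ratio index;
2. a dyad is scored only in windows both members span completely — a
   mid-window entry or exit deflates the index because `N_ab` can accrue
   only during co-residence while the denominators count the whole window;
3. the event condition (both-infant yes/no; immigrant-member yes/no) is
   evaluated over the *whole five-window span*: a comparison dyad with its
   own qualifying episode inside the span genuinely carries the event
   signal and labelling it a control would contaminate the control curve.

Events truncated by the observation period keep their partial series, so
offsets have unequal n. The same dyad may recur across overlapping events
(matched per event); the dyad random intercept absorbs its static level.

## Inference

The estimation backend is a Gaussian linear mixed model fitted by REML
(statsmodels `MixedLM`), with every random intercept expressed as a
variance component over an explicit indicator matrix. This supports the
crossed (individual × year) and multi-membership (dyad members ID1/ID2
share one variance) structures the models need. The backend and its
convergence are declared in each fit's metadata; when no optimizer
converges the fixed effects fall back to ordinary least squares with a
failure flag. Two modelling simplifications relative to a full Bayesian
treatment: the heavy-tailed (Student-t) response family is approximated by
the Gaussian likelihood, and intervals are normal approximations rather
than posterior quantiles. With the generator's Gaussian-logit noise this
approximation is well calibrated (the acceptance suite measures it); with
field data containing outliers a heavy-tailed backend would be the natural
extension point.

Continuous predictors are standardized by subtracting the mean and
dividing by twice the (population) standard deviation, making their
coefficients comparable with those of dichotomous predictors; binary flags
are left as 0/1. Standardization is idempotent. Before fitting,
generalized variance inflation factors are computed from a fixed-effects-
only design (determinant form of the predictor correlation matrix, the
1/(1−R²) rule for single columns); a non-finite GVIF halts the run unless
forced. Terms constant in a given table are pruned with a warning rather
than fitted — small simulated studies legitimately lack, say, an alpha
turnover. A term is *meaningful* when its interval (default 95%,
configurable) excludes zero. Marginal and conditional R² follow the
variance-decomposition definitions: fixed-effect variance over
fixed + random + residual, and fixed + random over the same total, so
conditional ≥ marginal always.

**Event smooths.** Strength is regressed on a cubic B-spline basis of the
window offset (df 4 — saturating the five support points; an unpenalized
low-rank basis, the frequentist counterpart of a penalized smooth with the
smoothing variance profiled out) interacted with the condition factor,
plus a condition main effect and a dyad random intercept. Per condition
level the fit reports: each spline coefficient with its interval; an `sds`
wigglyness summary (the standard deviation of the level's estimated spline
coefficients — 0 for a flat level); and a joint Wald chi-square test of
the level's spline coefficients, whose threshold at the configured
interval level classifies the smooth as meaningful. With only five
offsets, smaller bases would confound curvature with the pulse shape, and
penalization has little room to act; the saturated basis keeps the test
exact for any offset pattern.

No multiple-testing correction is applied anywhere; the per-term
meaningful flags are marginal statements, recorded as such in the output
metadata.

## Problem sizes and determinism

Simulation-based checks (sign recovery, interval calibration, event-smooth
detection) run 20 replicates each at the full study scale of 3 groups × 8
years — roughly 25k–45k scans and 150–500 dyad-year rows per replicate —
which keeps the whole test suite around one minute while leaving the power
of each check at the level the acceptance thresholds require. All
randomness flows from a single integer seed through spawned generator
streams; reruns of any pipeline configuration are byte-identical.

## Known limitations

- Group-year-level shocks are not represented in the fitted models (the
  year intercept is shared across groups, as in the motivating analysis),
  so purely group-year-level predictors such as alpha turnover can show
  mild interval undercoverage when such shocks exist.
- The immigrant first-scored-year rule leaves early-year joiners with a
  partially observed scored year; their dyads' indices are slightly
  deflated mechanically. This is a property of the annual design itself,
  inherited deliberately.
- Elo ratings assume rank is static within a tenure when initializing
  newcomers at the bottom; a newcomer who truly enters mid-hierarchy is
  misplaced until enough interactions accumulate.
- The event tables re-use comparison dyads across overlapping events;
  inference treats rows as exchangeable given the dyad intercept, which
  understates dependence when event density is very high.
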