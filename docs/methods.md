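# Methods

## Data model

A diary day is an ordered list of (activity, minutes) events summing to
exactly 1440 min at a 5-min resolution (`strict=False` relaxes the grid to
whole minutes for stress tests). Activities resolve through a taxonomy to
one of 13 macrodomains nested in 8 superdomains; three superdomains
(Passive Transport, Quiet Time, Sleep) are not subdivided and appear
under their own name at the macrodomain level, so macrodomain aggregation
(16 parts) always rolls up exactly to the superdomain aggregation
(8 parts). Sleep is an activity attribute (`is_sleep`), not a time-of-day
rule, so naps count as Sleep. The bundled taxonomy (~30 activities) is a
stand-in with placeholder MET values chosen inside plausible compendium
ranges; it exists so the pipeline is runnable and testable, and it is a
user-replaceable input for any substantive analysis. Effort levels
(e.g. soccer light/medium/hard) are distinct activity codes with distinct
METs rather than a runtime modifier.

## Composite days

Each child contributes one analysis day per type; when several days of a
type were recalled one is picked uniformly at random (per-child
substreams derived from the run seed, so selection is reproducible and
independent across children). The in-term composite is the raw-minute
convex combination (5·school + 2·weekend)/7 — the weights are
configurable, and (1, 0) reduces the composite to the school day. The
weighting is applied to raw minutes, not in log-ratio space: the literal
reading of a weighted amalgam of days, and the one that makes the
composite's population mean the same convex combination of the day-type
means. The holiday profile is the single selected holiday day,
unweighted. Children missing a day type are excluded with a logged
reason, not imputed.

## Compositional machinery

Closure, multiplicative zero replacement, the ilr transformation and its
inverse are implemented directly on arrays (last axis = parts) and
verified in tests against scikit-bio and closed forms. Choices that the
underlying methodology leaves open:

- **Zero replacement** — deterministic multiplicative simple replacement
  with δ = 0.65 and detection limit DL = 5 min (the diary resolution),
  both configurable. It is reproducible, preserves all ratios among
  non-zero parts exactly, and is adequate for count-like minutes. Zeros
  are replaced at the superdomain level, the level at which inference
  runs.
- **ilr basis** — the pivot (sequential binary partition) basis in fixed
  superdomain order. No inferential quantity depends on the basis (all
  test statistics are invariant under orthonormal basis change, which is
  tested to 1e-8); the choice affects only coordinate interpretability.
- **Percent TDEE decrement** — computed as 100·(in-term − holiday)/holiday.
  The holiday denominator is the only reading that reproduces the
  published worked example (123/2282 → 5.4 %); an option computes the
  in-term-denominator variant (123/2405 → 5.1 %).
- **Rounding for reporting** — nearest minute for times, one decimal for
  percents; differences are always computed from unrounded means.

## Inference

For two time points, the multivariate "time × coordinate" repeated-
measures formulation collapses exactly to the paired Hotelling T² on the
7-vector of per-child coordinate differences; that is the default
(`full`) test. `interaction_only` first applies the successive-difference
contrast across coordinates, testing whether the change is uniform over
coordinates — the literal interaction reading. Moderation is a one-way
MANOVA on the difference vectors (Wilks' Λ, Rao's F approximation, with
t = 1 when the radicand's denominator is non-positive). Degenerate
inputs: a zero mean difference yields T² = 0 and p = 1 even when the
sample covariance is singular; otherwise singular scatter matrices raise
with advice rather than returning pseudo-inverse artefacts.

Missing area-SES (IRSD) scores are completed by predictive mean matching:
OLS on complete cases with parental-education and weight-status codes as
predictors, each missing entry copying the observed value of one of
k = 5 donors with nearest fitted prediction, chosen uniformly under the
seed. A single stochastic imputation is performed (the typical missing
count here is 3 of 366); multiple imputation with pooling is out of
scope. IRSD enters moderation as sample-quantile tertiles with ties
assigned to the lower tertile. p-values are kept at machine precision;
"< 0.0001"-style formatting is a rendering concern.

## Energy

TDEE is factorial: Σ duration × MET over events (MET·min/day); PAL is
TDEE/1440. Intensity bands: SED requires MET ≤ 1.5 *and* sitting/lying
posture while awake; awake time below 3 METs that fails the posture
clause (standing or ambulatory at ≤ 1.5 MET) is LPA, so bands partition
awake time with no gap between the printed 1.5 and 1.6 cut-points
(implemented as (1.5, 3.0), [3.0, 6.0), [6.0, ∞)). Schofield BMR uses the
published weight-based coefficients for the 3–10 and 10–18 y bands,
shipped as a replaceable data table. The fat projection rounds the daily
deficit (pct/100 × BMR × PAL) to the nearest 10 kJ *before* multiplying
by the period length — this makes the period total an exact multiple of
the reported daily figure, matching the published arithmetic chain — and
reports fat mass to two significant figures using a configurable fat
energy density (default 37 kJ/g, the value consistent with the published
650 g figure). The decrement percentage is an explicit input to the
projection, decoupling it from any particular TDEE estimate.

## Synthetic populations

The generator draws, per child, a between-child effect in ilr space
(diagonal covariance), and per day adds within-child noise around a
day-type centre, back-transforms, apportions onto the 5-min grid by
largest-remainder rounding (total preserved exactly, no part moved by
more than 5 min), and splits each superdomain's minutes into 1–4
taxonomy activities (Dirichlet weights, Poisson-distributed activity
count). With probability `duplicate_day_prob` (0.25) a child recalls a
second day of a random type, exercising the random selection step.

Defaults emulate the study structure: n = 366 children aged 9–16, 53 %
female, weight-status probabilities 259/76/28 and education 162/140/61
out of 363, IRSD ~ N(1003, 68²) with 3 values missing. Day-type centres:
the holiday centre and the in-term composite target are the published
period means (closed to 1440); the weekend centre is a fixed plausible
in-term weekend day, and the school centre is derived as
(7·composite − 2·weekend)/5 so the 5:2 blend reproduces the composite
target exactly. A holiday day omits School-related time entirely with
probability 1 − 78/366 ≈ 0.787 (the observed share of children reporting
any holiday school-related time), redistributing those minutes
proportionally; this is the source of structural zeros.

Two calibration decisions deserve emphasis:

- **Dispersion** is calibrated so simulated per-part spreads roughly match
  the published holiday SDs: per-part log-variances from log-normal
  moment matching of the printed SD/mean ratios, then a diagonal ilr
  covariance fitted by bounded least squares (each coordinate variance
  floored at 0.02 so no log-contrast is degenerate), split evenly between
  between- and within-child components since no decomposition is
  published. The match is deliberately rough: the School-related holiday
  SD, for instance, exceeds the printed value because of the large
  structural-zero mass.
- **Centres are arithmetic-mean targets.** With dispersion this large, the
  arithmetic mean of a logistic-normal sample differs from its geometric
  centre by tens of minutes for small parts. The generator therefore
  applies a deterministic fixed-point mean correction in ilr space
  (common antithetic quasi-draws from a fixed internal stream, cached per
  configuration) so the population arithmetic mean of each day type —
  including dropout — equals its configured centre. Configured
  differences are then recovered unbiasedly by construction of the model,
  and the recovery experiment verifies the whole diary pipeline delivers
  them.

What the generator does *not* emulate: recall error and desirability
bias, seasonal structure, within-type day-to-day autocorrelation, and
realistic within-superdomain activity mixes (activities are sampled
exchangeably). Passing simulation tests therefore validate the
*statistical machinery* under the assumed model, not the substantive
field findings.

### Harness design

- `null_rejection_experiment` uses composite weights (1, 0) — a single
  school day against a single holiday day. This is deliberate: under
  identical day-type centres the 5:2 raw-minute composite is *not* an
  exact null, because the expected ilr image of an average of two noisy
  days is shifted by convexity (empirically the type-I rate inflates
  ~2-fold at n = 100 under the default noise). That shift is a genuine
  property of composite-day designs, worth knowing; calibration is
  therefore assessed on the exact paired null.
- Type-I, moderation-null and power harnesses generate superdomain
  compositions vectorised (with rounding and dropout but without event
  splitting, which the test statistics never see); the recovery
  experiment runs the full event-level pipeline. Default problem sizes —
  2000 null replicates at n = 100, 1000 moderation replicates at n = 366,
  50 recovery replicates — keep each harness in the tens of seconds while
  leaving Monte-Carlo error well below the tolerances being checked.
- Replicates use seeds spawned from (seed, replicate), so runs are
  independent and embarrassingly parallel yet fully reproducible.

## Known limitations

- The bundled taxonomy's MET values are placeholders; absolute TDEE/band
  outputs on bundled-taxonomy simulations are internally consistent but
  not compendium-grade.
- The diagonal-in-pivot-basis noise model cannot represent arbitrary
  between-part correlation structure.
- One imputation, not multiple; no univariate per-coordinate follow-up
  tests.
- The difference table reports arithmetic means (the field's reporting
  convention); `compositional_mean` provides the geometric centre but is
  not used in the headline table.
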