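# Methods

This package evaluates the effect of primary-health-care facility
accreditation on facility-level health outcomes in a quasi-experimental
design: individuals are assigned to facility catchments by GPS proximity,
their binary outcomes are collapsed into a facility × survey-wave panel of
percentages, and treatment effects are estimated by difference-in-differences
(DiD) estimators, with kernel propensity-score matching to absorb the
vulnerability-targeted rollout. A synthetic-data generator reproduces the
statistical structure of the inputs with known ground truth, so every stage
is testable without restricted survey data.

## Synthetic data model

**Districts.** Each district carries eight socio-economic indicators:
illiteracy, unemployment, and income-dependency ratios, shares without
electricity and without potable water (all Beta-distributed proportions),
average family size (3 + Gamma(2, 0.6) persons), household crowding
(0.8 + Gamma(2, 0.35) persons/room), and population size (lognormal). A
region label is drawn from the six-level set used for regional dummies.

**Vulnerability index.** The mean of the eight indicators after
z-standardization across the generated district set, signed so that higher
means more deprived. The seven deprivation indicators enter positively;
population size enters negatively (larger districts treated as less
vulnerable). The sign convention is a package choice, configurable via
`INDICATOR_SIGNS`. Indicators with (numerically) zero variance contribute
zero with a logged warning.

**Rollout.** Treatment is assigned at the district level: district *d* is
selected with probability `expit(logit(s) + τ·v_d)`, where `v_d` is the
vulnerability index, `τ` the targeting strength (default 1.0), and `s` the
target treated share (default 0.45). Selected districts receive one of the
configured rollout waves. Facilities in selected districts sit an
accreditation survey (scores drawn Beta(5, 2)); the three-tier rule awards
**full** accreditation at a score ≥ 0.80, **provisional** at [0.50, 0.80),
and **denies** below 0.50. Denied facilities stay untreated. Both full and
provisional count as treated from the rollout wave onward. A fraction of
accredited facilities (default 10%) is flagged as subject to other
concurrent interventions, to exercise the downstream exclusion rule.

**Geography.** Facilities sit on a jittered lattice over a ~1000 km box,
guaranteeing inter-facility spacing large relative to the woman-level GPS
jitter (isotropic Gaussian, SD 2 km); at the defaults, nearest-facility
linkage recovers the generating facility for >99% of women (measured
mislinkage ≈ 0%). Lattice cells are chunked into districts so districts are
spatially coherent.

**Outcomes.** Twelve binary indicators per woman (two family-planning
knowledge outcomes, five antenatal-care quality/coverage outcomes, two
delivery-care outcomes, three child-morbidity outcomes). For outcome *k*,
woman *w* at facility *i* in wave *t*:

    logit P(y=1) = logit(π_k) + γ_t + b_ik − κ·v_d(i) + θ_ikt

with baseline rate `π_k`, secular wave effect `γ_t` (log-odds), facility
random intercept `b_ik ~ N(0, σ_f²)` (σ_f = 0.3), and a confounding term
linking outcome levels to district vulnerability (κ = 0.5 by default).
`θ_ikt` is the planted treatment effect: for treated facility-waves it is
the log-odds shift whose probability-scale lift equals exactly
`effect_ppts/100` at that cell's no-treatment probability (clipped away
from 0/1). Planting the lift exactly in percentage points — rather than a
fixed logit offset — makes the generative model's infinite-n DiD equal the
configured effect regardless of wave effects and facility heterogeneity,
which is what the recovery studies require. Eligibility for each outcome's
denominator is Bernoulli (55–75% depending on outcome family), so
denominators differ by outcome as in real survey data.

Baseline rates default to national averages where a published figure
exists (ANC 4+ visits 56%, weight measurement 82%, blood pressure 82%,
informed of complications 34%, institutional delivery 60%, skilled-assisted
delivery 70%, fever 23%, ARI 14%, diarrhea 13%); the remaining three are
set to mid-range values (45%, 40%, 47%). The default of 25 women per
facility-wave matches the density implied by collapsing ~98,000 survey
records into ~3,800 facility-wave cells. An optional divergent pre-trend
(`pretrend_ppts_per_wave`) drifts the eventually treated group during
pre-rollout waves, for power studies of the parallel-trends test.

All randomness flows from a single seed through named substreams per stage
(districts, facilities, treatment, women), so stages can be regenerated
independently and datasets are byte-identical under a fixed seed.

## Spatial linkage

Great-circle (haversine) distance on a sphere of radius 6371.0088 km; the
metric is a package choice (only "GPS linkage" is specified by the design)
and is isolated in one function. Each woman is linked to the distance-
minimizing facility; ties break by lowest facility id, making assignment
invariant to facility-table order. There is no distance cutoff by default
(catchment use is assumed obligatory); an optional `max_distance_km` drops
and counts implausible links.

## Panel construction

Per facility, wave, and outcome: the percentage of *eligible* linked women
with the indicator set, with the denominator recorded. Rules applied, each
logged with counts:

- facilities that are accredited **and** flagged for concurrent
  interventions are removed entirely (the treatment contrast must reflect
  accreditation alone); flagged but never-accredited facilities stay;
- cells with fewer than 5 eligible women are set missing (no published
  rule exists; facility percentages from tiny denominators are noise —
  configurable via `min_denominator`);
- `policy_it = 1` iff wave `t` ≥ accreditation wave and status is
  provisional or full — accreditation between waves counts from the first
  wave after it, with no partial-exposure weighting.

Unbalanced panels are retained for the fixed-effects estimator; two-period
estimators use facilities observed in both chosen waves.

## Estimators

**Panel FE DiD** (`fit_did_fe`): `y_it = α + β·policy_it + γ_t + δ_i + ε_it`
estimated by the within transformation (facility demeaning) of outcome,
policy, and wave dummies; β is the effect in percentage points. Equivalent
to facility-dummy OLS (tested to 1e-8). Raises an explicit
no-identifying-variation error when no facility changes status.

**Two-period DiD** (`fit_did_2period`):
`y_it = α + β·acc_i + γ·d_post + δ·(acc_i × d_post) + ζ'fac_i + η'dist_i + ε_it`
on facilities observed in both waves, with facility covariates (eight staff
counts, building condition, catchment population) and district covariates
(eight indicators, region dummies). Reference levels are fixed (building
condition "bad", region "fully-urban") so coefficients are comparable
across runs. Collinear covariates are dropped with a warning recorded in
the result; a collinear term of interest is an error, never a silent drop.

**Cluster-robust inference.** Sandwich covariance summing within-cluster
score outer products, small-sample factor `G/(G−1) × (N−1)/(N−K)`,
p-values from t with `G−1` degrees of freedom. Clustering defaults to the
district — the level at which treatment is assigned — with a facility-level
option. For the within estimator, K counts the regressors of the demeaned
design but not the absorbed facility effects (the standard panel-FE
convention); counting absorbed effects inflates SEs by ~20% at these panel
dimensions and visibly mis-calibrates the nominal-5% test in simulation.

**Kernel PSM-DiD** (`psm_did`): a logit of treatment status on the eight
district indicators, fit by in-module IRLS (convergence when the largest
coefficient step < 1e-8, cap 100 iterations). Perfectly predicting dummy
levels and collinear covariates are dropped with warnings (they admit no
finite MLE); residual divergence raises an explicit separation error naming
the covariate. Region dummies are optional and off by default: treatment is
assigned at the district level, so the score model effectively has one
observation per district, and the extra five parameters frequently induce
quasi-separation at realistic district counts; regions still enter the
outcome-equation estimators. Common support uses the min–max rule with
off-support facilities excluded and counted. For treated facility *i* with
propensity `p_i` and bandwidth *h* (default 0.06, Epanechnikov; Gaussian
available):

    ω(i,j) = K((p_j − p_i)/h) / Σ_k K((p_k − p_i)/h)
    δ̂_i   = (y_i,post − y_i,pre) − Σ_{j∈C} ω(i,j) (y_j,post − y_j,pre)

and the overall estimate averages δ̂_i over treated facilities on support
(a catchment-population-weighted average is available). Treated units with
no control inside the bandwidth are dropped with a warning, never silently.
The estimate's reported analytic SE is the naive treated-level SD/√n_T and
is labelled as such; the supported inference is a district-level cluster
bootstrap that re-runs propensity fit, support, weights, and the estimate
on every draw and errors out if more than 20% of draws fail. Balance is
reported per covariate as raw and kernel-weighted means, Welch t tests
before/after matching (effective control sample size by the Kish formula),
and standardized mean differences against the pre-matching pooled SD.

## Diagnostics

**Parallel trends.** Restricted to the listed pre-waves *and* to cells not
yet treated (with a staggered rollout a listed wave may already be
post-treatment for an early cohort), regress the outcome on facility
effects, wave dummies, and (eventually treated) × (linear wave-rank trend);
the interaction's cluster-robust t is the test statistic. The linear-trend
form is a package choice; wave rank (0, 1, 2, …) is the time scale, so a
"2 ppts per wave" drift maps directly onto the coefficient.

**Placebo.** Fake-group experiments on the never-treated subsample:
pseudo-treatment is assigned at the district level (respecting the real
assignment mechanism), preserving the treated-district share, with pseudo
rollout waves drawn from the realized rollout distribution; the effect is
re-estimated per draw and the rejection rate at nominal 5% reported. A
fake-timing variant is available through the two-period estimator options.

**Pipeline runner.** `run_pipeline(config)` executes generate → link →
collapse → rules → estimate (all three estimators) → diagnostics from one
config mapping, logs sample-size changes at each stage, enforces the
accounting identity (women generated = linked + dropped-by-distance), and
writes a results JSON that is byte-identical under a fixed config and seed.

## Validation studies and problem sizes

The `studies` module fixes the Monte-Carlo study conditions; the
acceptance script runs them at full size, the analysis drivers at reduced
replicate counts:

- **Recovery**: 500 facilities in 40 districts, two waves, rollout between
  them, targeting strength 2.0 and confounding 1.0, +10 ppts planted on
  one outcome; 200 replicates. PSM-DiD and two-period DiD means land
  within a fraction of a ppt of truth; the naive post-period difference in
  means is biased by ~5 ppts, the size of the planted confounding.
- **Type-I calibration**: 400 independent null datasets (100 facilities,
  4 waves) for the FE t-test, and 400 placebo draws on one 300-facility
  null panel.
- **Pre-trend power**: 500 facilities over the five-wave design with the
  rollout in the last wave, so four waves are genuinely pre-treatment;
  2 ppts/wave planted drift; 200 replicates. (With only three pre-waves
  the same test's power is ~60% at these noise levels — the trend test
  gains roughly with the spread of the time points.)
- **Propensity recovery**: one logit fit at n = 5000 with true slopes
  (0.8, −0.5), judged against its model SEs.

## What the synthetic data does not emulate

No survey weights or multi-stage cluster sampling; no DHS GPS displacement
or road-network travel times; no re-assessment of provisionally accredited
facilities; no within-district heterogeneity in rollout timing; outcomes
are conditionally independent Bernoulli given the facility-wave cell (no
woman-level covariates or correlation across outcomes). Passing tests
therefore demonstrate estimator correctness and calibration under the
assumed sampling structure, not robustness to those real-data features.

## Known limitations

- The FE estimator is the classical two-way specification; with staggered
  adoption and heterogeneous effects it carries the usual negative-weight
  caveats (heterogeneity-robust estimators are out of scope; effects are
  homogeneous in the generator).
- Kernel bandwidth (0.06) and family follow applied-matching convention;
  no data-driven bandwidth selection.
- The PSM-DiD analytic SE ignores matching uncertainty by construction;
  use the bootstrap.
- Logistic separation handling drops offending dummies rather than
  penalizing; a Firth-type fit would retain them.
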