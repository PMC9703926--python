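# Methods

This note documents the models implemented in `sirscan`, the synthetic-data
generator that stands in for confidential screening data, the numerical
choices made where the design was open, and what the test suite does and does
not establish.

## Discrete-time survival model

Follow-up screening outcomes are interval-censored: a case is observed at a
round, not at a calendar time. Each subject `j` contributes one
pseudo-observation per attended follow-up round `t ∈ {2, 3}`, provided no
earlier round produced a diagnosis. The diagnosis indicator is modelled as

    y_jt ~ Bernoulli(λ_jt),
    log(−log(1 − λ_jt)) = log d_jt + α + Σ_k β_k x_jtk,

where `d_jt` (years, > 0) is the gap to the most recent prior examination.
With the complementary log-log link, `λ = 1 − exp(−d·exp(α + βx))` is exactly
the event probability of a constant-hazard exponential survival model
observed over `d` person-years, so `exp(β_k)` is a hazard ratio. Covariates
are sex (0 = men, 1 = women), log(age in years), log(BMI in kg/m²) and a
third-round dummy; no interactions.

Fitting goes through an IRLS binomial GLM (statsmodels) started from the
closed-form intercept `log(−log(1 − ȳ)) − mean(log d)`, followed by Newton
polishing with step-halving until the score norm is below 1e−9 (the suite
asserts < 1e−6), so the score equations hold tightly even with ~100 events
in ~440,000 records. The covariance is the inverse observed information at
the polished optimum. Zero events and rank-deficient designs raise typed
errors; quasi-separation surfaces as a cleared `converged` flag. Wald
intervals `exp(β̂ ± 1.96·SE)` are reported throughout; profile likelihood is
not used.

Intervals are taken from an `interval_years` column, or computed as exact day
counts / 365.25 when an `exam_date` column is present. BMI outside [5, 50]
kg/m² is treated as a recording error and replaced by the subject's
nearest-in-round in-range value (ties to the earlier round — the nearer
examination is the better proxy); subjects with no in-range value are
excluded. Eligibility (attended round 1, undiagnosed there) is an input
property of the cohort table, not inferred, because the first-round
diagnosis process is out of scope.

## SIRs and the spatial null

Expected counts `e_i = Σ_{j∈S_i} Σ_t λ̂_jt` conserve the fitted total by
construction. Because each pseudo-observation is a rare Bernoulli trial, the
regional totals are treated as `o_i ~ Poisson(r_i e_i)`; the homogeneous-risk
null is `r_i = 1` for all regions. Regions with `e_i = 0` (no analysable
records) are reported but dropped from all spatial tests. Both Monte Carlo
engines condition on the observed case total and redistribute it
multinomially with probabilities `e_i/Σe`, which keeps the reference
distribution exchangeable with the observed data under the null. The
uncertainty of the `e_i` themselves (they are estimates) is ignored in the
spatial tests, which can make their p-values slightly anti-conservative;
this is a known property of the two-stage design.

## Flexibly shaped spatial scan

Candidate zones for each starting region `i` are every connected subset of
size ≤ K drawn from `{i}` plus the K−1 regions nearest to `i` by centroid
Euclidean distance (ties broken by region id), de-duplicated across starting
regions. Enumeration uses the standard grow-only connected-subgraph
algorithm with an exclusion set, verified in the suite against brute-force
enumeration. The zone score is the Poisson log likelihood ratio

    llr(Z) = o_Z log(o_Z/e_Z) + (O−o_Z) log((O−o_Z)/(E−e_Z)) − O log(O/E)

when the inside rate exceeds the outside rate, else 0; zero counts contribute
zero. The original (unrestricted) likelihood ratio is used, not the
restricted variant. The maximum over zones is the test statistic; its
p-value is `(1 + #{replicate max ≥ observed})/(R + 1)`, never zero. Defaults:
K = 15 (the convention of the method's reference implementation), R = 999.
The reported cluster relative risk is `o_Z/e_Z`. Secondary clusters are
accepted greedily by descending llr among zones disjoint from all previously
accepted ones. Scanning is vectorised over zones (sparse membership matrix),
and a precomputed zone list can be reused across datasets that share a
geometry.

## C-index and MEET

The clustering-tendency index at scale `s` (km) is the quadratic form

    C(s) = Σ_i Σ_j w_ij(s) (r_i − p_i)(r_j − p_j),
    w_ij(s) = exp(−4 (d_ij/s)²),

with `r = o/O`, `p = e/E`. The Gaussian kernel is positive semidefinite, so
C ≥ 0, and C → 0 as `s → ∞` because both proportion vectors sum to one. The
default scale grid is 5, 10, …, 100 km. Per-scale p-values are Monte Carlo
ranks (not a chi-square approximation), so a single replicate set serves
every scale and the adjusted inference: the MEET statistic is the minimum
per-scale p, and the adjusted p-value is the share of replicates whose own
minimum (computed by tie-aware ranking within the replicate set) is at least
as extreme. The Monte Carlo p floors at 1/(R+1); when several scales tie at
the floor, the minimizing scale is reported as the tied scale with the
largest standardized excess `(C_obs − mean C_null)/sd C_null`, which keeps
the scale estimate informative for strong clusters.

## Dose-group models

Scenario doses per region are equally weighted; the representative dose is
the median (even counts: midpoint of the central pair), with min and max as
sensitivity aggregations. A mixed municipality's non-evacuated average enters
as one more scenario row. Groups use half-open cutpoints [0, 2), [2, 5),
[5, 10), [10, ∞) mGy. The ecological model has no intercept and exhaustive
group dummies with offset `log e_i`, so each fitted `exp(β̂_k)` equals the
group's pooled `Σo/Σe` exactly (asserted in the suite); the GLM route is kept
for the Wald intervals. The null model fixes every `r_i = 1` (zero
parameters), so `AIC_null = −2·loglik(o; e)`. The trend test is a Wald test
on an ordinal score 1–4 in a separate intercept-plus-score Poisson model — a
score-based choice made here because the analysis convention only requires
*a* trend p-value, not a specific construction. A group with regions but no
cases has an infinite MLE on the log scale and is reported as undefined
rather than fitted. The individual-level sensitivity model appends three
group dummies (lowest as reference) to the survival covariates; on simulated
data its estimates agree with the ecological ones within Monte Carlo error,
which the acceptance suite checks on a 250,000-subject cohort.

## Synthetic-data generator

The generator emulates the composition of a three-round screening cohort of
252,502 subjects: participation patterns D12-only / all-three / D13 with
shares 55,081 : 186,822 : 10,599, sex split 50.2/49.8, inter-examination
gaps from truncated normals with means 2.1 y (consecutive rounds) and 4.0 y
(skipped round) bounded to [0.02, 8.3] y, ages at the round-2 examination
from a truncated normal (mean 11.6 y, sd 5.2 y) with minimum 3 y so log(age)
is always defined (earlier-round ages are kept ≥ 1 y by bounding the drawn
gap), and BMI from a truncated normal (mean 18.5, sd 3.2 kg/m²) with a small
per-round jitter. A configurable fraction of BMI records (default 1% per
record, chosen so that the share of subjects needing replacement is a few
percent, as in real screening databases) is corrupted to an out-of-range
value; outcomes are always generated from the uncorrupted values, because
recording errors live in the database, not in the biology.

True hazard-ratio parameters default to sex 1.283, log-age 24.811, log-BMI
5.088, third round 0.459 — the magnitudes reported for this class of
screening cohort — and the intercept α = −22.358 was set once by solving
E[total cases] = 99 at the default scale under the generator's covariate
marginals. An optional planted cluster adds a constant excess log relative
risk on the cloglog scale for a connected set of regions.

Regions are synthetic: a square lattice with rook adjacency (10 km spacing),
or uniform random centroids in a 100 km square with Delaunay adjacency
(irregular, connected, planar — a reasonable stand-in for a prefecture's
59 municipalities). Population weights are log-normal (σ = 1), giving the
heavy-tailed municipality sizes real prefectures show. All distances are
planar Euclidean in km. One global integer seed drives named substreams
(CRC32-tagged SeedSequence spawn keys) so each stage is independently
reproducible and all outputs are bit-identical across runs at a fixed seed.

What the generator does *not* emulate: real geography or population rosters,
dose reconstruction, age–BMI dependence (independent marginals are used; the
joint distribution of the real cohort is unpublished), migration and
drop-out, or differential diagnostic effort between areas. Passing tests
therefore show that the estimators and tests behave correctly under the
stated data-generating process — unbiased recovery, nominal coverage and
type-I error, power against planted clusters — not that any particular real
dataset is free of the biases the generator omits.

## Problem sizes used by the test and acceptance suites

Sizes fixed by the acceptance design: Monte Carlo calibration uses 500 null
datasets at R = 199 (Flexscan and MEET rejection rates at nominal 0.05 must
fall in [0.03, 0.07]); Wald coverage uses 200 cohorts of 50,000 subjects
(coverage in [90%, 99%]); planted-cluster recovery uses 50 cohorts of
250,000 subjects over 59 regions with a 3× excess-risk cluster. Sizes the
design leaves open were fixed once as the package's own choices: calibration
nulls run on 15-region graphs with K = 5 (the calibration property does not
depend on graph size); the recovery scan uses K = 10 with a precomputed zone
list and R = 19, since only the most likely cluster — not its p-value — is
assessed; the planted cluster is the connected triple of regions maximizing
the minimum population share, so that every planted member carries enough
population for its signal to be attributable by any method. The oracle
checks (brute-force zone enumeration, double-sum C-index, closed-form group
RRs, direct likelihood maximisation) run on instances of at most 59 regions
or 200 records.

## Known limitations

- Wald intervals with ~100 events are adequate (the suite verifies coverage
  at the study scale) but would degrade for much rarer outcomes; no
  profile-likelihood or exact alternative is provided.
- The spatial tests inherit the two-stage design's assumption that the
  expected counts are known; their p-values do not propagate survival-model
  uncertainty.
- The scan's candidate-zone construction (K-nearest-neighbour restriction)
  can miss very elongated clusters whose members are not among each other's
  K nearest regions.
- The trend test's ordinal scores 1–4 treat the dose groups as equally
  spaced; a different spacing would give a different trend statistic.
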