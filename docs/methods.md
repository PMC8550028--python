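# Methods

`visconf` models trial-level behavior in masked binary identification tasks
where each trial yields an identification response and a graded subjective
report — the visibility of the stimulus, or confidence that the response was
correct. This note documents the generative models, the estimation and
comparison machinery, the synthetic-data conditions, and the numerical and
design choices a maintainer would want spelled out.

## Task and data model

A stimulus has an identity `S_id ∈ {−1, +1}` (e.g., grating orientation) and a
strength manipulated through the stimulus-onset asynchrony (SOA) between
target and mask; the five levels 8.3, 16.7, 33.3, 66.7 and 133.3 ms are the
package default. The observer gives an identification response
`R_id ∈ {−1, +1}` and a continuous rating in `[0, 1]`, which the analysis
discretizes into `n_categories = 5` equal partitions (half-open bins, the last
closed, so a rating of exactly 1 lands in the top category; ratings exactly on
an interior edge belong to the upper bin — the convention is ours, stated here
because boundary trials are possible with joystick scales). All likelihoods
operate on the resulting count tables over (identity × SOA × response ×
category); continuous-rating likelihoods are out of scope.

Two design presets reproduce the experiment arithmetic the package emulates:
`exp1` (11 blocks × 50 trials: 110 trials per SOA, 550 per observer) and
`exp2` (9 blocks × 45 trials: 81 per SOA, 405 per observer). Identities split
each SOA's trials as evenly as possible; with an odd count the `+1` identity
receives the extra trial (a bookkeeping choice — the real experiments
randomized orientation).

## Model families

All families except the last two share the standard equal-variance
signal-detection front end: the identification decision variable is

    δ_id ~ N(S_id · S_s / 2, σ_id),

with one free sensitivity `S_s ≥ 0` per SOA (not constrained monotone in SOA)
and `R_id = +1` iff `δ_id ≥ θ_id`. Under the default *constant* variance
assumption `σ_id = 1`, so `S_s` is the usual d′. Two robustness variants make
the variance *identity-dependent* (`σ_id = r_id^{S_id}`) or *SOA-dependent*
(`σ_id = sqrt(1 + k·S_s²)`), each adding one free parameter.

The graded report compares a report variable `δ_v` against four criteria per
response (a separate set for each `R_id`, as in the SDT rating tradition).
The families differ only in how `δ_v` arises:

| family | report variable | extra parameters |
|---|---|---|
| `sdt` | `δ_v = δ_id` | — |
| `noisy_sdt` | `δ_v ~ N(δ_id, σ_v)` | `σ_v` |
| `wev` | `δ_v ~ N((1−w)·δ_id + w·R_id·(S_s − S̄), σ_v)` | `w, σ_v` |
| `two_channel` | `δ_v ~ N(S_id·S_s·a/2, 1)`, independent of `δ_id` | `a` |
| `postdecisional` | `δ_v ~ N(δ_id + S_id·S_s·b, √b)` | `b` |
| `cnd` | `δ_v ~ N(ρ_SOA·δ_id, σ_v)` | `ρ₁..ρ₅, σ_v` |
| `rce` | winning channel of a two-channel race (below) | — |
| `bayes2d` | posterior probability of the identity (below) | `s, λ` |

The weighted-evidence-and-visibility (WEV) family is the centerpiece: its
report mixes identification evidence with identity-irrelevant
stimulus-strength evidence, `R_id·(S_s − S̄)` with `S̄` the mean sensitivity
across SOAs, weighted by `w ∈ [0, 1]`. This is what lets it predict
strength-graded reports even on incorrect trials. Note the strength term uses
the *response*, not the true identity; the postdecisional family's drift term
uses the true identity — both are implemented exactly as their defining
equations state.

The response-congruent-evidence (`rce`) family replaces the front end with two
identity-specific channels `δ_id− ~ N((1−S_id)·S_s/2 − θ_id, σ_id)` and
`δ_id+ ~ N((1+S_id)·S_s/2 + θ_id, σ_id)`; the larger channel determines the
response and *only the winning channel* informs the rating (`θ_id` here is an
a-priori bias toward `+1`).

The 2D Bayesian family (`bayes2d`) also has two channels, with means
`(1∓S_id)·Δt/2` on the physical SOA axis (milliseconds) and common noise `s`.
The observer computes the posterior probability of identity `+1` under a flat
prior over the five SOAs and both identities, and compares it against nine
increasing criteria in (0, 1) that jointly order the ten (identity ×
category) options from "certainly −1, top visibility" to "certainly +1, top
visibility"; the middle criterion plays the role of the identification
criterion. This option ordering is what reconciles a single criterion set
with the model's 11-parameter count (`s`, lapse `λ`, nine criteria). With
probability `λ` the joint response is replaced by a uniform draw over the ten
options. Because the channel noise `s` is itself free, only the constant
variance mode applies. Criteria live on the (unit-free) posterior axis, so
`s` absorbs the millisecond scale.

### Rating-criteria geometry

For `R_id = +1` the four criteria are strictly increasing in `δ_v`; for
`R_id = −1` the mapping is mirrored (strictly decreasing criteria: more
negative `δ_v` means a higher category). Mirroring is a convention choice —
consistent with the SDT rating tradition in which "more extreme evidence for
the chosen response" means a higher rating. For `rce` the rating variable is
the winning channel itself, which is large whenever its response wins, so
both criteria sets are increasing on that axis and only within-set ordering
is enforced. Criteria are *not* constrained to bracket `θ_id`: for the noisy
families `δ_v` can legitimately cross it; for pure `sdt` the cells on the
wrong side of `θ_id` are structurally zero and the fit pushes criteria onto
the response's half-line on its own.

### Free-parameter counts (5 SOAs, 5 categories, constant variance)

`sdt` and `rce` 14; `noisy_sdt`, `two_channel`, `postdecisional` 15; `wev`
16; `cnd` 20; `bayes2d` 11. The two variance variants add one each. These
counts are computed structurally, never stored.

## Likelihood evaluation

Every family's joint table P(R_id, R_v | S_id, SOA) is computed exactly or to
quadrature accuracy well below the statistical noise of any fit:

- `sdt` and `two_channel`: Gaussian-CDF interval differences (closed form).
- `noisy_sdt`, `wev`, `postdecisional`, `cnd`: the report mean is linear in
  `δ_id`, so (δ_id, δ_v) is bivariate Gaussian and each joint cell is a
  bivariate-normal rectangle probability. These are evaluated through Owen's
  T function, with `sqrt(1 − ρ²)` computed from the exact variance algebra
  (`σ_report_noise / σ_total`) so the degenerate small-noise limit stays
  accurate — the σ_v → 0 reduction onto `sdt` holds to better than 1e-6.
  An earlier quadrature formulation was replaced because no fixed node rule
  handles the near-degenerate limit gracefully.
- `rce`: per rating bin, the winning channel's density times the losing
  channel's CDF, integrated by the probability-space substitution
  `x = μ + σ·Φ⁻¹(p)` with 61-node Gauss–Legendre on the exact per-bin
  probability range (the integrand is smooth and bounded).
- `bayes2d`: the posterior equals `expit(H(δ+) − H(δ−))` where
  `H(x) = logsumexp_t[(x·t − t²/2)/s²]` is strictly increasing, so each
  posterior-criterion band is an *interval* in `δ+` whose endpoints are found
  by inverting `H` (dense-grid monotone interpolation, 4001 points spanning
  ±12 channel standard deviations; clamped extrapolation is safe because the
  conditional CDF saturates there). The joint cell then reduces to a smooth
  one-dimensional integral over `δ−`, evaluated with 61 Gauss–Legendre nodes
  in probability space. This replaces a tensor-grid treatment of the 2-D
  integral, which converges poorly on the discontinuous criterion-band
  indicator.

Probabilities are floored at 1e-10 inside the log-likelihood so structural
zeros meeting stray counts yield large-but-finite penalties. Every predicted
table is validated to sum to 1 ± 1e-6 per condition.

Each family also ships a trial simulator that samples the latent variables
per the defining equations (for `bayes2d`, the posterior is computed by the
literal double sum over SOAs × identities rather than through `H`). The
simulators deliberately share no numerical machinery with the likelihoods, so
the two code paths cross-validate each other; the test suite checks agreement
at 10⁶ trials per condition for every family.

## Fitting

Per participant and family, maximum likelihood on the count table:

1. **Coarse grid.** Starting values are seeded from the data: per-SOA d′
   estimates from hit/false-alarm rates (continuity-corrected) scaled by
   {0.6, 1, 1.4}; the identification criterion from the overall response
   split, offset by {−0.3, 0, +0.3}; rating criteria from the cumulative
   rating frequencies per response mapped through Gaussian quantiles at two
   spread presets; family parameters on small grids (σ_v ∈ {0.5, 1, 2},
   w ∈ {0.25, 0.5, 0.75}, a/b ∈ {0.5, 1, 2}, shared ρ ∈ {0.3, 0.7}, s ∈
   {15, 30, 60, 120} ms, λ ∈ {0.01, 0.05}; `bayes2d` criteria directly from
   the empirical option frequencies). Grids stay in the low hundreds of
   evaluations per family.
2. **Simplex.** The best five grid points (default) each seed a Nelder–Mead
   run (adaptive simplex, capped iterations), and each run is restarted four
   times from its incumbent to escape degenerate simplexes. Optimization is
   performed in an unconstrained parameterization: log for positive
   parameters, logit for unit-interval parameters, base-plus-log-increments
   for ordered criteria, and normalized positive increments for the
   `bayes2d` posterior criteria (a construction that keeps strict
   monotonicity under arbitrary float inputs). The whole procedure is
   deterministic given the data and settings.

AICc (`2·negLL + 2k + 2k(k+1)/(n−k−1)`) and BIC (`2·negLL + k·ln n`) use the
participant's trial count as `n`.

Defaults follow the five-starts/four-restarts procedure shape. Large
simulation studies (the recovery bootstrap) use lighter documented settings
(two starts, one restart, 150 simplex iterations) — a deliberate scaling
choice for bootstrap-sized workloads; both models in a comparison always
receive identical treatment, so the classification question is unaffected.

## Group-level inference

Model comparison works on per-participant AICc/BIC differences. The paired
JZS Bayes factor treats the differences as a one-sample t design with a
Cauchy prior (scale 1 by default) on the standardized effect size
δ = mean/SD; BF₁₀ is computed by integrating the t kernel over the
inverse-gamma mixture representation of the Cauchy prior (a single smooth 1-D
integral). Posterior samples of δ come from dense-grid inverse-CDF sampling
of the noncentral-t × Cauchy posterior (10⁶ samples by default, seeded), and
95% HDIs use the shortest sorted-window interval. The test suite checks the
integrator against an independent quadrature over the effect-size axis.

Information-criterion differences are binned into lower-inclusive bands at
|Δ| = 2, 4, 7 and 10 for histogram-style summaries, and Bayes factors are
labelled on the 1/3/10/30/100 ladder. Both two-sided; a one-sided prior
option was considered and deliberately not implemented — nothing in the
package's own analyses needs it.

## Synthetic data: what it emulates and what it does not

No raw data are deposited with the studies this package models, so all
pipeline stages run on synthetic cohorts. Per observer, parameters are drawn
uniformly from documented ranges chosen once to mimic the masked-orientation
psychometrics: sensitivities jittered (±0.25) around the increasing profile
(0.05, 0.6, 1.6, 2.6, 3.8) — identification near chance at 8.3 ms and near
ceiling at 133.3 ms; θ_id ∈ ±0.2; σ_v ∈ [0.5, 1.5]; w ∈ [0.2, 0.7]; criteria
spread so all five categories are populated. Categorical trials are simulated
from the generative model, then a continuous rating is drawn uniformly within
the chosen category's partition, which makes discretization exactly
invertible (a testing convenience; real rating densities are not uniform
within bins).

The joint generator produces visibility and confidence for the same trials:
one `δ_id` draw per trial, judgment-specific weights `w_vis`, `w_conf`, and
either shared or independently redrawn report noise (whether the two
judgments share their noise is genuinely undecidable from summary data, so
both modes exist; shared is the default in the analysis scripts).

Passing tests on these cohorts show the machinery is correct under the
model's own assumptions. They do not show that real observers satisfy those
assumptions — no sequential dependencies, no reaction-time structure, no
block or learning effects, uniform-within-bin ratings, and exactly balanced
designs are all idealizations.

## Model recovery

The bootstrap resamples parameter sets (with replacement) from a pool — real
fitted parameters when available via the CLI, otherwise a default pool of 12
synthetic draws — simulates each pseudo-observer at nominal design scale
(550 trials), fits the generative family and a competitor, and classifies
each simulated cohort by the paired Bayes factor on AICc/BIC differences at
threshold 3 ("moderate"), with a separate tally at 10 for compelling
evidence. The pool size of 12 is the package's scaled-down cohort (the
bootstrap cost grows linearly in it); the classification logic is
independent of that choice. The headline check: cohorts truly generated by
the response-congruent-evidence model are essentially never classified as
evidence for WEV.

## Numerical conventions and degenerate inputs

- SOA values from files are matched to design levels with absolute tolerance
  1e-6 (condition keying is by index, never by float equality).
- Gamma correlations use the pair-count form (C − D)/(C + D) computed from
  contingency tables by cumulative sums; expected (fractional) frequencies
  use products of cell weights, which is exact. All-tied inputs return NaN
  rather than raising.
- The 20%-threshold dissociation rates condition on strict inequality
  ("below 20%"); ratings exactly at threshold count as not below. Aggregation
  is participant mean first, then grand mean, and participants with empty
  conditioning sets are excluded from that mean (and counted).
- Zero-variance difference vectors raise a degenerate-data error in the
  Bayes factor rather than returning a number.
- All randomness flows through `numpy` Generators seeded from user-supplied
  integers via `SeedSequence` spawning; identical seeds give bit-identical
  cohorts, fits, posterior samples and CSV outputs.

## Problem sizes in the shipped analyses

The numbered scripts under `analysis/` run a 20-observer exp1-scale cohort
(four families fitted), a 12-observer joint cohort, and a 30-simulation
recovery bootstrap; the acceptance script uses 10 observers and 15
simulations; the test suite runs the recovery check at 50 simulations and
parameter recovery at 20 observers. These sizes are the package's choices
for routine reproduction; every stage accepts larger values through its
parameters or CLI flags.

## Known limitations

- Static models only: no sequential-sampling or reaction-time likelihoods.
- The `rce` criteria-versus-bias interaction is only constrained by
  within-set ordering; other identifying conventions are conceivable.
- Nelder–Mead with restarts is robust but not guaranteed global; the grid
  seeding makes gross misconvergence rare at experiment scale, and the
  recovery suites quantify what remains.
- AICc/BIC treat trials as independent, as the models themselves assume.
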