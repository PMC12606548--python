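# Methods

This note records the statistical model behind the package, the defaults
and why they are what they are, the numerical choices that are not visible
from the API, and what the simulation evidence does and does not show.

## Escalation boundary

Stage 1 tests, at each visited dose, H₀: p_T = φ_T (well tolerated)
against H₁: p_T = ρφ_T (overly toxic) from a single cohort of size c.
With equal priors the correct-decision probability of a boundary ψ on the
observed DLT fraction is

P(ψ) = ½·P(p̂_T < ψ | H₀) + ½·P(p̂_T ≥ ψ | H₁),

a step function of ψ whose argmax has the closed form
ψ = log[(1−φ_T)/(1−ρφ_T)] / log[ρ(1−φ_T)/(1−ρφ_T)], always strictly
between φ_T and ρφ_T. `psi_objective` implements the exact binomial
objective with the continue region x ≤ max{x : x/c < ψ}; the test suite
verifies the closed form against a 1000-point grid search for every cohort
size 1–30. Observed fraction exactly equal to ψ stops escalation (the
boundary is irrational for the default parameters, so this matters only
for hand-picked configurations). ρ defaults to 1.4, the conventional
over-toxicity multiplier of interval designs; φ_T defaults to 0.3.

## The walk and the wall

Sub-paths are built as "leftmost remaining column bottom-to-top, then top
remaining row left-to-right", which keeps true toxicity non-decreasing
along the path whenever the truth is row/column-monotone. Clinicians can
supply their own ordered paths via `DesignConfig.subpaths`.

When a dose fails the boundary, every combination dominating it in the
partial order is deemed overly toxic. Untried dominators are excluded
outright. A dominator that passed an *earlier* sub-path on its own
3-patient cohort is demoted too: the partial order outranks a small-sample
pass. This keeps the wall/excluded region upward-closed and the safe set
downward-closed — without the demotion both properties can fail whenever a
wall forms beneath a previously traversed top row. Demoted doses keep
their data, and the stage-2/3 MTD contour (built from much richer pooled
data) may readmit them; only actual walls are permanent.

Stage 1 ends when the matrix is exhausted or the remaining budget cannot
fund a full cohort; doses never reached stay untried and cannot enter A₁
(they have no screening data to randomize on).

## Early-efficacy screen

A Beta(1,1) prior on each dose's response rate gives the posterior
Beta(1+x_E, 1+l−x_E); a dose stays admissible while
Pr(p_E > φ_E | data) > 0.05. With c = 3 the screen cannot fail at stage 1
(the 0/3 tail beyond φ_E = 0.25 is 0.75⁴ ≈ 0.32), which is intentional:
stage 1 screens for *extreme* futility only, and the screen bites at stage
2 once ~9–12 patients accumulate (0/12 gives 0.75¹³ ≈ 0.024 < 0.05).

## Toxicity smoothing and the MTD contour

Per-dose toxicity point estimates are posterior means under a diffuse
Beta(0.05, 0.05) prior (raw proportions via `tox_prior=None`), weighted by
patient counts, and projected onto the cone of matrices non-decreasing in
both coordinates. The projection uses Dykstra's alternating scheme —
row-wise and column-wise weighted PAVA with correction increments,
tolerance 1e-8, capped at 10,000 sweeps — which converges to the exact
weighted least-squares projection onto the intersection of the two
monotone cones; untried cells are masked out. The implementation is
validated against scikit-learn's isotonic regression (1-D case) and an
SLSQP quadratic-program oracle over all pairwise constraints (2-D case).

The row-wise MTD is the non-eliminated dose whose smoothed estimate is
closest to φ_T. Two elimination rules are provided:

* `elimination="posterior"` (default): a dose is eliminated when
  Pr(p_T > φ_T | data) > 0.95 under a Beta(1,1) prior on its raw counts,
  once at least 3 patients have been treated there — the standard safety
  rule of interval-based combination designs.
* `elimination="threshold"`: eliminated when the isotonized estimate
  reaches ρφ_T.

Stage-1 walls are always eliminated. The posterior rule is the default
because it reproduces the reference operating characteristics of the
utility-only comparator in the all-toxic null scenario; the hard threshold
is noticeably more conservative at stage-2 sample sizes.

Ties in |estimate − φ_T| are frequent, not exotic: isotonic pooling
produces exactly equal estimates within a row. Tied estimates below the
target resolve to the *higher* dose (there is still room to escalate),
above the target to the lower dose. Resolving all ties downward cripples
the design — pooled blocks at the top of a safe row would be pruned from
the candidate set for no data-driven reason, and the correct-selection
rate in the two-optimum scenario drops by ~40 points.

## Utility and candidate set

Mean utility uses clinician scores on the four joint (response, DLT)
outcomes, anchored at U₁₀ = 100 and U₀₁ = 0 with defaults U₀₀ = 40,
U₁₁ = 60, normalized to [0, 1]. Because −U₁₀ + U₁₁ + U₀₀ − U₀₁ = 0 for the
defaults, the *true* mean utility depends only on the marginals — the
Gumbel association term cancels — which is what makes the scenario
library's printed utilities exactly recomputable from (p_T, p_E). The
candidate set keeps every admissible dose with Û ≥ γÛ_max; γ = 0.7
balances focusing stage 3 against keeping survival contenders alive.

## Survival selection

Simulated progression times are fully observed to the window τ, so each
patient contributes min(T, τ) with an event flag T ≤ τ; the Kaplan–Meier
product-limit estimate at τ then reduces to the empirical fraction
surviving past τ. The general estimator (validated against lifelines)
handles pre-τ censoring, which occurs in conduct mode with real follow-up
data. Survival beyond the landmark means strictly greater than τ. The
final selection is the KM argmax over C₃ with ties broken by higher
estimated utility, then lower j+k, then lower j; Go requires the estimate
to strictly exceed φ_S.

## Generative model

Joint binary outcomes follow the Gumbel-type bivariate Bernoulli model:
π(a,b) = marginal product + (−1)^(a+b)·p_E(1−p_E)p_T(1−p_T)·(e^φ−1)/(e^φ+1),
with association φ = 0.5 throughout the built-in scenarios; marginals are
recovered exactly for any φ. Survival is Weibull with scale calibrated per
dose so that S(τ) equals the scenario's landmark PFS probability. The
Weibull shape defaults to 1 (exponential): because the design consumes
survival only through the landmark indicator under complete τ-follow-up,
the shape is inert for the shipped scenarios, and it is exposed for
sensitivity work (e.g., accrual-censoring extensions). Survival is drawn
independently of the early outcomes given dose; no dependence structure is
asserted between response and progression beyond what the dose-level
marginals impose.

What the generator does *not* emulate: staggered accrual and accrual
suspension (early outcomes are available at cohort completion), patient
covariates or cohort drift, time-to-toxicity, and within-patient
correlation between response and progression time. Operating
characteristics computed here therefore speak to the design's decision
logic under clean homogeneous accrual, not to calendar-time trial
duration.

## Replication machinery

Each replicate derives its generator from `SeedSequence([master, rep])`
split into three per-stage streams, so (a) results are bitwise identical
across serial and parallel execution, and (b) design variants compared on
the same master seed consume identical stage-1 random numbers, making
paired contrasts (e.g., Great Wall minus CONV1) common-random-number
comparisons. Reference runs use 10,000 replicates (Monte-Carlo SE of a
percentage ≤ 0.5 points); the test suite uses 2,000 with tolerances
widened by three SEs.

## Known limitations

* CONV1's no-selection rule is "any admissible set empty"; it has no
  survival futility gate by construction, so its null-scenario behaviour
  is driven entirely by the toxicity/efficacy screens.
* Conduct mode treats recorded stage-1 follow-up times as event times
  unless they exceed τ (pre-τ censoring is honoured from stage 2 records,
  where survival actually informs decisions).
* The design assumes outcome homogeneity across stages; the
  `collect_stage1_efficacy=False` switch discards stage-1 response data
  when that assumption is doubtful, but there is no formal drift
  adjustment.
* Grids larger than the shipped 2×3 scenarios are fully supported by the
  machinery, but the shipped defaults (n₁ = 18 etc.) are sized for 2×3;
  re-tune sample sizes before trusting operating characteristics on 4×5.
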