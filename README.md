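# greatwall

A simulator and decision engine for the **Great Wall design**: a three-stage
phase I–II dose-optimization design for two-drug combination trials that
selects the dose combination maximizing *survival* benefit, not just early
response.

Most phase I–II designs pick an "optimal biological dose" from early
toxicity/response data and hope it also maximizes long-term benefit. When
early response is a poor surrogate for progression-free survival (common
with immunotherapies and targeted agents), that bet fails. This package is
for trial statisticians who want to (a) evaluate the design's operating
characteristics by simulation before running a trial, and (b) drive a live
trial decision-by-decision ("conduct mode").

## The design

Doses of drugs A and B form a J×K matrix with a *partial* toxicity order:
toxicity is non-decreasing along rows and columns, but off-diagonal pairs
are incomparable.

**Stage 1 — divide-and-conquer escalation.** The matrix is split into
totally ordered sub-paths (leftmost remaining column, then top remaining
row). One cohort (default c = 3) is treated per dose; escalation continues
while the observed DLT fraction p̂<sub>T</sub> stays below the boundary

ψ = log[(1−φ_T)/(1−ρφ_T)] / log[ρ(1−φ_T)/(1−ρφ_T)],

which maximizes the equal-prior correct-decision probability for
H₀: p_T = φ_T against H₁: p_T = ρφ_T (defaults φ_T = 0.3, ρ = 1.4, so
ψ ≈ 0.3585). When a dose fails, a "wall" is built there: the dose and its
entire upward cone are deemed overly toxic, and the search resumes on the
next sub-path. The walls link into the *Great Wall*; everything below it,
screened by a Beta-posterior early-efficacy test
Pr(p_E > φ_E | data) > 0.05, forms the admissible set A₁.

**Stage 2 — randomize and refine.** n₂ patients are equally randomized over
A₁. Pooled toxicity estimates are smoothed by matrix (bimonotone) isotonic
regression, a row-wise MTD contour is drawn (estimate closest to φ_T, with
a posterior safety-elimination rule), and the admissible set is re-screened
for efficacy. Each dose's mean utility

Ū(d) = Σ U(a,b) π(a,b | d) / 100,  U = (U₁₀, U₁₁, U₀₀, U₀₁) = (100, 60, 40, 0)

balances response against toxicity; the candidate set C₂ keeps every dose
with Û ≥ γ·Û_max (default γ = 0.7).

**Stage 3 — survival selection.** n₃ more patients are randomized over C₂;
all patients ever treated at C₂ doses are followed for τ = 6 months. After
a final MTD-contour pruning (C₃), the optimal dose combination is
argmax over C₃ of the Kaplan–Meier landmark estimate ψ̂_S(d), with a
**Go/No-Go** gate: Go iff ψ̂_S(d̂) > φ_S (default 0.3).

Two comparator variants share stage 1: **conv1** (stages 1–2 with the full
n₂+n₃ budget, selecting the utility argmax — no survival data) and
**greatwall-m** (skips stage 2, randomizing n₂+n₃ over A₁ directly).

## Worked example

Eight built-in 2×3 scenarios (true DLT, response, and 6-month PFS
probabilities per dose) ship with the package. Scenario 5 is the
interesting misalignment case: A2B2 has the best mean utility (0.68) but
A2B1 has the best 6-month PFS (0.45).

```bash
greatwall oc --scenario 5 --reps 2000 --seed 1 --designs greatwall,conv1
```

```
dose  sel_pct  pat_pct   scenario   variant  mean_n
A2B1    57.05    21.61 scenario-5 greatwall   71.32
A2B2     9.60    20.73 scenario-5 greatwall   71.32
A2B3     2.65     7.26 scenario-5 greatwall   71.32
A1B1     1.00    19.81 scenario-5 greatwall   71.32
A1B2     5.90    19.49 scenario-5 greatwall   71.32
A1B3     6.05    11.11 scenario-5 greatwall   71.32
none    17.75     0.00 scenario-5 greatwall   71.32
A2B1    22.20    20.37 scenario-5     conv1   71.34
A2B2    57.05    16.81 scenario-5     conv1   71.34
...
[greatwall] no-selection 17.8% mean n 71.3 correct-ODC 57.0%
[conv1] no-selection 3.0% mean n 71.3 correct-ODC 22.2%
```

`sel_pct` is the share of simulated trials selecting that dose as the final
optimal dose combination, `pat_pct` the share of patients treated there,
and `mean_n` the average total sample size (maximum 18+36+20 = 74). The
survival stage raises correct selection of A2B1 from 22% (utility-only
CONV1, which chases A2B2) to 57%.

Single-trial and conduct modes:

```bash
greatwall run --scenario 8 --seed 3 --out result.json
greatwall conduct --data patients.csv --rows 2 --cols 3
```

`conduct` replays a patient-level CSV (`patient_id, stage, j, k, y_tox,
y_eff, time_days, event`) and prints the next recommended action (treat a
cohort, randomize, terminate, or select with Go/No-Go).

Everything is also available as a library:

```python
import greatwall as gw

cfg = gw.DesignConfig()                      # all defaults shown above
sc = gw.scenario_library()[5]
summary = gw.simulate_oc(sc, cfg, n_reps=10_000, seed=1)
print(summary.sel((2, 1)), summary.nosel_pct, summary.mean_n)
```

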