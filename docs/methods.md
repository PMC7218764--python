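# Methods

## Model structure

The model is a closed-cohort Markov state-transition model with annual
cycles. A cohort of 1,000 children enters at age 11 and is followed for
30 cycles. The canonical state space has fifteen states, identified by
the single letters of the cost table:

| id | state | annual cost (2017 USD) |
|----|-------|------------------------|
| A | No RHD | 0 |
| B | Undiagnosed asymptomatic borderline RHD | 0 |
| C | Untreated asymptomatic definite RHD | 0 |
| D | Untreated mild clinical RHD | 0 |
| E | Untreated severe clinical RHD | 0 |
| F | Diagnosed borderline RHD | 25.84 |
| G | Treated asymptomatic definite RHD | 93.93 |
| H | Treated mild clinical RHD | 337.47 |
| I | Treated severe clinical RHD | 854.00 |
| RG/RH/RI | Resolved RHD (from G/H/I) | 93.93 / 337.47 / 854.00 |
| K | Post surgery | 854.00 |
| X | Surgery (tunnel) | 4,120.51 |
| Z | Death | 0 |

On the state count: the primary study's abstract describes a 13-state
model while its cost table prices fifteen states (three "resolved"
states are listed separately). The engine is state-space-agnostic; the
canonical bundle uses the fifteen costed states because costs exist for
all of them. Surgery is a tunnel state (self-transition forced to zero):
an operation takes one cycle, after which survivors are post-surgical.
Death is absorbing and reachable from every state.

The permitted edges (shipped as an allowed-edge list and enforced at
bundle validation) encode: regression of latent disease to normal;
progression borderline→definite→mild→severe; care-seeking from untreated
clinical states into their treated counterparts; resolution of treated
disease under prophylaxis; surgery from definite/clinical/post-surgical
states; and death from everywhere. The published model diagram is not
reproduced in text form anywhere public, so this edge list is the
package's own transcription of the described disease course; users can
supply their own list per bundle.

## Strategies

Both arms share one transition matrix. Secondary prophylaxis enters as a
multiplicative hazard reduction on the *treated* rows — treated
definite→clinical/surgery progression × (1 − 0.50) and treated
mild→severe × (1 − 0.50) in the base case — with the freed probability
mass returned to the self-transition, so treated and untreated rows
differ exactly by the prophylaxis effect. Strategies then differ only at
cycle 0:

- **Standard care**: the enrolment distribution as observed; no one-time
  costs.
- **Screening**: of screened occupants of B, a fraction
  `sensitivity_borderline` moves to F; of screened occupants of C,
  `sensitivity_definite` moves to G. Scans cost
  `cohort × screened_fraction × $6.60` at cycle 0. Disease-free screened
  children test falsely positive with probability `1 − specificity` and
  incur a one-time follow-up cost while remaining disease-free.

Borderline detections deliberately go to the *diagnosed borderline*
state rather than a treated arm: borderline follow-up is costed
separately and carries a "disutility of knowing" as a small disability
weight on F. Screening is strictly one-time; repeat rounds are out of
scope.

## Outcomes and discounting

Costs and years lived with disability (YLD) accrue end-of-cycle by
default: the state occupied during cycle *t* is trace row *t*,
discounted by (1.03)^−t; a begin-of-cycle switch exists
(`cycle_accrual`). The half-cycle correction is off by default; when
enabled (`half_cycle_correction`), occupancy flows are integrated by the
trapezoid rule over cycle boundaries 0..n, the usual compromise between
the begin and end conventions. One-time screening costs sit at cycle 0
undiscounted.

Years of life lost (YLL) for the `d_t = z_t − z_{t−1}` new deaths of
cycle *t* (valid because death is absorbing) use the remaining life
expectancy at the attained age, linearly interpolated from the bundle's
life table. Two conventions are implemented (`yll_mode`):

- `stream` (default): the expectancy is paid out as whole life-years
  starting the year after death, each discounted to time 0, the
  fractional final year pro-rated — the usual discounted-YLL treatment;
- `lump`: the undiscounted expectancy discounted once at the death
  cycle.

DALYs = YLD + YLL; the effectiveness axis is DALYs *averted*
(comparator − intervention). ICER = ΔC/ΔE when ΔE > 0; dominance labels
replace the ratio when the signs make it meaningless; NMB = λΔE − ΔC
with λ = $25,949.85 per DALY averted.

## Uncertainty

Probabilistic sensitivity analysis redraws, per iteration: every
transition probability from its descriptor (beta with the point estimate
as mean and effective sample size 100 by default), every positive state
cost from a gamma matched to (mean, variance), and every disability
weight from a triangular distribution on its 95% uncertainty interval.
All state costs share one variance — the surgery state's, the only state
with primary variance data — unless a state carries its own descriptor.
Sampled rows are repaired minimally: draws clip to [0, 1], a row whose
outgoing mass exceeds 1 is rescaled (the self-loop takes the remainder),
and tunnel rows renormalise to exactly 1. Iterations that still cannot
form a valid matrix are redrawn (cap 100, counted and reported). The
CEAC reports, along a threshold grid (default 0 to 2λ in 200 steps), the
fraction of iterations with positive NMB.

One-way analysis sweeps each registered parameter between bounds with
everything else at base: transitions and costs at the 95% interval
implied by their descriptors (transition highs capped at the row's
stochastic headroom), disability weights at their intervals, the
discount rate over 0–5%, screening sensitivities over 80–100% (definite)
and 50–80% (borderline), the definite-prophylaxis effect from none to
its base 50%, and the clinical-prophylaxis effect over 25–75%. Sweeping
an edge out of the surgery tunnel redistributes the complement over the
row's other edges in base proportions (survivors go to post-surgery).
Rows are ordered by |ICER(high) − ICER(low)|.

## Synthetic parameter bundles

The primary transition-probability, disability-weight, life-table and
enrolment-distribution estimates for the Brazilian evaluation are not
publicly printed; the package therefore generates complete bundles that are
*structurally* faithful — same topology, same invariants, same
distribution families — without claiming numeric fidelity to any
published estimate. Generator choices (all documented in
`rhdcea/synthetic.py` and overridable):

- transition probabilities drawn once per bundle from broad uniform
  ranges chosen to be clinically plausible for an endemic school-age
  cohort (e.g. background mortality 0.05–0.2%/yr, borderline regression
  10–30%/yr, definite→mild progression 4–12%/yr, peri-operative
  mortality 3–8%); treated rows copy their untreated analogues before
  the prophylaxis reduction is applied;
- latent-RHD enrolment prevalence 4.2%, split 3:1
  borderline:definite (screening-literature-typical, marked synthetic);
- disability weights in GBD style: zero for unaware latent disease,
  0.012 (0.006–0.018) for the diagnosed-borderline "disutility of
  knowing", 0.049/0.233 for mild/severe clinical disease, 0.324 for the
  surgery year;
- a linear life table (70 years at birth, −0.78 years of remaining
  expectancy per year of age), a plausible stand-in for a
  socioeconomically disadvantaged urban Brazilian cohort;
- baseline screening characteristics at the midpoints of the one-way
  ranges: sensitivity 0.65 (borderline), 0.90 (definite), specificity
  0.95; false-positive follow-up costed at one year of
  diagnosed-borderline care ($25.84);
- shared cost variance from a 30% coefficient of variation on the
  surgery cost.

What the generator does **not** emulate: age-dependence of transitions,
correlation between parameters, adherence dynamics beyond the scalar
prophylaxis effect, and the real study's estimated transition values.
Passing tests on generated bundles therefore demonstrate correctness of
the machinery (conservation laws, closed forms, decision identities,
sampler calibration, reproducibility) — not agreement of absolute
outputs with any real population. Under the default synthetic dynamics
screening is dominant (cost-saving); with its own primary estimates
the published evaluation found screening costlier but cost-effective
(ICER ≈ $10,148/DALY averted), and the package reproduces that ICER
from the published totals as an arithmetic consistency check.

The three-state toy bundle (Healthy/Sick/Dead, everyone initially sick)
exists purely for verification: with zero mortality its discounted
totals are geometric series, checked against the engine to 1e-9.

## Numerical choices

- Row-stochasticity enforced to 1e-9 on input and renormalised exactly;
  trace mass conservation asserted to 1e-9 per cycle.
- Monetary values are floats carrying the 2-decimal USD inputs at full
  precision internally; reports round to 2 decimals.
- Bundle CSV round-trips use `repr` serialisation and round-trip float
  parsing, so save→load is the identity.
- Degenerate descriptors (zero variance/width) short-circuit sampling so
  an all-point PSA reproduces the deterministic run bit-for-bit.
- Problem sizes in the shipped analyses: 10,000 PSA iterations in the
  acceptance script (a 200-iteration PSA is already stable to ~3
  percentage points); property tests use 50 hypothesis examples and
  1e5-draw sampler-moment checks.

## Known limitations

- Cohort proportions only; no microsimulation, so no individual history
  dependence (beyond the surgery tunnel) or overtaking of the
  memoryless assumption.
- Cycle-constant transition matrix in the base model (the engine accepts
  per-cycle matrices, unused by the shipped bundles).
- Screening is a single round at enrolment; confirmatory-echo cascades
  and programme administration costs are not modelled separately.
- QALYs are unsupported by design; outcomes are DALY-based throughout.
- No expected-value-of-perfect-information analysis.
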