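# Methods

This note documents the model implemented by `htncea`, the conventions and
assumptions behind its bundled configuration, and what its synthetic inputs
do and do not establish about real populations.

## State space and cycle structure

The cohort is tracked over `disease × complication × vital` states: four
blood-pressure states (normal, pre-hypertension, stage I, stage II) crossed
with the eight subsets of {AMI, stroke, ESRD} while alive, plus one
absorbing dead state. One cycle is one year. Within a cycle the update
order is fixed:

1. disease-state transition (4×4 row-stochastic matrix; permitted moves are
   normal→pre, pre→normal, pre→stage I, stage I→stage II);
2. complication events, drawn per current disease state with independent
   annual hazards — joint events arise as products of the marginal
   probabilities, which is what generates the combined complication nodes;
3. immediate case fatality applied to incident events (for simultaneous
   events, survival probabilities multiply);
4. annual mortality applied to carriers whose complications predate the
   cycle.

Complications persist for life; disease-state transitions continue
unchanged after a complication. There is no background (non-complication)
mortality — life-years lost therefore reflect the modelled complications
only, consistent with a model whose purpose is to compare prevention
strategies against those complications.

**Counting convention.** No half-cycle correction is applied. Costs and
utilities are evaluated on the end-of-cycle occupancy for cycles 1..T;
cycle 0 carries the initial distribution and zero flows. With a unit
utility stream this yields exactly the T-year annuity factor
Σ₁ᵀ (1+r)^(−t) (≈ 14.877 at r = 3 %, T = 20), which the test suite checks
in closed form. The convention is simple, auditable, and switchable in
principle (a half-cycle variant would average adjacent occupancies); it was
chosen because the effect on *incremental* comparisons, which are
differences of identically-counted arms, is second-order.

## Parameters

Every input is a `Param`: a base-case value plus an uncertainty
distribution (Beta for probabilities, Triangular for costs and the discount
rate, point mass otherwise). Conventions:

- **Base-case vs distribution.** The base-case run uses the printed
  base-case value even where it is inconsistent with the printed
  distribution's mean (e.g. the ESRD stage II hazard 0.001716 vs
  Beta(462, 4538), mean 0.0924); the PSA samples the printed distribution.
  Both columns are followed literally rather than silently reconciled.
- **Presets.** Two published sources of the base-case complication hazards
  disagree (tabulated values vs narrative annual rates). Both ship:
  `table1` (default) and `section24`
  (`load_parameters(path, preset="section24")`).
- **Costs.** Cost items carry only triangular distributions; their
  base-case value defaults to the mode (the "most likely" value). One
  published triple (hypertension visit cost, printed as 45/40/54) violates
  low ≤ mode ≤ high and is encoded re-ordered as (40, 45, 54).
- **ESRD mortality.** A single published case fatality of 0.30 is encoded
  as the *annual* mortality of ESRD carriers with zero immediate (acute)
  fatality: renal failure kills through ongoing disease, not an index
  event.
- **Assumption-flagged inputs.** The four natural-history transition
  probabilities, the initial state distribution, and all utility weights
  are not published (the underlying cohort estimates are not public). The
  bundled config carries documented placeholders flagged `assumption: true`
  and the CLI audit log tags them on every validation:
  transitions 0.08 / 0.06 / 0.05 per year (normal→pre, pre→I, I→II) with
  regression 0.10 per year; initial prevalence 50/30/15/5 %; state utility
  weights 1.00 / 0.97 / 0.93 / 0.88 with complication multipliers
  AMI 0.76, stroke 0.63, ESRD 0.54 (catalogue-typical magnitudes). A
  complication combination's weight is the product of its multipliers
  (configurable alternative: minimum). Because of these placeholders the
  bundled configuration's absolute totals are *illustrative*: they
  exercise the full pipeline but do not reproduce any published table.
- **Care utilisation.** Per-visit and per-admission unit costs are turned
  into annual state costs by documented utilisation assumptions
  (`care_model` block): 4 follow-up visits/yr for MI and stroke carriers,
  2 and 4 hypertension visits/yr for stage I/II, annual admission
  probabilities 0.01/0.05 for stage I/II. ESRD carriers incur the annual
  ESRD cost from the event year onward. Terminal care is charged once, in
  the cycle of death.

**Sampling.** `sample_parameter_set` draws every distributed parameter with
a counter-based (Philox) generator keyed by the seed, so identical seeds
give identical parameter sets across platforms. Beta draws are probabilities
by construction and triangular draws cannot leave their support, so no
truncation is needed; the only reachable invalidity is the shared
multinomial row of the pre-hypertension state (progression + regression
> 1), which is renormalised to sum 1 with a runtime warning.

## Interventions

A strategy maps each (state, risk-group) pair to bundles drawn from:
lifestyle modification at three intensities, screening/awareness,
regular/advanced checkups (cost-only add-ons), and a prophylactic drug.
Defaults:

| strategy | assignment |
|---|---|
| usual care | nothing (baseline clinical care only) |
| population-wide | mid-intensity lifestyle to every state below stage II |
| high-risk | drug + education to stage I and II (threshold rule) |
| personalized | low risk: screening + low lifestyle; mid: mid lifestyle + regular checkup; high: full lifestyle + drug + advanced checkup; stage II: drug in every group |

All assignments are overridable through the `strategies` config block; the
published source shows the personalized grid only as a risk-colour figure,
so the default escalation is this package's design choice.

**Efficacy.** The achievable systolic reduction is state-specific
(7 mm Hg in pre-hypertension, 16 in stage I, 19.5 in stage II; the normal
state is assumed to match pre-hypertension — no figure is published).
Diastolic figures are carried but unused. ΔSBP maps to a hazard ratio by
`HR = 2^(−ΔSBP/20)` — the log-linear risk-halving per 20 mm Hg systolic,
the standard reading of the prospective-collaboration evidence, applied
identically to progression and complication hazards. Compliance (60 %
lifestyle, 70 % screening, 50 % medication) acts as an all-or-nothing
population mixture, `HR_eff = c·HR + (1 − c)`, not a partial-effect scaler.
Per state at most one awareness-type effect and one drug effect apply
(extra bundles add cost, not additional blood-pressure lowering); their
effective ratios multiply. The modified probability is
`p' = 1 − (1−p)^HR_eff` — scaling on the rate scale, which keeps
probabilities valid for any multiplier. Two deliberate asymmetries: the
pre→normal regression rate is never boosted by interventions or risk scores
(its covariate and treatment dependence is unstated; configurable for the
risk score via `modify_regression`), and awareness-type bundles have no
effect in stage II, where only drug treatment lowers blood pressure.

**Costs of intervention.** Bundle costs are programme costs: charged
annually to every targeted alive person regardless of compliance. (The
alternative — charging compliers only — would make a zero-compliance
programme free; the programme-cost convention keeps the null-efficacy limit
"same outcomes, added cost".)

## Risk scores and stratification

The state-specific risk score is log-linear, `η = β₀ + βᵀx`, and multiplies
progression rates by `exp(η)` on the rate scale — the proportional-hazards
convention of multistate regression models. No fitting machinery is
included: weights are config inputs. The default synthetic covariates are
standardised age and BMI (normal), sex and smoking (Bernoulli) with
illustrative weights (0.30, 0.25, 0.20, 0.40) and an intercept (−0.22)
centring the mean score at zero so that the average-risk group tracks the
base-case natural history. Risk groups are score tertiles by default
(matching a three-colour risk grid); explicit cutoffs are configurable.
Group-level simulation uses each tertile's mean score — a first-order
approximation to integrating over the within-group score distribution;
since `exp` is convex this slightly understates the population-average
progression (Jensen), an error shared by all strategy arms and therefore
largely differenced out of increments.

## Probabilistic sensitivity analysis

Each replicate r draws one parameter set with a Philox generator keyed by
(master seed, r) and evaluates *all* strategies on that draw (common random
numbers, so increment variance is not inflated by between-replicate
parameter noise). The risk-group structure is held fixed across replicates:
sampled uncertainty covers the published parameter distributions, not the
synthetic covariate model. Defaults: 10,000 replicates; willingness-to-pay
grid 0–300,000 USD/QALY in 10,000-USD steps. The CEAC counts exact NMB ties
as one half, making a two-way comparison's curves sum to one. The
acceptance script uses 2,000 replicates (Monte-Carlo standard error of a
CEAC value ≤ 0.5/√2000 ≈ 0.011) and 10,000 synthetic profiles; the test
suite uses smaller sizes chosen so each assertion's tolerance dominates its
Monte-Carlo error (4 standard errors for mean-recovery checks).

## Synthetic data: what it does and does not show

The synthetic module generates everything the pipeline consumes: covariate
profiles with *known* score structure, tertile groups, and toy parameter
sets with closed-form behaviour (frozen cohort; single-transition geometric
chain, occupancy 1 − (1−p)^t; single-complication model, first-cycle deaths
h·m) that serve as independent oracles for the engine. Passing tests
therefore establish that the machinery is arithmetically correct and
self-consistent — mass conservation, closed-form equivalence, analytic
distribution means, reproducibility — not that the bundled parameter values
describe any real cohort. The generator makes no attempt to imitate real
covariate distributions or their correlations (covariates are independent),
and the true score weights it embeds are the same weights the risk model
uses, so stratification recovery is exact by construction rather than an
estimation result.

## Numerical choices

- Engine state update is exact expectation propagation (deterministic
  cohort); no microsimulation noise. Stochasticity enters only through
  parameter sampling in the PSA.
- Mass conservation is asserted every cycle at 1e-9; toy-model oracle
  equivalence holds at 1e-12.
- ICURs are reported to the nearest USD and QALYs to 4 decimals in tables
  (raw floats are available with `rounded=False`). A negative ICUR is
  reported verbatim alongside its dominance flag; it is not a price.
- Quadrant tie-breaks: boundary increments fall into trade-off quadrants,
  (0, 0) north-east by convention; ICUR is undefined (raises) at
  ΔQALY = 0.
- A unit hazard-ratio multiplier is an exact no-op (avoiding the
  floating-point drift of `1 − (1−p)^1`).

## Limitations

- The unpublished inputs (transitions, prevalence, utilities) make the
  bundled configuration's absolute costs and QALYs illustrative; published
  headline totals are used only as inputs to the incremental arithmetic,
  which the economics module reproduces exactly.
- Only three complications are modelled; omitted sequelae (retinopathy,
  peripheral arterial disease) bias against prevention.
- No background mortality, no age structure: the cohort is homogeneous
  apart from the risk score, and hazards are constant within state over the
  horizon.
- No adverse drug events, treatment switching, or efficacy waning; no
  extended-dominance league tables (comparisons are pairwise against a
  single comparator).
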