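# htncea

Cost-utility analysis of personalized hypertension prevention with a
four-state Markov cohort model.

`htncea` is for health-economics and epidemiology researchers who want to
compare hypertension prevention strategies — usual care, population-wide
lifestyle modification, a high-risk (threshold) approach, and risk-guided
personalized prevention — on cost and quality-adjusted life years, with full
probabilistic sensitivity analysis.

## The model

**Natural history.** A closed cohort moves yearly through four
blood-pressure states — normal, pre-hypertension, stage I, stage II — with
annual progression probabilities `p(normal→pre)`, `p(pre→I)`, `p(I→II)` and
a single regression probability `p(pre→normal)`; regression past stage I is
structurally impossible and stage II is absorbing within the disease space.

**Complications and death.** Each state carries annual hazards of three
end-organ complications — acute myocardial infarction (AMI), stroke,
end-stage renal disease (ESRD) — acting independently within a cycle, which
generates the seven combined complication nodes (AMI, stroke, ESRD and their
joint occurrences). Incident events face an immediate case fatality;
prevalent carriers an annual mortality. Complications persist for life.

**Economics.** Discounted costs (event admissions, chronic care, programme
costs) and QALYs (state weights times complication multipliers) accumulate
at cycle end over a 20-year horizon at a 3 %/yr discount rate. Strategies
are compared by incremental cost-utility ratio
`ICUR = Δcost / ΔQALY` and net monetary benefit `NMB(λ) = λ·QALY − cost`.

**Interventions.** A strategy maps each (state, risk group) pair to
intervention bundles. A bundle's achievable systolic reduction ΔSBP becomes
a hazard ratio via the log-linear relation `HR = 2^(−ΔSBP/20)` (risk halves
per 20 mm Hg), diluted by all-or-nothing compliance,
`HR_eff = c·HR + (1−c)`, and applied on the rate scale,
`p' = 1 − (1−p)^HR_eff`, to the state's progression and complication
hazards. Awareness-type interventions cannot lower blood pressure in
clinically overt stage II disease; drug treatment can.

**Personalization.** A log-linear risk score `η = β₀ + βᵀx` over individual
covariates multiplies progression rates by `exp(η)`. The score distribution
is split at tertiles into low/mid/high risk groups, which receive escalating
bundles under the personalized strategy.

**Uncertainty.** Every distributed parameter (Beta for probabilities,
Triangular for costs and the discount rate) is redrawn per Monte-Carlo
replicate; all strategies share each draw. Outputs are the
cost-effectiveness plane scatter of (ΔQALY, Δcost) and cost-effectiveness
acceptability curves, `P(strategy has the highest NMB at λ)` over a
willingness-to-pay grid.

## Worked example

Run all four strategies on the bundled base-case configuration (its
unpublished inputs — transition probabilities, initial prevalence, utility
weights — are documented assumptions, flagged in the config):

```sh
htncea run --strategy all --seed 1 --out results
```

prints

```
       strategy  cost     qaly increment_cost increment_qaly  icur     quadrant
     usual_care  1714  13.8735           None           None  None
population_wide  9173  13.9797           7459         0.1062 70249 trade_off_ne
      high_risk  2450  13.9851            736         0.1115  6600 trade_off_ne
   personalized 14556  14.0298          12842         0.1563 82183 trade_off_ne
```

Read: under usual care the average cohort member accrues 13.87 discounted
QALYs and USD 1,714 of discounted cost over 20 years. Every active strategy
gains QALYs (e.g. +0.1115 for the high-risk approach); all three land in the
north-east quadrant (more effective, more costly) under the bundled
assumptions, the high-risk approach being the cheapest per QALY gained
(ICUR ≈ USD 6,600/QALY). A `results/manifest.json` makes the run
reproducible bit for bit.

The same in Python:

```python
import htncea as h

ps = h.load_default_parameters()                      # bundled base case
profiles = h.generate_profiles(h.SyntheticCohortSpec(n=10_000, seed=1))
_, groups = h.make_risk_groups(profiles)              # tertile risk groups
strategies = list(h.default_strategies().values())
results = h.evaluate_strategies(ps, strategies, groups)
print(h.comparison_table(results))

psa = h.run_psa(ps, strategies, n=10_000, seed=1, groups=groups)
ceac = h.compute_ceac(psa)                            # acceptability curves
```

Other subcommands: `htncea validate` (config check with parameter
provenance), `htncea psa` (CE-plane scatter and CEAC, optional plots),
`htncea cea` (comparison table from computed or supplied totals),
`htncea synth` (synthetic profiles and oracle toy configurations).

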