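# Bundled base-case configuration for the hypertension prevention
# cost-utility model.  Published estimates carry a `source` tag; inputs the
# source literature does not print (the four natural-history transition
# probabilities, the initial state distribution, utility weights, care
# utilisation and the risk-score model) are modelling assumptions and are
# flagged `assumption: true`.  All costs USD, all rates per year.

transition:
  # Annual natural-history transition probabilities.  The published model
  # cites cohort-estimated values that are not printed; these placeholders
  # are plausible community-cohort magnitudes.
  normal_to_pre:    {value: 0.08, dist: {beta: [80, 920]},  assumption: true}
  pre_to_stage1:    {value: 0.06, dist: {beta: [60, 940]},  assumption: true}
  stage1_to_stage2: {value: 0.05, dist: {beta: [50, 950]},  assumption: true}
  pre_to_normal:    {value: 0.10, dist: {beta: [100, 900]}, assumption: true}

hazards:
  ami:
    normal:  {value: 0.003,    dist: {beta: [30, 9970]}, source: literature}
    pre:     {value: 0.003748, dist: {beta: [32, 9968]}, source: literature}
    stage1:  {value: 0.00633,  dist: {beta: [68, 9932]}, source: literature}
    stage2:  {value: 0.008737, dist: {beta: [95, 9905]}, source: literature}
    mortality_immediate: {value: 0.15,   dist: {beta: [15, 85]},    source: literature}
    mortality_yearly:    {value: 0.0311, dist: {beta: [311, 9689]}, source: literature}
  stroke:
    normal:  {value: 0.00075,  dist: {beta: [7.5, 9992.5]},   source: literature}
    pre:     {value: 0.000937, dist: {beta: [9.37, 9990.63]}, source: literature}
    stage1:  {value: 0.001675, dist: {beta: [18, 9982]},      source: literature}
    stage2:  {value: 0.00333,  dist: {beta: [72, 9928]},      source: literature}
    mortality_immediate: {value: 0.19,   dist: {beta: [19, 81]},    source: literature}
    mortality_yearly:    {value: 0.0201, dist: {beta: [201, 9799]}, source: literature}
  esrd:
    normal:  {value: 0.000075,  dist: {beta: [0.75, 9999.25]}, source: literature}
    pre:     {value: 0.0000937, dist: {beta: [20, 9980]},      source: literature}
    stage1:  {value: 0.001213,  dist: {beta: [321, 9679]},     source: literature}
    stage2:  {value: 0.001716,  dist: {beta: [462, 4538]},     source: literature}
    # A single renal-failure case fatality of 0.30 is published; it is
    # modelled as an annual mortality of carriers, with no acute-event death.
    mortality_immediate: {value: 0.0, assumption: true}
    mortality_yearly:    {value: 0.30, source: literature}

costs:
  mi_admission:     {dist: {triangular: [2706, 3006, 3068]}, source: NHI Taiwan}
  mi_visit:         {dist: {triangular: [50, 55, 66]},       source: NHI Taiwan}
  stroke_admission: {dist: {triangular: [1027, 1141, 1370]}, source: NHI Taiwan}
  stroke_visit:     {dist: {triangular: [54, 59, 71]},       source: NHI Taiwan}
  esrd_annual:      {dist: {triangular: [18000, 20000, 24000]}, source: NHI Taiwan}
  htn_admission:    {dist: {triangular: [583, 647, 777]},    source: NHI Taiwan}
  # published triple reordered to satisfy low <= mode <= high
  htn_visit:        {dist: {triangular: [40, 45, 54]},       source: NHI Taiwan}
  lifestyle_low:    {dist: {triangular: [300, 450, 600]},    source: NHI Taiwan}
  lifestyle_mid:    {dist: {triangular: [300, 600, 900]},    source: NHI Taiwan}
  lifestyle_full:   {dist: {triangular: [900, 1200, 1500]},  source: NHI Taiwan}
  checkup_advanced: {dist: {triangular: [300, 400, 500]},    source: NHI Taiwan}
  checkup_regular:  {dist: {triangular: [100, 200, 300]},    source: NHI Taiwan}
  screening:        {dist: {triangular: [40, 80, 120]},      source: NHI Taiwan}
  terminal_care:    {dist: {triangular: [2000, 5000, 10000]}, source: NHI Taiwan}
  drug:             {dist: {triangular: [60, 120, 180]},     source: NHI Taiwan}

utilities:
  # QALY weights are not published for this model; assumed values follow
  # common catalogue magnitudes.  Complication entries are multipliers on the
  # state weight; combinations multiply (see combination_rule).
  state:        {normal: 1.00, pre: 0.97, stage1: 0.93, stage2: 0.88}
  complication: {ami: 0.76, stroke: 0.63, esrd: 0.54}
  combination_rule: product

compliance:
  lifestyle:  {value: 0.60, dist: {beta: [60, 40]}, source: literature}
  screening:  {value: 0.70, dist: {beta: [70, 30]}, source: literature}
  medication: {value: 0.50, dist: {beta: [50, 50]}, source: literature}

efficacy:
  # Achievable systolic/diastolic reduction (mm Hg) by state.  The normal
  # state has no published figure; it is assumed to match pre-hypertension.
  # Stage II reductions are attainable by pharmacological treatment only.
  sbp_reduction: {normal: 7.0, pre: 7.0, stage1: 16.0, stage2: 19.5}
  dbp_reduction: {normal: 3.0, pre: 3.0, stage1: null, stage2: 8.1}

economics:
  discount_rate: {value: 0.03, dist: {triangular: [0.0, 0.03, 0.05]}, source: literature}
  horizon_years: 20
  # Initial prevalence across states: published appendix unavailable;
  # assumed community-screening mix.
  initial_state_distribution: {normal: 0.50, pre: 0.30, stage1: 0.15, stage2: 0.05}

care_model:
  # Annual utilisation assumptions converting per-visit/per-admission unit
  # costs into state costs.
  mi_visits_per_year: 4
  stroke_visits_per_year: 4
  htn_visits_per_year: {stage1: 2, stage2: 4}
  htn_admissions_per_year: {stage1: 0.01, stage2: 0.05}

risk_model:
  # Log-linear state-specific risk score; exp(score) multiplies progression
  # rates.  Covariate weights are illustrative (not estimated from data);
  # the intercept centres the population mean score at zero.
  intercept: -0.22
  modify_regression: false
  covariates:
    age_z:  {distribution: normal,    mu: 0.0, sigma: 1.0, weight: 0.30}
    male:   {distribution: bernoulli, p: 0.5,  weight: 0.20}
    bmi_z:  {distribution: normal,    mu: 0.0, sigma: 1.0, weight: 0.25}
    smoker: {distribution: bernoulli, p: 0.3,  weight: 0.40}
  cutoffs: null
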