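# Methods

`cvdcheck` models the lifetime cost-effectiveness of a one-off cardiovascular
health check offered to 45–49 year old Australians in general practice,
compared with usual care (no check). The pipeline has four stages; this note
records the model, its assumptions, the numerical conventions, and what the
shipped synthetic inputs do and do not represent.

## 1. Synthetic population and intervention effect

Each individual carries four risk factors — systolic blood pressure (SBP,
mmHg), total cholesterol (TC, mmol/L), HDL cholesterol (mmol/L) and current
smoking — drawn **independently** from sex-specific categorical
distributions (no correlation structure is imposed; joint survey
microdata would be needed to estimate one). Each bin carries a
representative value used as the risk-equation input; values are set
explicitly in the config (roughly central in each bin, not necessarily the
arithmetic midpoint).

The shipped distributions are a **calibrated emulation** of national-survey
categories, not source survey data: bin boundaries and representative values
were fixed on demographic plausibility (e.g. 22% male / 15% female smoking,
26% / 12% SBP > 140 mmHg), and the remaining bin masses were calibrated once
so that the usual-care arm's exact expected 5-year CVD risk and the
between-arm relative risk match the published summary estimates (males
3.74%, RR 0.869; females 1.47%, RR 0.905). Consequences: sampled cohorts
reproduce those targets by construction, so passing incidence tests
demonstrates internal consistency of the machinery, not predictive validity
against real survey data.

The health check acts at the distribution level. For each treated factor a
meta-analytic relative risk RR of *remaining at high risk* multiplies the
above-threshold mass (SBP > 140 mmHg: 0.71; TC > 6 mmol/L: 0.63; smoking:
0.90); the displaced mass is redistributed over the below-threshold bins
proportionally to their existing masses, preserving the shape of the
low-risk distribution. Thresholds must coincide with bin boundaries, and
masses are conserved to 1e-9. HDL is untreated. Benefits are assumed to
last five years.

## 2. Five-year CVD risk

Individual risk uses the published parametric (Weibull accelerated
failure-time) Framingham equation for incident CVD (Anderson, Odell, Wilson
& Kannel, *Am Heart J* 1991;121:293–298):

    p(t) = 1 − exp(−exp((ln t − μ)/σ)),   σ = exp(0.6536 − 0.2402 μ)

with μ linear in female sex, ln age, ln SBP, smoking, ln(TC/HDL), diabetes
and LVH. Diabetes and LVH are fixed absent (the target population is
healthy adults). The equation is evaluated at age 47, the midpoint of the
eligibility band, for every individual; t = 5 years.

Arm-level incidence is the cohort mean of individual risks. Two routes are
provided: a microsimulation (`simulate_arms`: fresh n = 5,000 cohorts per
arm per repetition, 1,000 repetitions by default, means and 2.5/97.5
percentiles across repetitions) and the exact expectation over the product
of bins (`expected_risk`, 240 terms), which is the infinite-cohort limit
and parameterises the deterministic base case. Repetition percentile
intervals reflect cohort sampling only; parameter uncertainty lives in the
PSA.

## 3. Markov cohort model

Twelve states: event-free; five one-cycle tunnel states for the first event
of unstable angina (UA), stable angina (SA), myocardial infarction (MI),
stroke, TIA; five lifelong post-event states; dead. No repeat events and no
non-CVD morbidity. The cohort enters event-free at **age 45** and runs 50
one-year cycles (to age 94). That entry age makes cycles 1–5 coincide with
ages 45–49, where the arm-specific 5-year risk applies, and cycle 6 with
age 50, where the registry-style age-band incidence tables begin — and it
reproduces the published control-arm life expectancies.

Transitions per cycle:

- event-free → tunnel: the 5-year arm incidence is converted to a constant
  annual probability `1 − (1 − p5)^(1/5)` (round-trip exact) for cycles
  1–5, then age-band subtype incidence applies identically in both arms
  (cycles 6+). Annual first-event probability is split across subtypes by
  the 45–49 event-allocation shares (normalised; they are taken from
  hospitalisation episode proportions).
- competing risks are composed death-first: background CVD-free mortality d
  applies to the event-free state; event probabilities apply to survivors
  (scaled by 1 − d); the remainder stays event-free.
- tunnel/post states die with probability min(1, SMR × d), with one SMR per
  subtype (sex-specific for MI and stroke) applied in both the event year
  and all post-event years; tunnel survivors move to the matching post
  state; post states are otherwise absorbing except death.

Rewards are counted at cycle end with the first cycle discounted
(discount factor (1+ρ)^(−cycle); no half-cycle correction — a deliberate
simplification; the scenario machinery accepts any discount rate if a user
wants to bracket the effect). Following the reporting convention of the
analysis this package reproduces, **life-years are reported undiscounted**
while QALYs and costs are discounted at ρ = 5%/year (3.5% as scenario).

Utilities: age/sex population norms apply to the event-free state. The
per-subtype CVD weights w are **multipliers** on the age-matched population
utility: an acute (tunnel) year is valued u_pop × w, and post-event years
carry the acute decrement reduced by the fraction r:

    u_post = u_pop × (1 − (1 − r)(1 − w)),   r = 0.5 base case.

r = 1 restores the population norm after the event year; r = 0 carries the
full acute decrement for life. TIA has w = 1 and never contributes a
decrement. The multiplicative convention was chosen because it is the only
reading under which the published scenario spread over r is arithmetically
consistent with the published life-year gains.

## 4. Costs and ICERs

Health-system perspective, nominal AUD. The intervention arm carries the
per-attendee direct health-check cost **once, undiscounted, at entry**
(the check happens at time zero; a config switch discounts/spreads it
instead). The direct cost comes from a service-bundle calculator: base
check cost plus, per detected risk condition, prevalence × uptake ×
compliance × annual bundle cost; minimum = base cost alone, maximum = full
uptake and compliance. The shipped bundle table is synthetic, calibrated to
the published per-attendee means and bounds.

Both arms accrue: acute admission cost per tunnel-state occupancy and an
annual post-event cost equal to a fraction f of the acute cost (f = 0.15
base; 0.10/0.20 scenarios) for every post-state year. Usual care has no
primary-care cost.

ICERs are Δcost/ΔLY and Δcost/ΔQALY on unrounded values, with standard
dominance classification; a zero effect difference yields an "undefined"
flag rather than an exception. Display rounding (3 decimals for LY/QALY,
whole dollars) is applied only in reports.

## 5. Probabilistic sensitivity analysis

One joint independent draw per iteration (1,000 by default), full model
evaluation per draw, sex and arm:

- lognormal for SMRs: location = mean of log CI bounds, scale = log CI
  half-width / 1.96 (the sampler median is the geometric CI midpoint);
- beta for utilities by moment matching from mean and SE (infeasible
  moments raise a fit error; SE = 0 degenerates to the mean);
- uniform for costs: printed ranges (±25% acute costs; direct cost over its
  printed min–max) and a default ±25% for quantities whose ranges are not
  printed (event allocation — renormalised after perturbation — age-band
  incidence, mortality);
- arm-specific 5-year incidence uniform within its simulated 2.5/97.5
  percentile interval, with **both arms sharing one quantile per draw**
  (positive correlation). Independent overlapping intervals would
  manufacture draws where the check increases incidence, a pattern the
  underlying mechanism (mass moving to lower-risk bins under a monotone
  risk equation) cannot produce; a flag restores independent sampling.

The CEAC reports, per willingness-to-pay λ on a $0–150k grid ($28k and
$50k always included), the fraction of draws with λ·ΔQALY − Δcost ≥ 0.

## 6. Reproducibility and problem sizes

A single master seed fans out to per-stage streams via
`numpy.random.SeedSequence` spawning; identical (config, seed) pairs give
bitwise identical cohorts, PSA draws and CSV outputs. Default problem
sizes — 5,000 individuals per sex per repetition, 1,000 repetitions for
incidence intervals (200 in the routine test, a scaling that leaves the RR
means unchanged to ±0.005), 50 Markov cycles, 1,000 PSA draws — follow the
study design and run in seconds on one core.

## 7. Known limitations

- Risk factors are sampled independently; real risk factors cluster, so the
  tails of the risk distribution are thinner than in survey microdata.
- The synthetic distributions and cost bundles are calibrated emulations:
  agreement with published aggregate incidence/costs is built in, and tests
  against those values validate the machinery, not the inputs.
- One SMR per subtype for both the event year and all later years; acute
  case fatality is not modelled separately.
- No repeat CVD events, no treatment harms, no risk-factor drift within the
  5-year effect window, no costs of opportunistic risk-factor detection in
  usual care.
- The residual discrepancy against the published results is concentrated in
  the discounted survival channel (our utility-weighted discounted survival
  gain is ~30% larger than the published figures imply, with the morbidity
  channel and undiscounted life-year gain in close agreement); the
  acceptance artefacts report this honestly rather than recalibrating.
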