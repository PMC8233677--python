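# Methods

## Model structure

`opidyn` is a discrete-time (annual-cycle) compartmental model of the
opium-dependent population of Iran, ages 15–64. The population occupies
four mutually exclusive stocks: methadone maintenance (MMT),
buprenorphine maintenance (BMT), detoxification with relapse prevention
(DETOX), and untreated or non-evidence-based treatment (UNTREATED).
Three outcome flows are tracked per year: deaths (all stocks), heroin
transitions (UNTREATED only), and abstinence events (all stocks;
abstinence means no illegal opioid use in the 12th month).

All probabilities are stored on the percent scale, exactly as the
national point estimates are published, and converted to fractions only
inside arithmetic. Stocks are continuous (fractional persons); rounding
to integers happens only in reports, where rounding is half-up to match
table conventions.

### Outflow closure and discontinuation

Each treated stock's annual outflow must account for every person:
`stay + death + discontinuation = 100`. The "stay" quantity is one-year
retention for the maintenance groups (Ƃ_M = 33.3, Ƃ_B = 30.0) and
treatment success for DETOX (Ψ_D = 10.0), since a detox episode is
completed within the year and has no retention concept. This is the only
closure under which all three published discontinuation probabilities
(Φ_M = 65.93, Φ_B = 69.61, Φ_D = 89.47) are reproduced exactly, so the
package derives Φ from the closure rather than accepting it as a free
input (supplied values are cross-checked to within 0.02, the printed
rounding grain).

### Abstinence as an event, not an outflow

Abstinence is counted as an annual event indicator and does not remove
persons from stocks. Two observations force this: the outflow closure
above leaves no residual flow for abstainers, and the total dependent
population is specified to grow at the demographic rate. Abstinence
counts are therefore interpretable as "person-years with a successful
treatment outcome", not as exits from dependence.

### Constant prevalence and demographic growth

Prevalence (2.06%) is held constant, so the dependent-population target
for year t is `pop × G(t−1)` with `pop = 1,180,553` and G the cumulative
growth factor. The growth rate itself is not published; the packaged
default calibrates a constant rate from the published 30-year growth of
28.93% over 29 annual increments, giving 0.880%/yr (closed form
`1.2893^(1/29) − 1`). Explicit per-year factor series are also accepted
for non-constant demography.

### Advancement modes

The year-over-year update is not fully identified by the published
description, so two modes are implemented and labelled on every
trajectory:

- **fixed_shares (default).** Each year the grown population target is
  reallocated across the four stocks by the entry shares
  (θ_M = 20.71, θ_B = 5.37, θ_D = 2.42, θ_W = 71.50). This treats the
  entry shares as the standing annual composition implied by treatment
  coverage (coverage is annual treatment *entry*), makes every outcome
  exactly linear in the coverage factor, and reproduces the published
  year-1 quantities; it is the reproducibility-oriented default.
- **flow_based.** Explicit person accounting: survivors of each treated
  stock split into stayers and discontinuers (who move to UNTREATED);
  the untreated pool loses deaths and heroin transitions, absorbs the
  discontinued, and redistributes by the entry shares at the start of
  the next year; finally new dependents enter UNTREATED — never a
  treated stock, since new dependents have not yet sought treatment —
  to restore the constant-prevalence target. Replenishment only tops
  up; if the interim population already exceeds the target (e.g. under
  sharply negative growth) the step raises an infeasibility error
  rather than silently deleting people. A per-year ledger of all flows
  is retained, and the conservation identity
  `stocks(t+1) = stocks(t) − deaths − heroin + replenishment` holds to
  1e-9 relative for arbitrary valid parameter sets.

Under the flow contract, a closed system (no deaths, no heroin, no
growth, full retention) conserves the total exactly while the untreated
stock drains geometrically into treatment at rate θ_W per year; the
treated stocks are not individually stationary because the untreated
pool re-enters treatment every year by construction.

Within a year the order of operations is fixed: outcomes are computed on
start-of-year stocks; flows apply at year end; entries and replenishment
at the start of the next year. Competing events within a year are
applied independently to the same start-of-year stock, matching how the
annual probabilities were estimated.

### Coverage scenarios

`scale_coverage(p, f)` multiplies the three treated entry shares by f,
preserving the within-treatment mix, and assigns the complement to
UNTREATED. The six standard scenarios f ∈ {0.25, 0.5, 0.75, 1.25, 1.5,
1.75} correspond to total coverage 7.13–49.88% around the 28.5% status
quo. Factors must be positive and may not push treated shares above
100%.

### Scenario contrasts and the decade statistic

Per year, the absolute change is `B_t − A_t` and the relative change
`(B_t − A_t)/A_t` (alternative minus baseline; baseline is always the
factor-1.0 run with the same parameters, mode and horizon, and
cross-mode comparisons are refused). Years with a zero baseline are
flagged as undefined rather than NaN-propagated. Per decade (years 1–10,
11–20, 21–30) the summary statistic is the sum of the ten relative
changes (as fractions), reported with the cumulative absolute change;
the decade percentage change is defined as that sum times ten. The
published decade summaries for all six scenarios are packaged as
reference input data (`data/table2_reference.csv`).

## Uncertainty propagation

The published interval estimates come with no stated method, so the
package provides its own, clearly labelled design: parameter-perturbation
Monte Carlo with percentile (2.5/97.5) intervals. Every annual
probability is drawn independently around its point value with a
configurable relative standard deviation (default 5%, an explicit
placeholder exposed in configuration, with no claim of matching any
particular evidence synthesis); truncated-normal on the percent scale is
the default family, beta on the fraction scale the alternative. Entry
shares are perturbed jointly and renormalized to sum to 100;
discontinuation is re-derived per draw so every sampled set satisfies
the closures. Baseline and alternative arms share each draw (common
random parameters), which provably reduces contrast variance; an
independent-arms option exists for diagnostics. Draws are addressed by
`(seed, draw_index)` substreams, making results order-independent and
bit-for-bit reproducible on one platform. Invalid draws (closures that
cannot hold under the perturbation) are excluded and counted; more than
10% failures aborts with advice to reduce the spread. The unperturbed
point estimate is reported alongside the interval; percentile intervals
are not forced to bracket it.

## Synthetic data and the microsimulation oracle

The generator produces structurally valid random parameter sets: entry
shares from a flat Dirichlet simplex (rescaled around any pinned
values), rates from realistic uniform ranges with untreated mortality
(2.2–6%) strictly above treated mortality (0.2–2%) — the ordering
observed in treatment cohorts and the premise of the monotonicity
properties — and closures that always hold. Pinning every key reproduces
the packaged point estimates exactly. Random demographic growth series
support a mean rate with optional jitter.

The agent-based microsimulation applies the identical annual event order
at the individual level (categorical death/stay/discontinue draws per
stock, independent abstinence indicators, untreated death/heroin/stay
draws, pool redistribution, replenishment into UNTREATED), scaled by
`initial_population / n_agents`. Because it is estimand-matched to the
cohort model, its scaled counts converge at the binomial rate; oracle
tests assert agreement within three binomial standard errors at 100,000
agents. What passing these tests shows is internal consistency of the
two implementations under the stated assumptions — not realism of the
assumptions themselves: the generator emulates neither age/sex
structure, nor secular trends in prevalence, nor correlations between
parameters.

## Numerical choices

- Tolerances: entry-share sum 1e-9 (percent scale); outflow closures
  1e-6 at validation, exact by construction after derivation; flow
  conservation asserted at 1e-9 relative; display rounding half-up to
  2 decimals (counts to integers).
- `mortality_scale` (default 1.0) multiplies all death probabilities.
  It exists as a calibration hook because the published year-1 death
  count is not recoverable from the published death rates under any
  per-100/per-1000 reading (the model's year-1 deaths at the point
  estimates are ≈26,844); no value other than 1.0 is asserted anywhere.
  In `flow_based` mode a scaled mortality shrinks the discontinuation
  residual rather than breaking conservation.
- Degenerate inputs: zero coverage, zero rates, single-year horizons and
  zero-growth demography are all legal and tested; factor 0 is not (the
  baseline contrast would be undefined).
- Problem sizes: oracle tests use 100,000 agents over 3 years and 20
  random parameter sets; conservation is checked over 1,000 random sets;
  interval-coverage calibration uses 200 replications of 100 draws at a
  one-year horizon. These sizes give comfortable statistical resolution
  for the assertions made (3 SE bounds, ≥90% coverage).

## Known limitations

- The long-run published trajectories and scenario deltas (year-30
  outcome counts, per-year contrast magnitudes after year 1) are not
  derivable from the published annual parameters under either
  advancement mode; they imply a compartment-composition drift whose
  generating mechanism is not specified. The package reproduces the
  quantities that are arithmetically determined by the published
  parameters and treats the rest as out of scope; its own decade
  statistics (e.g. first-decade heroin change of −10.0% under +25%
  coverage in `fixed_shares` mode) land close to, but not exactly on,
  the published figures.
- Heroin dependence is an absorbing exit, not a modelled population:
  no injection, HIV, or heroin-treatment submodel.
- No age structure, no behavioural feedback of coverage on treatment
  seeking, and constant prevalence by assumption; the uncertainty
  module propagates parameter uncertainty only, not structural
  uncertainty across the two advancement modes.
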