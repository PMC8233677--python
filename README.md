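# opidyn

Discrete-time compartmental modelling of opium-dependence treatment
coverage in Iran.

Opium is the most widely used illegal drug in Iran, with an estimated
prevalence of dependence of 2.06% among people aged 15–64 — about
1.18 million people in 2019. Each year a share of this population enters
one of three evidence-based treatment modalities — methadone maintenance
(MMT), buprenorphine maintenance (BMT), or detoxification followed by
relapse prevention — while the remainder stays untreated or receives
non-evidence-based care. `opidyn` is for health-policy modellers who
want to ask: *what happens to deaths, transitions to heroin dependence,
and opiate abstinence over 30 years if treatment coverage is scaled up
or down from the status quo of 28.5%?*

## The model

The dependent population is split into four annual stocks
g ∈ {MMT, BMT, DETOX, UNTREATED} by entry shares θ_g (θ_M = 20.71,
θ_B = 5.37, θ_D = 2.42, θ_W = 71.50, in percent). Within a year, events
are applied to start-of-year stocks S_g:

- deaths: S_g · Ꝩ_g (annual death probabilities 0.77, 0.39, 0.53, 2.91%),
- heroin transitions (untreated only): S_W · Ɣ_W with Ɣ_W = 1.50%,
- abstinence events (no illegal opioid use in month 12): S_g · Ψ_g
  (27.0, 26.0, 10.0, 1.0%).

Maintenance retention is Ƃ_M = 33.3% and Ƃ_B = 30.0%; the annual
discontinuation probability of each treated group is derived from the
outflow closure Φ_g = 100 − stay_g − Ꝩ_g (stay = retention for MMT/BMT,
success for DETOX), giving Φ_M = 65.93, Φ_B = 69.61, Φ_D = 89.47.
Prevalence is held constant, so the total population follows demographic
growth only (0.880%/yr, calibrated to 28.93% over 29 annual steps).
Coverage scenarios multiply the treated entry shares by a factor
f ∈ {0.25, …, 1.75}; scenarios are contrasted against the f = 1 baseline
per year ((B_t − A_t)/A_t) and per decade through the statistic
Ɵ\* = Σ_t (B_t − A_t)/A_t, whose decade percentage change is Ɵ\* × 10.
Parameter uncertainty is propagated by Monte-Carlo perturbation of all
annual probabilities (truncated-normal or beta, default 5% relative SD)
with percentile intervals.

Two advancement modes are provided: a quasi-static `fixed_shares` mode
(each year the grown population is reallocated by entry shares; the
default) and an explicit `flow_based` stock-and-flow mode with a full
person-conservation ledger. An agent-based microsimulation with the same
annual event rules serves as an independent stochastic oracle for both.

## Worked example

```python
import opidyn as od

p = od.load_parameters()                 # packaged national estimates
base = od.run_scenario(p, factor=1.0, horizon=30)
up = od.run_scenario(p, factor=1.25, horizon=30)

y1 = base.outcomes[0]
print(f"year 1 (status quo): deaths {y1.total_deaths:,.0f}, "
      f"heroin transitions {y1.heroin_transitions:,.0f}, "
      f"abstinence events {y1.total_abstinence:,.0f}")
print(f"dependent population: {base.states[0].total:,.0f} -> "
      f"{base.states[-1].total:,.0f} "
      f"(+{(base.states[-1].total/base.states[0].total-1)*100:.2f}%)")

s = od.decade_theta(up, base, "heroin", decade=1)
print(f"first decade, +25% coverage: cumulative heroin change "
      f"{s.cumulative:,.0f}, theta {s.theta:.3f} ({s.percent:.1f}%)")

est = od.monte_carlo_comparison(
    p, 1.25, 1, "fixed_shares",
    od.Statistic("year_relative", "heroin", year=1),
    od.UncertaintySpec(rel_sd=0.05, draws=1000, seed=1),
)
print(f"year-1 heroin change, +25% coverage: {est.point:.2f}% "
      f"(95% CI {est.lower:.2f} to {est.upper:.2f})")
```

prints

```
year 1 (status quo): deaths 26,844, heroin transitions 12,661, abstinence events 93,794
dependent population: 1,180,553 -> 1,522,087 (+28.93%)
first decade, +25% coverage: cumulative heroin change -13,129, theta -0.997 (-10.0%)
year-1 heroin change, +25% coverage: -9.97% (95% CI -11.27 to -8.74)
```

Reading: at status-quo coverage, roughly 12,700 untreated opium
dependents move to heroin dependence in the first year while about
93,800 people achieve month-12 abstinence; constant prevalence plus
demographic growth raises the dependent population by 28.93% over
30 years; expanding coverage by a quarter (28.5% → 35.63%) cuts
first-decade heroin transitions by about 10%, with the Monte-Carlo
interval reflecting 5% parameter uncertainty.

The same pipeline is available from the shell:

```sh
opidyn run --factor 1.0 --horizon 30 --out out/statusquo
opidyn compare --horizon 30 --out out/grid
opidyn mc --factor 1.25 --outcome heroin --draws 1000 --seed 1 --out out/mc
```

Each invocation writes CSV/JSON outputs plus a manifest from which the
run can be replayed exactly.

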