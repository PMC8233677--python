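"""Annual compartmental dynamics of the treatment model.

The model advances in one-year steps over a default 30-year horizon.
Prevalence of opium dependence is held constant, so the total dependent
population grows only with demography: ``target(t) = pop * G(t-1)`` where
``G`` is the cumulative growth factor.  Within a year, outcomes (deaths,
heroin transitions out of the untreated group, and abstinence events) are
computed on start-of-year stocks; flows between groups are applied at
year end; entries into treatment occur at the start of the next year.

Two advancement modes are provided:

``fixed_shares``
    Quasi-static: each year the whole population is reallocated across
    the four groups by the annual entry shares.  This reading treats the
    entry shares as the standing annual composition implied by treatment
    coverage (coverage is *annual treatment entry*), makes every year's
    outcome a closed-form function of the coverage factor, and is the
    default.

``flow_based``
    Explicit stock-and-flow accounting: survivors of each treated group
    split into those who stay and those who discontinue into UNTREATED;
    the untreated pool then loses deaths and heroin transitions, absorbs
    the discontinued, and redistributes by the entry shares at the start
    of the next year; finally new dependents (demographic replenishment)
    enter UNTREATED — never any treated group — to restore the constant
    prevalence target.  A per-year ledger of all flows is retained.

Abstinence (no illegal opioid use in month 12) is an *event counter*,
not a stock outflow: the outflow closure of each treated group
(stay + death + discontinuation = 100) leaves no residual flow for
abstainers, and abstinent persons remain in the dependent population's
accounting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .parameters import (
    GROUPS,
    TREATED_GROUPS,
    ConfigurationError,
    ParameterSet,
    ScenarioInfeasibleError,
    TreatmentGroup,
    scale_coverage,
)

__all__ = [
    "CompartmentState",
    "AnnualOutcomes",
    "FlowLedger",
    "Trajectory",
    "OUTCOME_NAMES",
    "population_target",
    "calibrate_growth_rate",
    "initial_allocation",
    "annual_outcomes",
    "advance_fixed_shares",
    "advance_flow_based",
    "run_scenario",
]

Mode = Literal["fixed_shares", "flow_based"]
OUTCOME_NAMES = ("deaths", "heroin", "abstinence")

_W = TreatmentGroup.UNTREATED


@dataclass(frozen=True)
class CompartmentState:
    """Stocks of the four groups at the start of one model year."""

    year: int
    stock: dict[TreatmentGroup, float]

    @property
    def total(self) -> float:
        return sum(self.stock.values())


@dataclass(frozen=True)
class AnnualOutcomes:
    """Within-year event counts computed on start-of-year stocks."""

    deaths: dict[TreatmentGroup, float]
    heroin_transitions: float
    abstinence_events: dict[TreatmentGroup, float]

    @property
    def total_deaths(self) -> float:
        return sum(self.deaths.values())

    @property
    def total_abstinence(self) -> float:
        return sum(self.abstinence_events.values())

    def total(self, outcome: str) -> float:
        if outcome == "deaths":
            return self.total_deaths
        if outcome == "heroin":
            return self.heroin_transitions
        if outcome == "abstinence":
            return self.total_abstinence
        raise KeyError(f"unknown outcome {outcome!r}; expected {OUTCOME_NAMES}")


@dataclass(frozen=True)
class FlowLedger:
    """Accounting of every person-flow from year t to t+1 (flow_based)."""

    year: int
    deaths: dict[TreatmentGroup, float]
    heroin_transitions: float
    retained: dict[TreatmentGroup, float]
    discontinued: dict[TreatmentGroup, float]
    entries: dict[TreatmentGroup, float]
    untreated_remaining: float
    replenishment: float


@dataclass
class Trajectory:
    """One scenario's complete run: states and outcomes for years 1..H."""

    scenario: str
    mode: str
    factor: float
    states: list[CompartmentState]
    outcomes: list[AnnualOutcomes]
    ledgers: list[FlowLedger] | None = None

    @property
    def horizon(self) -> int:
        return len(self.states)

    @property
    def years(self) -> np.ndarray:
        return np.array([s.year for s in self.states])

    def series(self, outcome: str) -> np.ndarray:
        """Per-year totals of one outcome over the whole horizon."""
        return np.array([o.total(outcome) for o in self.outcomes])

    def population(self) -> np.ndarray:
        return np.array([s.total for s in self.states])

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-year, per-group table of stocks and outcomes."""
        rows = []
        for s, o in zip(self.states, self.outcomes):
            for g in GROUPS:
                rows.append(
                    {
                        "year": s.year,
                        "group": g.value,
                        "stock": s.stock[g],
                        "deaths": o.deaths[g],
                        "heroin_transitions": (
                            o.heroin_transitions if g is _W else 0.0
                        ),
                        "abstinence_events": o.abstinence_events[g],
                        "scenario": self.scenario,
                        "mode": self.mode,
                    }
                )
        return pd.DataFrame(rows)


def calibrate_growth_rate(total_percent: float, steps: int = 29) -> float:
    """Constant annual growth rate (percent) whose ``steps`` increments
    compound to ``total_percent`` overall growth."""
    return ((1.0 + total_percent / 100.0) ** (1.0 / steps) - 1.0) * 100.0


def population_target(p: ParameterSet, year: int) -> float:
    """Dependent-population size mandated by constant prevalence at ``year``.

    Year 1 returns the initial population exactly; later years compound
    the demographic growth specification over ``year - 1`` increments.
    """
    if year < 1:
        raise ValueError(f"year must be >= 1, got {year}")
    if year == 1:
        return p.initial_population
    return p.initial_population * p.growth.cumulative_factor(year - 1)


def initial_allocation(p: ParameterSet) -> CompartmentState:
    """Allocate the year-1 population across groups by entry share."""
    return CompartmentState(
        year=1,
        stock={g: p.initial_population * p.entry_share[g] / 100.0 for g in GROUPS},
    )


def annual_outcomes(s: CompartmentState, p: ParameterSet) -> AnnualOutcomes:
    """Deaths, heroin transitions and abstinence events for one year.

    All three are computed on the same start-of-year stocks (competing
    events are applied independently, mirroring how the annual
    probabilities were estimated).
    """
    deaths = {
        g: s.stock[g] * p.death[g] / 100.0 * p.mortality_scale for g in GROUPS
    }
    abstinence = {g: s.stock[g] * p.success[g] / 100.0 for g in GROUPS}
    heroin = s.stock[_W] * p.heroin_transition / 100.0
    return AnnualOutcomes(
        deaths=deaths, heroin_transitions=heroin, abstinence_events=abstinence
    )


def advance_fixed_shares(s: CompartmentState, p: ParameterSet) -> CompartmentState:
    """Next year's state under the quasi-static reading: the grown
    population target reallocated by entry share."""
    target = population_target(p, s.year + 1)
    return CompartmentState(
        year=s.year + 1,
        stock={g: target * p.entry_share[g] / 100.0 for g in GROUPS},
    )


def advance_flow_based(
    s: CompartmentState, p: ParameterSet
) -> tuple[CompartmentState, FlowLedger]:
    """Next year's state with explicit person-flow accounting.

    Treated groups: ``stay`` persons remain (retention for maintenance,
    success for detox), deaths are removed, and the residual discontinues
    into UNTREATED.  The post-flow untreated pool (stayers minus deaths
    and heroin transitions, plus the newly discontinued) redistributes by
    the entry shares at the start of the next year.  Demographic
    replenishment tops the UNTREATED stock up — never down — to the
    constant-prevalence target; a total already above target raises
    :class:`ScenarioInfeasibleError` rather than silently removing people.
    """
    out = annual_outcomes(s, p)
    retained = {
        g: s.stock[g] * p.stay_probability(g) / 100.0 for g in TREATED_GROUPS
    }
    discontinued = {}
    for g in TREATED_GROUPS:
        resid = s.stock[g] - retained[g] - out.deaths[g]
        if resid < -1e-9 * max(s.stock[g], 1.0):
            raise ScenarioInfeasibleError(
                f"outflows of {g.value} exceed its stock in year {s.year}"
            )
        discontinued[g] = max(resid, 0.0)

    pool = (
        s.stock[_W]
        - out.deaths[_W]
        - out.heroin_transitions
        + sum(discontinued.values())
    )
    if pool < -1e-9 * max(s.stock[_W], 1.0):
        raise ScenarioInfeasibleError(
            f"untreated outflows exceed the untreated stock in year {s.year}"
        )
    pool = max(pool, 0.0)

    entries = {g: pool * p.entry_share[g] / 100.0 for g in TREATED_GROUPS}
    w_remaining = pool * p.entry_share[_W] / 100.0

    target = population_target(p, s.year + 1)
    interim_total = sum(retained.values()) + pool
    replenishment = target - interim_total
    if replenishment < -1e-9 * target:
        raise ScenarioInfeasibleError(
            f"population {interim_total:.1f} exceeds the year-{s.year + 1} "
            f"target {target:.1f}; cannot replenish downwards"
        )
    replenishment = max(replenishment, 0.0)

    stock = {g: retained[g] + entries[g] for g in TREATED_GROUPS}
    stock[_W] = w_remaining + replenishment
    ledger = FlowLedger(
        year=s.year,
        deaths=out.deaths,
        heroin_transitions=out.heroin_transitions,
        retained=retained,
        discontinued=discontinued,
        entries=entries,
        untreated_remaining=w_remaining,
        replenishment=replenishment,
    )
    return CompartmentState(year=s.year + 1, stock=stock), ledger


def run_scenario(
    p: ParameterSet,
    factor: float = 1.0,
    horizon: int = 30,
    mode: Mode = "fixed_shares",
    label: str | None = None,
) -> Trajectory:
    """Run one coverage scenario over ``horizon`` years.

    ``factor`` rescales the treated entry shares before the run (1.0 is
    the status quo).  Deterministic given its inputs.
    """
    if horizon < 1:
        raise ValueError(f"horizon must be >= 1, got {horizon}")
    if mode not in ("fixed_shares", "flow_based"):
        raise ConfigurationError(f"unknown mode {mode!r}")
    scaled = scale_coverage(p, factor).validate()
    if label is None:
        label = "status quo" if factor == 1.0 else f"{(factor - 1) * 100:+.0f}%"

    states = [initial_allocation(scaled)]
    outcomes = [annual_outcomes(states[0], scaled)]
    ledgers: list[FlowLedger] | None = [] if mode == "flow_based" else None
    for _ in range(horizon - 1):
        if mode == "fixed_shares":
            nxt = advance_fixed_shares(states[-1], scaled)
        else:
            nxt, ledger = advance_flow_based(states[-1], scaled)
            ledgers.append(ledger)
        states.append(nxt)
        outcomes.append(annual_outcomes(nxt, scaled))
    return Trajectory(
        scenario=label,
        mode=mode,
        factor=factor,
        states=states,
        outcomes=outcomes,
        ledgers=ledgers,
    )
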