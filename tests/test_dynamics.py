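"""Annual advancement, outcome flows, and scenario runs."""

import numpy as np
import pytest

from opidyn.dynamics import (
    advance_fixed_shares,
    advance_flow_based,
    annual_outcomes,
    calibrate_growth_rate,
    initial_allocation,
    population_target,
    run_scenario,
)
from opidyn.parameters import (
    ConfigurationError,
    GrowthSpec,
    ScenarioInfeasibleError,
    TreatmentGroup,
    load_parameters,
)
from opidyn.synthetic import toy_ledger_config

M, B, D, W = (
    TreatmentGroup.MMT,
    TreatmentGroup.BMT,
    TreatmentGroup.DETOX,
    TreatmentGroup.UNTREATED,
)


class TestPopulationTarget:
    def test_year_one_is_exactly_initial(self, table1):
        assert population_target(table1, 1) == 1_180_553

    def test_zero_growth_is_flat(self, table1):
        import dataclasses

        flat = dataclasses.replace(table1, growth=GrowthSpec.constant(0.0))
        assert population_target(flat, 30) == 1_180_553

    def test_calibrated_rate_reproduces_30_year_projection(self, table1):
        # 29 annual increments at the calibrated rate land on the
        # projected year-30 dependent population
        assert population_target(table1, 30) == pytest.approx(
            1_522_063, rel=1e-4
        )

    def test_series_growth_and_exhaustion(self, table1):
        import dataclasses

        p = dataclasses.replace(
            table1, growth=GrowthSpec.from_series([1.01, 1.02])
        )
        assert population_target(p, 3) == pytest.approx(
            1_180_553 * 1.01 * 1.02
        )
        with pytest.raises(ConfigurationError):
            population_target(p, 4)

    def test_invalid_year(self, table1):
        with pytest.raises(ValueError):
            population_target(table1, 0)


def test_calibrated_growth_rate_value():
    rate = calibrate_growth_rate(28.93, steps=29)
    assert rate == pytest.approx(0.880, abs=1e-3)
    assert (1 + rate / 100.0) ** 29 == pytest.approx(1.2893)


class TestInitialAllocation:
    def test_share_proportional_stocks(self, table1):
        s = initial_allocation(table1)
        assert s.stock[W] == pytest.approx(844_095.4, abs=0.1)
        assert s.stock[M] == pytest.approx(244_492.5, abs=0.1)
        assert s.total == pytest.approx(1_180_553)

    def test_all_untreated_corner(self, table1):
        import dataclasses

        p = dataclasses.replace(
            table1,
            entry_share={M: 0.0, B: 0.0, D: 0.0, W: 100.0},
        )
        s = initial_allocation(p)
        assert s.stock[W] == p.initial_population
        assert s.stock[M] == 0.0


class TestAnnualOutcomes:
    def test_year_one_event_counts(self, table1):
        o = annual_outcomes(initial_allocation(table1), table1)
        assert round(o.heroin_transitions) == 12_661
        assert o.total_abstinence == pytest.approx(93_793.8, abs=0.1)
        assert o.heroin_transitions <= initial_allocation(table1).stock[W]

    def test_zero_rates_give_zero_outcomes(self):
        doc = toy_ledger_config()
        doc.update(
            k_m=0.0, k_b=0.0, k_d=0.0, k_w=0.0, gamma_w=0.0,
            psi_m=0.0, psi_b=0.0, psi_d=0.0, psi_w=0.0,
            b_m=100.0, b_b=100.0,
        )
        p = load_parameters(doc)
        o = annual_outcomes(initial_allocation(p), p)
        assert o.total_deaths == 0.0
        assert o.heroin_transitions == 0.0
        assert o.total_abstinence == 0.0

    def test_mortality_scale_multiplies_deaths_only(self, table1):
        import dataclasses

        p2 = dataclasses.replace(table1, mortality_scale=2.0)
        s = initial_allocation(table1)
        assert annual_outcomes(s, p2).total_deaths == pytest.approx(
            2 * annual_outcomes(s, table1).total_deaths
        )
        assert annual_outcomes(s, p2).heroin_transitions == annual_outcomes(
            s, table1
        ).heroin_transitions


class TestFixedSharesAdvance:
    def test_zero_growth_steady_state(self, toy):
        s = initial_allocation(toy)
        nxt = advance_fixed_shares(s, toy)
        assert nxt.stock == s.stock

    def test_growth_scales_every_stock(self, table1):
        s = initial_allocation(table1)
        nxt = advance_fixed_shares(s, table1)
        factor = 1.0 + table1.growth.rate_percent / 100.0
        for g in s.stock:
            assert nxt.stock[g] == pytest.approx(s.stock[g] * factor)


class TestFlowBasedAdvance:
    def test_toy_hand_ledger(self, toy):
        # 3 persons, shares 50/50 MMT/untreated, retention 50%,
        # deaths 10%, heroin 20%, zero growth -- worked by hand:
        #   stocks (1.5, 1.5); deaths 0.15 each; heroin 0.30
        #   retained MMT 0.75, discontinued 0.60
        #   pool = 1.5 - 0.15 - 0.30 + 0.60 = 1.65
        #   entries MMT 0.825, untreated remainder 0.825
        #   replenishment = 3 - (0.75 + 1.65) = 0.60
        s = initial_allocation(toy)
        nxt, ledger = advance_flow_based(s, toy)
        assert ledger.deaths[M] == pytest.approx(0.15)
        assert ledger.deaths[W] == pytest.approx(0.15)
        assert ledger.heroin_transitions == pytest.approx(0.30)
        assert ledger.retained[M] == pytest.approx(0.75)
        assert ledger.discontinued[M] == pytest.approx(0.60)
        assert ledger.entries[M] == pytest.approx(0.825)
        assert ledger.untreated_remaining == pytest.approx(0.825)
        assert ledger.replenishment == pytest.approx(0.60)
        assert nxt.stock[M] == pytest.approx(1.575)
        assert nxt.stock[W] == pytest.approx(1.425)
        assert nxt.total == pytest.approx(3.0)

    def test_conservation_identity_on_defaults(self, table1):
        s = initial_allocation(table1)
        nxt, ledger = advance_flow_based(s, table1)
        lhs = nxt.total
        rhs = (
            s.total
            - sum(ledger.deaths.values())
            - ledger.heroin_transitions
            + ledger.replenishment
        )
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_closed_system_conserves_total_and_drains_untreated(self):
        # no deaths, no heroin, no growth, full retention: the total is
        # conserved exactly while the untreated pool redistributes into
        # treatment geometrically at its own entry share
        doc = toy_ledger_config()
        doc.update(
            k_m=0.0, k_b=0.0, k_d=0.0, k_w=0.0, gamma_w=0.0,
            b_m=100.0, b_b=100.0, psi_d=100.0,
        )
        p = load_parameters(doc)
        traj = run_scenario(p, 1.0, 6, "flow_based")
        w_share = p.entry_share[W] / 100.0
        w0 = traj.states[0].stock[W]
        for t, s in enumerate(traj.states):
            assert s.total == pytest.approx(3.0, rel=1e-12)
            assert s.stock[W] == pytest.approx(w0 * w_share**t, rel=1e-9)

    def test_negative_growth_infeasibility(self, table1):
        import dataclasses

        shrinking = dataclasses.replace(
            table1, growth=GrowthSpec.constant(-10.0)
        )
        s = initial_allocation(shrinking)
        with pytest.raises(ScenarioInfeasibleError):
            advance_flow_based(s, shrinking)


class TestRunScenario:
    def test_year_one_equivalence_across_modes(self, table1):
        fixed = run_scenario(table1, 1.0, 1, "fixed_shares")
        flow = run_scenario(table1, 1.0, 1, "flow_based")
        assert fixed.states[0].stock == flow.states[0].stock
        assert fixed.outcomes[0] == flow.outcomes[0]

    @pytest.mark.parametrize("mode", ["fixed_shares", "flow_based"])
    def test_population_matches_target_every_year(self, table1, mode):
        traj = run_scenario(table1, 1.0, 30, mode)
        for s in traj.states:
            assert s.total == pytest.approx(
                population_target(table1, s.year), rel=1e-6
            )

    def test_fixed_shares_outcomes_linear_in_factor(self, table1):
        runs = {
            f: run_scenario(table1, f, 5, "fixed_shares")
            for f in (0.75, 1.0, 1.25)
        }
        for outcome in ("deaths", "heroin", "abstinence"):
            lo, mid, hi = (runs[f].series(outcome) for f in (0.75, 1.0, 1.25))
            np.testing.assert_allclose(hi - mid, mid - lo, rtol=1e-9)

    def test_horizon_one_and_bad_inputs(self, table1):
        assert run_scenario(table1, 1.0, 1).horizon == 1
        with pytest.raises(ValueError):
            run_scenario(table1, 1.0, 0)
        with pytest.raises(ScenarioInfeasibleError):
            run_scenario(table1, 4.0, 1)
        with pytest.raises(ConfigurationError):
            run_scenario(table1, 1.0, 1, "continuous")

    def test_scenario_labels(self, table1):
        assert run_scenario(table1, 1.0, 1).scenario == "status quo"
        assert run_scenario(table1, 1.25, 1).scenario == "+25%"
        assert run_scenario(table1, 0.5, 1).scenario == "-50%"
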