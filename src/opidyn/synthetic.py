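"""Synthetic inputs and an agent-based oracle for the treatment model.

This module makes every stage of the pipeline testable without external
data: it generates random but structurally valid parameter sets (shares
on the simplex, closable outflows, untreated mortality exceeding treated
mortality, as observed in practice), random demographic growth series,
and an individual-level Bernoulli microsimulation that follows exactly
the same annual event order as the deterministic model.  Because the
microsimulation and the cohort model are estimand-matched, the scaled
microsimulation counts converge to the deterministic outcomes at the
binomial rate, which is what the oracle-agreement tests assert.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from .dynamics import (
    AnnualOutcomes,
    CompartmentState,
    Trajectory,
    population_target,
)
from .parameters import (
    GROUPS,
    TREATED_GROUPS,
    GrowthSpec,
    ParameterSet,
    ParameterValidationError,
    TreatmentGroup,
    derive_discontinuation,
)

__all__ = [
    "random_parameter_set",
    "random_growth_series",
    "microsimulate",
    "toy_ledger_config",
    "write_example_configs",
]

_W = TreatmentGroup.UNTREATED
_GROUP_INDEX = {g: i for i, g in enumerate(GROUPS)}

# Default sampling ranges (percent scale) for free parameters.  Treated
# death probabilities are kept strictly below the untreated one, the
# ordering seen in treatment cohorts, so generated sets also satisfy the
# monotonicity premises of the scenario analysis.
_DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "b_m": (10.0, 70.0),
    "b_b": (10.0, 70.0),
    "psi_m": (5.0, 40.0),
    "psi_b": (5.0, 40.0),
    "psi_d": (4.0, 30.0),
    "psi_w": (0.1, 3.0),
    "k_m": (0.2, 2.0),
    "k_b": (0.2, 2.0),
    "k_d": (0.2, 2.0),
    "k_w": (2.2, 6.0),
    "gamma_w": (0.1, 5.0),
    "prevalence": (0.5, 5.0),
    "pop": (1e5, 2e6),
    "beta": (0.0, 2.0),
}
_THETA_KEYS = ("theta_m", "theta_b", "theta_d", "theta_w")


class GenerationError(RuntimeError):
    """The constraints could not be satisfied within the retry budget."""


def _resolve(
    key: str,
    rng: np.random.Generator,
    constraints: Mapping[str, Any],
) -> float:
    c = constraints.get(key)
    if c is None:
        lo, hi = _DEFAULT_RANGES[key]
    elif np.isscalar(c):
        return float(c)
    else:
        lo, hi = float(c[0]), float(c[1])
    return float(rng.uniform(lo, hi))


def _draw_shares(
    rng: np.random.Generator, constraints: Mapping[str, Any]
) -> dict[TreatmentGroup, float]:
    pinned = {
        k: float(constraints[k])
        for k in _THETA_KEYS
        if np.isscalar(constraints.get(k))
    }
    free = [k for k in _THETA_KEYS if k not in pinned]
    remainder = 100.0 - sum(pinned.values())
    if remainder < -1e-9:
        raise GenerationError("pinned entry shares exceed 100%")
    values = dict(pinned)
    if free:
        parts = rng.dirichlet(np.ones(len(free))) * max(remainder, 0.0)
        values.update(dict(zip(free, parts)))
    order = dict(zip(_THETA_KEYS, GROUPS))
    return {order[k]: values[k] for k in _THETA_KEYS}


def random_parameter_set(
    seed: int,
    constraints: Mapping[str, Any] | None = None,
    max_retries: int = 100,
) -> ParameterSet:
    """A random parameter set that always passes validation.

    ``constraints`` maps configuration keys to either a scalar (pinning
    the value — pinning every key to the published estimates reproduces
    them exactly) or a ``(low, high)`` range.  Entry shares are drawn
    from a flat simplex scaled to whatever the pinned shares leave free.
    """
    constraints = dict(constraints or {})
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    last_err: Exception | None = None
    for _ in range(max_retries):
        try:
            beta = constraints.get("beta")
            if isinstance(beta, (Mapping, list, tuple)):
                growth = _parse_constraint_growth(beta)
            else:
                growth = GrowthSpec.constant(_resolve("beta", rng, constraints))
            p = ParameterSet(
                prevalence=_resolve("prevalence", rng, constraints),
                initial_population=_resolve("pop", rng, constraints),
                entry_share=_draw_shares(rng, constraints),
                retention={
                    TreatmentGroup.MMT: _resolve("b_m", rng, constraints),
                    TreatmentGroup.BMT: _resolve("b_b", rng, constraints),
                },
                success={
                    TreatmentGroup.MMT: _resolve("psi_m", rng, constraints),
                    TreatmentGroup.BMT: _resolve("psi_b", rng, constraints),
                    TreatmentGroup.DETOX: _resolve("psi_d", rng, constraints),
                    _W: _resolve("psi_w", rng, constraints),
                },
                death={
                    TreatmentGroup.MMT: _resolve("k_m", rng, constraints),
                    TreatmentGroup.BMT: _resolve("k_b", rng, constraints),
                    TreatmentGroup.DETOX: _resolve("k_d", rng, constraints),
                    _W: _resolve("k_w", rng, constraints),
                },
                heroin_transition=_resolve("gamma_w", rng, constraints),
                growth=growth,
            )
            return derive_discontinuation(p).validate()
        except (ParameterValidationError, ValueError) as err:
            last_err = err
    raise GenerationError(
        f"no valid parameter set after {max_retries} retries: {last_err}"
    )


def _parse_constraint_growth(beta: Any) -> GrowthSpec:
    if isinstance(beta, Mapping):
        if "rate_percent" in beta:
            return GrowthSpec.constant(float(beta["rate_percent"]))
        if "total_percent" in beta:
            return GrowthSpec.from_total(
                float(beta["total_percent"]), int(beta["steps"])
            )
        if "factors" in beta:
            return GrowthSpec.from_series(beta["factors"])
    return GrowthSpec.from_series(beta)


def random_growth_series(
    seed: int,
    horizon: int,
    mean_rate: float = 0.88,
    jitter: float = 0.0,
) -> np.ndarray:
    """Per-step demographic growth factors for years 1..horizon.

    ``mean_rate`` and ``jitter`` are in percent per year; jitter 0
    reduces to the constant-rate factor.  Returns ``horizon - 1``
    positive factors (one per annual increment).
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rates = mean_rate + rng.normal(0.0, jitter, size=horizon - 1)
    return np.maximum(1.0 + rates / 100.0, 1e-6)


# -- agent-based oracle ----------------------------------------------------


def microsimulate(
    p: ParameterSet,
    n_agents: int,
    horizon: int,
    seed: int,
    mode: str = "flow_based",
) -> Trajectory:
    """Individual-level Bernoulli simulation of the annual dynamics.

    Each agent independently experiences the model's annual events in
    the deterministic order: outcomes (death, heroin transition,
    abstinence) are resolved on the start-of-year group; end-of-year
    flows move discontinued agents to UNTREATED; the untreated pool
    redistributes by entry share at the start of the next year; new
    agents replenish UNTREATED up to the constant-prevalence target.
    Counts are scaled by ``initial_population / n_agents`` so the
    aggregate trajectory is directly comparable to the cohort model.
    """
    if n_agents < 1:
        raise ValueError("n_agents must be >= 1")
    if mode not in ("fixed_shares", "flow_based"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    shares = np.array([p.entry_share[g] / 100.0 for g in GROUPS])
    shares = shares / shares.sum()
    death_p = np.array(
        [p.death[g] / 100.0 * p.mortality_scale for g in GROUPS]
    )
    success_p = np.array([p.success[g] / 100.0 for g in GROUPS])
    stay_p = np.zeros(4)
    for g in TREATED_GROUPS:
        stay_p[_GROUP_INDEX[g]] = p.stay_probability(g) / 100.0
    gamma = p.heroin_transition / 100.0
    w_idx = _GROUP_INDEX[_W]

    base_scale = p.initial_population / n_agents
    groups = rng.choice(4, size=n_agents, p=shares)

    states: list[CompartmentState] = []
    outcomes: list[AnnualOutcomes] = []
    for year in range(1, horizon + 1):
        if mode == "fixed_shares":
            scale = population_target(p, year) / n_agents
            if year > 1:
                groups = rng.choice(4, size=n_agents, p=shares)
        else:
            scale = base_scale

        counts = np.bincount(groups, minlength=4)
        states.append(
            CompartmentState(
                year=year,
                stock={g: counts[_GROUP_INDEX[g]] * scale for g in GROUPS},
            )
        )

        u = rng.random(groups.shape[0])
        dead = u < death_p[groups]
        # heroin transition competes with death for untreated survivors
        is_w = groups == w_idx
        heroin = is_w & ~dead & (u < death_p[w_idx] + gamma)
        abstinent = rng.random(groups.shape[0]) < success_p[groups]

        death_counts = np.bincount(groups[dead], minlength=4)
        abst_counts = np.bincount(groups[abstinent], minlength=4)
        outcomes.append(
            AnnualOutcomes(
                deaths={
                    g: death_counts[_GROUP_INDEX[g]] * scale for g in GROUPS
                },
                heroin_transitions=float(heroin.sum()) * scale,
                abstinence_events={
                    g: abst_counts[_GROUP_INDEX[g]] * scale for g in GROUPS
                },
            )
        )

        if year == horizon:
            break
        if mode == "fixed_shares":
            continue

        # end-of-year flows: stayers keep their group, everyone else in a
        # treated group discontinues into the untreated pool
        stays = ~dead & ~heroin & (
            is_w | (u >= 1.0 - stay_p[groups])
        )
        pool = ~dead & ~heroin & ~stays  # discontinued treated agents
        keep = ~dead & ~heroin
        groups = groups[keep]
        in_pool = pool[keep] | (groups == w_idx)
        # start-of-next-year reallocation of the untreated pool
        groups[in_pool] = rng.choice(4, size=int(in_pool.sum()), p=shares)

        target = population_target(p, year + 1)
        n_new = int(round(target / base_scale)) - groups.shape[0]
        if n_new > 0:
            groups = np.concatenate(
                [groups, np.full(n_new, w_idx, dtype=groups.dtype)]
            )

    return Trajectory(
        scenario="microsim",
        mode=f"microsim:{mode}",
        factor=1.0,
        states=states,
        outcomes=outcomes,
    )


# -- packaged fixtures -----------------------------------------------------


def toy_ledger_config() -> dict[str, Any]:
    """A three-person toy population with round-number rates, small enough
    that the first flow-based year can be checked by hand."""
    return {
        "prevalence": 1.0,
        "pop": 3,
        "theta_m": 50.0,
        "theta_b": 0.0,
        "theta_d": 0.0,
        "theta_w": 50.0,
        "b_m": 50.0,
        "b_b": 50.0,
        "psi_m": 20.0,
        "psi_b": 20.0,
        "psi_d": 50.0,
        "psi_w": 2.0,
        "k_m": 10.0,
        "k_b": 10.0,
        "k_d": 10.0,
        "k_w": 10.0,
        "gamma_w": 20.0,
        "beta": 0.0,
    }


def write_example_configs(outdir: str | Path, seeds: tuple[int, ...] = (1, 2, 3)) -> list[Path]:
    """Write example configuration files: the packaged national defaults,
    the hand-checkable toy set, and random sets with recorded seeds."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    from .parameters import default_config

    for name, doc in (
        ("defaults.yaml", default_config()),
        ("toy_ledger.yaml", toy_ledger_config()),
    ):
        path = outdir / name
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
        written.append(path)

    for seed in seeds:
        p = random_parameter_set(seed)
        doc = {
            "seed": int(seed),
            "prevalence": p.prevalence,
            "pop": p.initial_population,
            "theta_m": p.entry_share[TreatmentGroup.MMT],
            "theta_b": p.entry_share[TreatmentGroup.BMT],
            "theta_d": p.entry_share[TreatmentGroup.DETOX],
            "theta_w": p.entry_share[_W],
            "b_m": p.retention[TreatmentGroup.MMT],
            "b_b": p.retention[TreatmentGroup.BMT],
            "psi_m": p.success[TreatmentGroup.MMT],
            "psi_b": p.success[TreatmentGroup.BMT],
            "psi_d": p.success[TreatmentGroup.DETOX],
            "psi_w": p.success[_W],
            "k_m": p.death[TreatmentGroup.MMT],
            "k_b": p.death[TreatmentGroup.BMT],
            "k_d": p.death[TreatmentGroup.DETOX],
            "k_w": p.death[_W],
            "gamma_w": p.heroin_transition,
            "beta": p.growth.rate_percent,
        }
        doc = {
            k: (float(v) if isinstance(v, (int, float, np.floating)) and k != "seed" else v)
            for k, v in doc.items()
        }
        path = outdir / f"random_seed{seed}.yaml"
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
        written.append(path)
    return written
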