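"""Monte-Carlo propagation of parameter uncertainty.

Interval estimates for scenario contrasts are produced by perturbing the
annual probabilities around their point values, re-running both the
baseline and the alternative scenario with the *same* drawn parameter
set (common random parameters couple the two arms and shrink contrast
variance), and taking percentile bounds of the per-draw statistics.

Two perturbation families are available, both parameterized by a
relative standard deviation on the point value:

``truncnorm``
    Normal on the percent scale, truncated to [0, 100] (default).
``beta``
    Beta on the fraction scale with matching mean and standard
    deviation.

Entry shares are perturbed jointly and renormalized to sum to 100;
discontinuation probabilities are re-derived after each draw so every
sampled set satisfies the outflow closures.  Draws are addressed by
``(seed, draw_index)`` substreams, so results are independent of
evaluation order and bit-for-bit reproducible on one platform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy import stats

from .comparison import cumulative_window, decade_theta, per_year_change
from .dynamics import Trajectory, run_scenario
from .parameters import (
    GROUPS,
    TREATED_GROUPS,
    ParameterSet,
    ParameterValidationError,
    TreatmentGroup,
    derive_discontinuation,
)

__all__ = [
    "UncertaintySpec",
    "Statistic",
    "IntervalEstimate",
    "sample_parameter_set",
    "monte_carlo_comparison",
]


@dataclass(frozen=True)
class UncertaintySpec:
    """Perturbation model for probabilistic sensitivity analysis.

    ``rel_sd`` is the relative standard deviation applied to every
    probability (0 collapses every draw to the point values).  Parameters
    are drawn independently of one another.
    """

    rel_sd: float = 0.05
    distribution: Literal["truncnorm", "beta"] = "truncnorm"
    draws: int = 1000
    seed: int = 0
    level: float = 0.95

    def __post_init__(self) -> None:
        if self.draws < 2:
            raise ValueError("draws must be >= 2")
        if self.rel_sd < 0:
            raise ValueError("rel_sd must be >= 0")
        if not (0 < self.level < 1):
            raise ValueError("level must be in (0, 1)")


@dataclass(frozen=True)
class Statistic:
    """A scalar scenario-contrast statistic evaluated per draw.

    kinds:
      - ``year_relative``: relative change (%) of an outcome at ``year``
      - ``decade_percent``: decade statistic times ten, for ``decade``
      - ``cumulative_change``: summed absolute change over ``window``
        (inclusive year pair; defaults to the whole horizon)
    """

    kind: Literal["year_relative", "decade_percent", "cumulative_change"]
    outcome: str
    year: int = 1
    decade: int = 1
    window: tuple[int, int] | None = None

    def evaluate(self, alt: Trajectory, base: Trajectory) -> float:
        if self.kind == "year_relative":
            comp = per_year_change(alt, base, self.outcome)
            idx = self.year - 1
            if not (0 <= idx < base.horizon):
                raise ValueError(f"year {self.year} outside horizon")
            if not comp.rel_defined[idx]:
                raise ParameterValidationError(
                    f"baseline {self.outcome} is zero in year {self.year}"
                )
            return float(comp.rel_change_pct[idx])
        if self.kind == "decade_percent":
            return decade_theta(alt, base, self.outcome, self.decade).percent
        if self.kind == "cumulative_change":
            first, last = self.window or (1, base.horizon)
            return cumulative_window(alt, self.outcome, first, last) - (
                cumulative_window(base, self.outcome, first, last)
            )
        raise ValueError(f"unknown statistic kind {self.kind!r}")


@dataclass(frozen=True)
class IntervalEstimate:
    """Percentile interval around the unperturbed point estimate.

    The point is computed from the unperturbed parameters, so percentile
    bounds are not guaranteed to bracket it; ``lower <= upper`` always
    holds.
    """

    point: float
    lower: float
    upper: float
    level: float
    draws: int
    excluded: int
    seed: int


def _draw_value(
    rng: np.random.Generator, value: float, spec: UncertaintySpec
) -> float:
    """One perturbed probability (percent scale), guaranteed in [0, 100]."""
    if spec.rel_sd == 0 or value == 0.0:
        return value
    sd = spec.rel_sd * value
    if spec.distribution == "truncnorm":
        a = (0.0 - value) / sd
        b = (100.0 - value) / sd
        return float(stats.truncnorm.rvs(a, b, loc=value, scale=sd, random_state=rng))
    # beta on the fraction scale, mean m, sd rel_sd * m
    m = value / 100.0
    var = (spec.rel_sd * m) ** 2
    k = m * (1.0 - m) / var - 1.0
    if k <= 0:
        raise ParameterValidationError(
            f"rel_sd {spec.rel_sd} too large for a beta perturbation of "
            f"{value}%"
        )
    return float(rng.beta(m * k, (1.0 - m) * k) * 100.0)


def sample_parameter_set(
    p: ParameterSet, spec: UncertaintySpec, draw_index: int
) -> ParameterSet:
    """One perturbed, re-validated parameter set.

    Deterministic in ``(spec.seed, draw_index)``; independent of the
    order in which draws are requested.  Raises
    :class:`~opidyn.parameters.ParameterValidationError` when the drawn
    probabilities cannot close a treated group's outflow (counted as a
    failed draw by :func:`monte_carlo_comparison`).
    """
    if spec.rel_sd == 0:
        return p
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=(draw_index,))
    )
    shares = {g: _draw_value(rng, p.entry_share[g], spec) for g in GROUPS}
    total = sum(shares.values())
    if total <= 0:
        raise ParameterValidationError("drawn entry shares sum to zero")
    shares = {g: s * 100.0 / total for g, s in shares.items()}

    sampled = replace(
        p,
        entry_share=shares,
        retention={g: _draw_value(rng, v, spec) for g, v in p.retention.items()},
        success={g: _draw_value(rng, v, spec) for g, v in p.success.items()},
        death={g: _draw_value(rng, v, spec) for g, v in p.death.items()},
        heroin_transition=_draw_value(rng, p.heroin_transition, spec),
        discontinuation={},
    )
    return derive_discontinuation(sampled).validate()


def monte_carlo_comparison(
    p: ParameterSet,
    factor: float,
    horizon: int,
    mode: str,
    statistic: Statistic,
    spec: UncertaintySpec,
    coupled: bool = True,
    return_draws: bool = False,
):
    """Percentile interval for a scenario-contrast statistic.

    Per draw, the baseline (factor 1.0) and the alternative scenario are
    run with the same sampled parameters when ``coupled`` (the default;
    ``coupled=False`` samples the two arms independently and exists for
    variance diagnostics).  Failed draws — perturbations that cannot form
    a valid parameter set — are excluded and counted; more than 10%
    failures aborts with advice to reduce ``rel_sd``.

    Returns an :class:`IntervalEstimate`, or ``(estimate, draws_array)``
    when ``return_draws`` is set.
    """
    if spec.draws < 30:
        warnings.warn(
            f"only {spec.draws} Monte-Carlo draws; percentile intervals "
            "will be unstable",
            stacklevel=2,
        )
    base_point = run_scenario(p, 1.0, horizon, mode)
    alt_point = run_scenario(p, factor, horizon, mode)
    point = statistic.evaluate(alt_point, base_point)

    values: list[float] = []
    excluded = 0
    for i in range(spec.draws):
        try:
            draw = sample_parameter_set(p, spec, i)
            if coupled:
                draw_base = draw
            else:
                draw_base = sample_parameter_set(p, spec, spec.draws + i)
            base = run_scenario(draw_base, 1.0, horizon, mode)
            alt = run_scenario(draw, factor, horizon, mode)
            values.append(statistic.evaluate(alt, base))
        except (ParameterValidationError, ValueError):
            excluded += 1
    if excluded > 0.10 * spec.draws:
        raise ParameterValidationError(
            f"{excluded}/{spec.draws} Monte-Carlo draws invalid; "
            "reduce rel_sd"
        )

    arr = np.asarray(values)
    alpha = (1.0 - spec.level) / 2.0
    est = IntervalEstimate(
        point=point,
        lower=float(np.percentile(arr, 100.0 * alpha)),
        upper=float(np.percentile(arr, 100.0 * (1.0 - alpha))),
        level=spec.level,
        draws=len(values),
        excluded=excluded,
        seed=spec.seed,
    )
    return (est, arr) if return_draws else est
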