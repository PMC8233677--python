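"""Parameter set for the opium-dependence treatment model.

The model follows the opium-dependent population of Iran (ages 15-64)
through four mutually exclusive annual treatment states: methadone
maintenance (MMT), buprenorphine maintenance (BMT), detoxification with
relapse prevention (DETOX), and untreated / non-evidence-based care
(UNTREATED).  Every probability is stored on the *percent* scale, exactly
as the national point estimates are published, and converted to a
fraction only inside arithmetic.  This avoids transcription drift between
the configuration files, the reports, and the published tables.

The annual outflow of each treated compartment is constrained to close:
for the maintenance groups ``retention + death + discontinuation = 100``
and for DETOX ``success + death + discontinuation = 100``.  The
discontinuation probabilities are therefore derived, not free inputs
(see :func:`derive_discontinuation`).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from decimal import Decimal, ROUND_HALF_UP
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = [
    "TreatmentGroup",
    "TREATED_GROUPS",
    "GrowthSpec",
    "ParameterSet",
    "ConfigurationError",
    "ParameterValidationError",
    "ScenarioInfeasibleError",
    "load_parameters",
    "derive_discontinuation",
    "scale_coverage",
    "coverage_decomposition",
    "treated_coverage",
    "display_round",
]


class ConfigurationError(ValueError):
    """A configuration document is missing or malformed."""


class ParameterValidationError(ValueError):
    """A parameter value violates a model constraint."""


class ScenarioInfeasibleError(ValueError):
    """A requested coverage scenario cannot be represented (shares > 100%)."""


class TreatmentGroup(str, Enum):
    """The four annual states an opium-dependent person can occupy.

    DETOX denotes detoxification followed by relapse-prevention care
    (psychosocial interventions, self-help groups, naltrexone).
    UNTREATED covers both no treatment and non-evidence-based treatment.
    """

    MMT = "MMT"
    BMT = "BMT"
    DETOX = "DETOX"
    UNTREATED = "UNTREATED"


GROUPS: tuple[TreatmentGroup, ...] = tuple(TreatmentGroup)
TREATED_GROUPS: tuple[TreatmentGroup, ...] = (
    TreatmentGroup.MMT,
    TreatmentGroup.BMT,
    TreatmentGroup.DETOX,
)

# ASCII aliases for the published symbols, used as configuration keys.
_SHARE_KEYS = {
    TreatmentGroup.MMT: "theta_m",
    TreatmentGroup.BMT: "theta_b",
    TreatmentGroup.DETOX: "theta_d",
    TreatmentGroup.UNTREATED: "theta_w",
}
_RETENTION_KEYS = {TreatmentGroup.MMT: "b_m", TreatmentGroup.BMT: "b_b"}
_SUCCESS_KEYS = {
    TreatmentGroup.MMT: "psi_m",
    TreatmentGroup.BMT: "psi_b",
    TreatmentGroup.DETOX: "psi_d",
    TreatmentGroup.UNTREATED: "psi_w",
}
_DEATH_KEYS = {
    TreatmentGroup.MMT: "k_m",
    TreatmentGroup.BMT: "k_b",
    TreatmentGroup.DETOX: "k_d",
    TreatmentGroup.UNTREATED: "k_w",
}
_PHI_KEYS = {
    TreatmentGroup.MMT: "phi_m",
    TreatmentGroup.BMT: "phi_b",
    TreatmentGroup.DETOX: "phi_d",
}

_SHARE_SUM_TOL = 1e-9
_FLOW_SUM_TOL = 1e-6


def display_round(x: float, ndigits: int = 2) -> float:
    """Half-up rounding for human-readable reports.

    Banker's rounding (Python's default) would print 35.625 as 35.62;
    published tables round half away from zero, so reports do too.
    Internal arithmetic never rounds.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class GrowthSpec:
    """Annual demographic growth of the dependent population (``beta``).

    Either a constant annual rate in percent, or an explicit per-step
    sequence of growth *factors* (year t -> t+1 multipliers).  Exactly one
    of the two is set.
    """

    rate_percent: float | None = None
    factors: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if (self.rate_percent is None) == (self.factors is None):
            raise ConfigurationError(
                "growth spec requires exactly one of rate_percent or factors"
            )
        if self.factors is not None and any(f <= 0 for f in self.factors):
            raise ParameterValidationError("growth factors must be positive")

    @classmethod
    def constant(cls, rate_percent: float) -> "GrowthSpec":
        return cls(rate_percent=rate_percent)

    @classmethod
    def from_series(cls, factors) -> "GrowthSpec":
        return cls(factors=tuple(float(f) for f in factors))

    @classmethod
    def from_total(cls, total_percent: float, steps: int) -> "GrowthSpec":
        """Constant rate calibrated so ``steps`` annual increments compound
        to ``total_percent`` overall growth."""
        if steps < 1:
            raise ConfigurationError("growth calibration needs steps >= 1")
        rate = ((1.0 + total_percent / 100.0) ** (1.0 / steps) - 1.0) * 100.0
        return cls(rate_percent=rate)

    def cumulative_factor(self, steps: int) -> float:
        """Total growth multiplier over ``steps`` annual increments."""
        if steps < 0:
            raise ValueError("steps must be >= 0")
        if self.factors is not None:
            if steps > len(self.factors):
                raise ConfigurationError(
                    f"growth series has {len(self.factors)} steps, "
                    f"{steps} requested"
                )
            return math.prod(self.factors[:steps])
        return (1.0 + self.rate_percent / 100.0) ** steps


@dataclass(frozen=True)
class ParameterSet:
    """Full annual-probability parameterization of the treatment model.

    All probabilities are percentages.  ``entry_share`` allocates the
    dependent population across the four groups at the start of a year and
    must sum to 100.  ``retention`` is defined for the maintenance groups
    only; ``discontinuation`` for the three treated groups (derived).
    ``mortality_scale`` is a dimensionless calibration multiplier applied
    to every death probability (default 1, i.e. published rates as-is).
    """

    prevalence: float
    initial_population: float
    entry_share: Mapping[TreatmentGroup, float]
    retention: Mapping[TreatmentGroup, float]
    success: Mapping[TreatmentGroup, float]
    death: Mapping[TreatmentGroup, float]
    heroin_transition: float
    growth: GrowthSpec
    discontinuation: Mapping[TreatmentGroup, float] = field(default_factory=dict)
    mortality_scale: float = 1.0

    # -- helpers -----------------------------------------------------------
    def stay_probability(self, group: TreatmentGroup) -> float:
        """Percent of a treated group remaining in that group at year end.

        Retention for the maintenance groups; for DETOX (a completed
        one-year episode) the completers-with-abstinence fraction plays
        that role — the only closure under which the three published
        discontinuation probabilities are all reproduced exactly.
        """
        if group in _RETENTION_KEYS:
            return self.retention[group]
        if group is TreatmentGroup.DETOX:
            return self.success[group]
        raise KeyError(f"no stay probability for {group}")

    def validate(self) -> "ParameterSet":
        """Check every structural invariant; return self if consistent."""
        def _check_pct(name: str, v: float, lo: float = 0.0) -> None:
            if not (lo <= v <= 100.0) or not math.isfinite(v):
                raise ParameterValidationError(
                    f"{name} = {v!r} outside [{lo}, 100]"
                )

        if not (0.0 < self.prevalence < 100.0):
            raise ParameterValidationError(
                f"prevalence = {self.prevalence!r} outside (0, 100)"
            )
        if not self.initial_population > 0:
            raise ParameterValidationError("pop must be > 0")
        if self.mortality_scale < 0:
            raise ParameterValidationError("mortality_scale must be >= 0")

        for g in GROUPS:
            _check_pct(_SHARE_KEYS[g], self.entry_share[g])
            _check_pct(_SUCCESS_KEYS[g], self.success[g])
            _check_pct(_DEATH_KEYS[g], self.death[g])
        for g in _RETENTION_KEYS:
            _check_pct(_RETENTION_KEYS[g], self.retention[g])
        _check_pct("gamma_w", self.heroin_transition)

        share_sum = sum(self.entry_share[g] for g in GROUPS)
        if abs(share_sum - 100.0) > _SHARE_SUM_TOL:
            raise ParameterValidationError(
                f"entry shares sum to {share_sum!r}, expected 100"
            )

        kw = self.death[TreatmentGroup.UNTREATED]
        if kw + self.heroin_transition > 100.0 + _SHARE_SUM_TOL:
            raise ParameterValidationError(
                "k_w + gamma_w exceed 100%: untreated outflow infeasible"
            )

        for g in TREATED_GROUPS:
            if g not in self.discontinuation:
                raise ParameterValidationError(
                    f"discontinuation missing for {g.value}; "
                    "call derive_discontinuation first"
                )
            _check_pct(_PHI_KEYS[g], self.discontinuation[g])
            closure = (
                self.stay_probability(g)
                + self.death[g]
                + self.discontinuation[g]
            )
            if abs(closure - 100.0) > _FLOW_SUM_TOL:
                raise ParameterValidationError(
                    f"outflow of {g.value} sums to {closure!r}, expected 100"
                )
        if TreatmentGroup.UNTREATED in self.discontinuation:
            raise ParameterValidationError(
                "discontinuation is undefined for UNTREATED"
            )
        return self


def derive_discontinuation(p: ParameterSet) -> ParameterSet:
    """Close each treated group's annual outflow.

    phi = 100 - stay - death, where *stay* is retention for MMT/BMT and
    treatment success for DETOX.  Idempotent: re-deriving an already
    closed set returns the same values.
    """
    phi: dict[TreatmentGroup, float] = {}
    for g in TREATED_GROUPS:
        value = 100.0 - p.stay_probability(g) - p.death[g]
        if not (0.0 <= value <= 100.0):
            raise ParameterValidationError(
                f"derived {_PHI_KEYS[g]} = {value!r} outside [0, 100]"
            )
        phi[g] = value
    return replace(p, discontinuation=phi)


def treated_coverage(p: ParameterSet) -> float:
    """Total annual treatment coverage: percent of dependents entering any
    evidence-based treatment group."""
    return sum(p.entry_share[g] for g in TREATED_GROUPS)


def scale_coverage(p: ParameterSet, factor: float) -> ParameterSet:
    """Rescale the treated entry shares by ``factor``.

    The within-treatment mix (MMT : BMT : DETOX) is preserved and the
    UNTREATED share absorbs the complement so the shares still sum to 100.
    ``factor`` is the scenario dial: 0.75 is a 25% coverage cut, 1.25 a
    25% expansion.
    """
    if not factor > 0:
        raise ScenarioInfeasibleError("coverage factor must be > 0")
    shares = {g: p.entry_share[g] * factor for g in TREATED_GROUPS}
    total = sum(shares.values())
    if total > 100.0 + _SHARE_SUM_TOL:
        raise ScenarioInfeasibleError(
            f"scaled treated shares sum to {total:.2f}% > 100%"
        )
    shares[TreatmentGroup.UNTREATED] = 100.0 - total
    return replace(p, entry_share=shares)


def coverage_decomposition(
    total_coverage: float,
    detox_fraction_of_total: float,
    mmt_fraction_of_maintenance: float,
) -> dict[TreatmentGroup, float]:
    """Split total treatment coverage into per-group entry shares.

    ``detox_fraction_of_total`` is the percent of all coverage that is
    detox + relapse prevention; the remainder is maintenance treatment,
    split between MMT and BMT by ``mmt_fraction_of_maintenance``.  The
    UNTREATED share is the complement of total coverage.  Values are
    returned unrounded; round only for display.
    """
    for name, v in (
        ("total_coverage", total_coverage),
        ("detox_fraction_of_total", detox_fraction_of_total),
        ("mmt_fraction_of_maintenance", mmt_fraction_of_maintenance),
    ):
        if not (0.0 <= v <= 100.0):
            raise ParameterValidationError(f"{name} = {v!r} outside [0, 100]")
    detox = total_coverage * detox_fraction_of_total / 100.0
    maintenance = total_coverage - detox
    mmt = maintenance * mmt_fraction_of_maintenance / 100.0
    bmt = maintenance - mmt
    return {
        TreatmentGroup.MMT: mmt,
        TreatmentGroup.BMT: bmt,
        TreatmentGroup.DETOX: detox,
        TreatmentGroup.UNTREATED: 100.0 - total_coverage,
    }


# -- configuration loading -------------------------------------------------

_FIELD_DESCRIPTIONS = {
    "prevalence": "prevalence of opium dependence among ages 15-64, percent",
    "pop": "number of opium-dependent persons at year 1",
    "theta_m": "annual entry share, MMT",
    "theta_b": "annual entry share, BMT",
    "theta_d": "annual entry share, detox + relapse prevention",
    "theta_w": "annual entry share, untreated",
    "b_m": "one-year retention in MMT",
    "b_b": "one-year retention in BMT",
    "psi_m": "treatment success (month-12 abstinence), MMT",
    "psi_b": "treatment success, BMT",
    "psi_d": "treatment success, detox + relapse prevention",
    "psi_w": "spontaneous abstinence, untreated",
    "k_m": "annual death probability, MMT",
    "k_b": "annual death probability, BMT",
    "k_d": "annual death probability, detox + relapse prevention",
    "k_w": "annual death probability, untreated",
    "gamma_w": "annual transition to heroin dependence, untreated",
    "beta": "annual demographic growth of the dependent population",
}

_REQUIRED_KEYS = tuple(_FIELD_DESCRIPTIONS)


def _require(doc: Mapping[str, Any], key: str) -> Any:
    if key not in doc or doc[key] is None:
        raise ConfigurationError(
            f"missing required parameter '{key}' "
            f"({_FIELD_DESCRIPTIONS.get(key, key)})"
        )
    return doc[key]


def _parse_growth(raw: Any) -> GrowthSpec:
    if isinstance(raw, GrowthSpec):
        return raw
    if isinstance(raw, (int, float)):
        return GrowthSpec.constant(float(raw))
    if isinstance(raw, (list, tuple)):
        return GrowthSpec.from_series(raw)
    if isinstance(raw, Mapping):
        if "rate_percent" in raw:
            return GrowthSpec.constant(float(raw["rate_percent"]))
        if "factors" in raw:
            return GrowthSpec.from_series(raw["factors"])
        if "total_percent" in raw and "steps" in raw:
            return GrowthSpec.from_total(
                float(raw["total_percent"]), int(raw["steps"])
            )
    raise ConfigurationError(
        "beta must be a rate in percent, a list of growth factors, or a "
        "mapping with rate_percent / factors / (total_percent, steps)"
    )


def default_config() -> dict[str, Any]:
    """The packaged national point-estimate configuration (2019 baseline)."""
    text = (
        resources.files("opidyn").joinpath("data/table1_defaults.yaml").read_text()
    )
    return yaml.safe_load(text)


def load_parameters(
    config: str | Path | Mapping[str, Any] | None = None,
) -> ParameterSet:
    """Build a validated :class:`ParameterSet` from a configuration.

    ``config`` may be ``None`` (packaged national defaults), a mapping, or
    a path to a YAML or JSON document.  Missing discontinuation entries
    are derived; explicitly supplied ones are cross-checked against the
    derived closure (tolerance 0.02, the published rounding grain) and
    replaced by the exact derived values.
    """
    if config is None:
        doc: Mapping[str, Any] = default_config()
    elif isinstance(config, Mapping):
        doc = config
    else:
        path = Path(config)
        if not path.exists():
            raise ConfigurationError(f"config file not found: {path}")
        text = path.read_text()
        doc = (
            json.loads(text)
            if path.suffix.lower() == ".json"
            else yaml.safe_load(text)
        )
        if not isinstance(doc, Mapping):
            raise ConfigurationError(f"config {path} is not a mapping")

    p = ParameterSet(
        prevalence=float(_require(doc, "prevalence")),
        initial_population=float(_require(doc, "pop")),
        entry_share={g: float(_require(doc, k)) for g, k in _SHARE_KEYS.items()},
        retention={g: float(_require(doc, k)) for g, k in _RETENTION_KEYS.items()},
        success={g: float(_require(doc, k)) for g, k in _SUCCESS_KEYS.items()},
        death={g: float(_require(doc, k)) for g, k in _DEATH_KEYS.items()},
        heroin_transition=float(_require(doc, "gamma_w")),
        growth=_parse_growth(_require(doc, "beta")),
        mortality_scale=float(doc.get("mortality_scale", 1.0)),
    )
    p = derive_discontinuation(p)
    for g, key in _PHI_KEYS.items():
        if key in doc and doc[key] is not None:
            supplied = float(doc[key])
            if abs(supplied - p.discontinuation[g]) > 0.02:
                raise ConfigurationError(
                    f"supplied {key} = {supplied} inconsistent with derived "
                    f"closure {p.discontinuation[g]:.4f}"
                )
    return p.validate()
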