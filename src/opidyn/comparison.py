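"""Scenario contrasts: per-year changes and the decade change statistic.

An alternative-coverage trajectory ``B`` is compared with a baseline
(status quo) trajectory ``A`` outcome by outcome.  Per year the absolute
change is ``B_t - A_t`` and the relative change ``(B_t - A_t) / A_t``
(positive when the alternative exceeds the baseline).  Per decade the
summary statistic is

    theta = sum over the decade's ten years of (B_t - A_t) / A_t,

reported alongside the cumulative absolute change; the decade's
percentage change is defined as ``theta * 10``.  Decades partition a
30-year run as years 1-10, 11-20 and 21-30.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .dynamics import OUTCOME_NAMES, Trajectory

__all__ = [
    "ScenarioComparison",
    "DecadeSummary",
    "ComparisonError",
    "per_year_change",
    "decade_theta",
    "decade_percent_from_theta",
    "cumulative_window",
    "decade_table",
    "load_decade_reference",
]

DECADE_LENGTH = 10


class ComparisonError(ValueError):
    """Trajectories cannot be contrasted (mismatched horizon or mode)."""


@dataclass(frozen=True)
class ScenarioComparison:
    """Per-year contrast of one outcome between two trajectories.

    ``rel_defined`` flags the years where the baseline is non-zero; the
    relative change is reported only there (it is left 0 and flagged,
    never NaN-propagated, where the baseline vanishes).
    """

    outcome: str
    base_label: str
    alt_label: str
    years: np.ndarray
    base: np.ndarray
    alt: np.ndarray

    @property
    def abs_change(self) -> np.ndarray:
        return self.alt - self.base

    @property
    def rel_defined(self) -> np.ndarray:
        return self.base != 0.0

    @property
    def rel_change(self) -> np.ndarray:
        """Relative change as fractions, 0 where undefined (see rel_defined)."""
        return np.divide(
            self.abs_change,
            self.base,
            out=np.zeros_like(self.base, dtype=float),
            where=self.rel_defined,
        )

    @property
    def rel_change_pct(self) -> np.ndarray:
        return self.rel_change * 100.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "outcome": self.outcome,
                "year": self.years,
                "base": self.base,
                "alt": self.alt,
                "abs_change": self.abs_change,
                "rel_change_pct": self.rel_change_pct,
                "rel_defined": self.rel_defined,
            }
        )


@dataclass(frozen=True)
class DecadeSummary:
    """Cumulative and relative change of one outcome over one decade."""

    outcome: str
    decade: int
    cumulative: float
    theta: float

    @property
    def percent(self) -> float:
        return decade_percent_from_theta(self.theta)


def decade_percent_from_theta(theta: float) -> float:
    """Decade percentage change implied by the decade statistic."""
    return theta * 10.0


def _check_pair(alt: Trajectory, base: Trajectory) -> None:
    if alt.horizon != base.horizon:
        raise ComparisonError(
            f"horizons differ: alt {alt.horizon} vs base {base.horizon}"
        )
    if alt.mode != base.mode:
        raise ComparisonError(
            f"cross-mode comparison refused: alt {alt.mode!r} vs "
            f"base {base.mode!r}"
        )


def per_year_change(
    alt: Trajectory, base: Trajectory, outcome: str
) -> ScenarioComparison:
    """Yearly absolute and relative change of ``outcome``, alt vs base."""
    if outcome not in OUTCOME_NAMES:
        raise KeyError(f"unknown outcome {outcome!r}; expected {OUTCOME_NAMES}")
    _check_pair(alt, base)
    return ScenarioComparison(
        outcome=outcome,
        base_label=base.scenario,
        alt_label=alt.scenario,
        years=base.years,
        base=base.series(outcome),
        alt=alt.series(outcome),
    )


def decade_theta(
    alt: Trajectory, base: Trajectory, outcome: str, decade: int
) -> DecadeSummary:
    """Decade statistic for ``decade`` (1-based, ten model years each)."""
    if decade < 1:
        raise ComparisonError(f"decade must be >= 1, got {decade}")
    comp = per_year_change(alt, base, outcome)
    last = decade * DECADE_LENGTH
    if last > alt.horizon:
        raise ComparisonError(
            f"decade {decade} needs horizon >= {last}, have {alt.horizon}"
        )
    sel = slice((decade - 1) * DECADE_LENGTH, last)
    if not comp.rel_defined[sel].all():
        raise ComparisonError(
            f"baseline {outcome} vanishes inside decade {decade}; "
            "theta undefined"
        )
    return DecadeSummary(
        outcome=outcome,
        decade=decade,
        cumulative=float(comp.abs_change[sel].sum()),
        theta=float(comp.rel_change[sel].sum()),
    )


def cumulative_window(
    traj: Trajectory, outcome: str, first_year: int, last_year: int
) -> float:
    """Sum of one outcome over the inclusive year window."""
    if not (1 <= first_year <= last_year <= traj.horizon):
        raise ComparisonError(
            f"window [{first_year}, {last_year}] outside horizon "
            f"1..{traj.horizon}"
        )
    return float(traj.series(outcome)[first_year - 1 : last_year].sum())


def decade_table(
    base: Trajectory, alternatives: Mapping[float, Trajectory]
) -> pd.DataFrame:
    """Decade-by-scenario grid of cumulative changes and theta.

    One row per (outcome, decade, coverage factor); mirrors the layout in
    which decade summaries are conventionally reported.
    """
    n_decades = base.horizon // DECADE_LENGTH
    rows = []
    for outcome in OUTCOME_NAMES:
        for decade in range(1, n_decades + 1):
            for factor, alt in alternatives.items():
                s = decade_theta(alt, base, outcome, decade)
                rows.append(
                    {
                        "outcome": outcome,
                        "decade": decade,
                        "factor": factor,
                        "coverage_pct": sum(
                            v
                            for g, v in alt.states[0].stock.items()
                            if g.value != "UNTREATED"
                        )
                        / alt.states[0].total
                        * 100.0,
                        "cumulative": s.cumulative,
                        "theta": s.theta,
                        "percent": s.percent,
                    }
                )
    return pd.DataFrame(rows)


def load_decade_reference() -> pd.DataFrame:
    """Published decade summaries (cumulative change and theta) for the
    six coverage scenarios, packaged as reference input data."""
    with resources.files("opidyn").joinpath("data/table2_reference.csv").open() as fh:
        return pd.read_csv(fh)
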