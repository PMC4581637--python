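"""Effectiveness: lives saved converted to discounted life-years gained.

National lives-saved estimates (typically produced by an external
coverage-to-mortality model such as the Lives Saved Tool) are scaled to the
study district by population share, multiplied by the remaining life
expectancy at the age death was averted, and discounted to present value
with the standard annuity formula.

Four population groups are distinguished: stillbirths, deaths under one
month, deaths at 1-59 months, and maternal deaths. Negative lives saved
(coverage shifts that increase deaths in one group) propagate through with
their sign.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .errors import InputError

__all__ = [
    "Group",
    "LivesSavedRecord",
    "PopulationContext",
    "LifeExpectancyTable",
    "LYGResult",
    "scale_to_district",
    "discounted_lyg_per_death",
    "compute_lyg",
    "per_100k",
]


class Group(str, enum.Enum):
    """Population groups in which averted deaths are classified."""

    STILLBIRTH = "stillbirth"
    NEONATAL_UNDER_1M = "neonatal_under_1m"
    CHILD_1_59M = "child_1_59m"
    MATERNAL = "maternal"


@dataclass(frozen=True)
class LivesSavedRecord:
    """Lives saved in one population group, at national scale."""

    group: Group
    lives_saved: float
    per_100k: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "group", Group(self.group))


@dataclass(frozen=True)
class PopulationContext:
    """District and national populations used to scale national estimates."""

    district_population: float
    national_population: float

    def __post_init__(self) -> None:
        if self.district_population <= 0 or self.national_population <= 0:
            raise InputError("populations must be > 0")
        if self.district_population > self.national_population:
            raise InputError(
                "district_population must not exceed national_population"
            )

    @property
    def share(self) -> float:
        return self.district_population / self.national_population


@dataclass(frozen=True)
class LifeExpectancyTable:
    """Remaining life expectancy (years) at the time death is averted.

    Must contain an entry for every :class:`Group`. Stillbirths and
    neonatal deaths conventionally use life expectancy at birth; 1-59-month
    deaths the expectancy conditional on surviving infancy; maternal deaths
    the remaining expectancy at the mean maternal age.
    """

    values: Mapping[Group, float]

    def __post_init__(self) -> None:
        values = {Group(g): float(v) for g, v in self.values.items()}
        for g, v in values.items():
            if v < 0:
                raise InputError(f"life expectancy for {g.value} must be >= 0")
        object.__setattr__(self, "values", values)

    def __getitem__(self, group: Group | str) -> float:
        group = Group(group)
        try:
            return self.values[group]
        except KeyError:
            raise InputError(
                f"life-expectancy table has no entry for group {group.value!r}"
            ) from None


@dataclass(frozen=True)
class LYGResult:
    """Discounted life-years gained per group; total is the exact sum."""

    per_group: Mapping[Group, float]
    total: float
    discount_rate: float


def scale_to_district(national_lives: float, ctx: PopulationContext) -> float:
    """Scale a national lives-saved estimate to the district by population share."""
    return national_lives * ctx.share


def discounted_lyg_per_death(remaining_le, rate):
    """Discounted life-years gained per death averted.

    The present value of one life-year per year over ``remaining_le`` years
    at annual discount rate ``rate``: ``(1 - (1 + rate)**-E) / rate``,
    extended continuously to fractional years, with the undiscounted limit
    ``E`` at zero rate. Accepts scalars or numpy arrays in either argument.
    """
    le = np.asarray(remaining_le, dtype=float)
    r = np.asarray(rate, dtype=float)
    if np.any(le < 0):
        raise InputError("remaining life expectancy must be >= 0")
    if np.any(r < 0):
        raise InputError("discount rate must be >= 0")
    # where() evaluates both branches; guard the rate=0 division. The
    # expm1/log1p form avoids cancellation at very small rates.
    safe_r = np.where(r == 0, 1.0, r)
    out = np.where(r == 0, le, -np.expm1(-le * np.log1p(safe_r)) / safe_r)
    if np.ndim(remaining_le) == 0 and np.ndim(rate) == 0:
        return float(out)
    return out


def compute_lyg(
    table: Iterable[LivesSavedRecord],
    le: LifeExpectancyTable,
    ctx: PopulationContext,
    rate: float = 0.03,
) -> LYGResult:
    """District-level discounted life-years gained, by group and in total.

    Per group: ``scale_to_district(lives) * discounted_lyg_per_death(LE,
    rate)``. The total is the plain sum of the per-group values, so the
    result is exactly additive. Negative lives saved yield negative LYG.
    """
    per_group: dict[Group, float] = {}
    for record in table:
        lives = scale_to_district(record.lives_saved, ctx)
        factor = discounted_lyg_per_death(le[record.group], rate)
        per_group[record.group] = per_group.get(record.group, 0.0) + lives * factor
    return LYGResult(
        per_group=per_group, total=float(sum(per_group.values())), discount_rate=rate
    )


def per_100k(lives: float, population: float) -> float:
    """Lives saved per 100 000 population."""
    if population <= 0:
        raise InputError(f"population must be > 0, got {population}")
    return lives * 100_000.0 / population
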