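"""Programme costing: annuitization, attrition and overhead.

An itemized cost ledger (the structure of a programme costing table:
start-up, direct recurrent, indirect recurrent and volunteer line items) is
turned into a total annual programme cost by

* annuitizing one-off start-up (capital) costs over the programme's useful
  life with the standard annuity factor,
* inflating pre-service training costs by ``1 / (1 - attrition_rate)`` to
  account for trained workers lost after training, and
* adding a percentage overhead on recurrent costs to represent expenditure
  incurred at higher administrative levels.

All amounts are in international dollars (PPP-adjusted); conversion from
local currency happens upstream, never per line item.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable

from .errors import InputError

__all__ = [
    "CostCategory",
    "CostComponent",
    "CostLedger",
    "CostBreakdown",
    "annuity_factor",
    "equivalent_annual_cost",
    "apply_attrition",
    "overhead_cost",
    "total_annual_cost",
]


class CostCategory(str, enum.Enum):
    """The four costing categories of a community-based programme ledger."""

    START_UP = "start_up"
    DIRECT_RECURRENT = "direct_recurrent"
    INDIRECT_RECURRENT = "indirect_recurrent"
    VOLUNTEER = "volunteer"


@dataclass(frozen=True)
class CostComponent:
    """One line item of a programme cost ledger.

    Parameters
    ----------
    name
        Free-text label, e.g. ``"Pre-service training"``.
    category
        One of the four :class:`CostCategory` values.
    amount
        Cost in international dollars, non-negative.
    is_training
        Whether this is a pre-service training line subject to the
        attrition adjustment.
    annualized
        Whether ``amount`` is already an annual-equivalent figure. Raw
        capital outlays should set this ``False`` so they are annuitized.
    """

    name: str
    category: CostCategory
    amount: float
    is_training: bool = False
    annualized: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "category", CostCategory(self.category))
        if not math.isfinite(self.amount) or self.amount < 0:
            raise InputError(
                f"component {self.name!r}: amount must be finite and >= 0, "
                f"got {self.amount}"
            )


@dataclass(frozen=True)
class CostLedger:
    """An itemized district cost ledger plus its costing assumptions."""

    district_id: str
    components: tuple[CostComponent, ...]
    overhead_pct: float = 0.15
    attrition_rate: float = 0.0
    discount_rate: float = 0.03
    useful_life_years: float = 10.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple(self.components))
        if not 0 <= self.overhead_pct < 1:
            raise InputError(f"overhead_pct must be in [0, 1), got {self.overhead_pct}")
        if not 0 <= self.attrition_rate < 1:
            raise InputError(
                f"attrition_rate must be in [0, 1), got {self.attrition_rate}"
            )
        if self.discount_rate < 0:
            raise InputError(f"discount_rate must be >= 0, got {self.discount_rate}")
        if self.useful_life_years <= 0:
            raise InputError(
                f"useful_life_years must be > 0, got {self.useful_life_years}"
            )

    def subtotal(self, category: CostCategory | str) -> float:
        """Raw (unadjusted) sum of component amounts in one category."""
        category = CostCategory(category)
        return float(
            sum(c.amount for c in self.components if c.category is category)
        )


@dataclass(frozen=True)
class CostBreakdown:
    """Annual cost by category; ``total_annual`` is the exact sum of parts."""

    startup_annual: float
    direct_recurrent: float
    indirect_recurrent: float
    volunteer: float
    overhead: float
    total_annual: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "total_annual",
            self.startup_annual
            + self.direct_recurrent
            + self.indirect_recurrent
            + self.volunteer
            + self.overhead,
        )


def annuity_factor(rate: float, years: float) -> float:
    """Present value of a 1-dollar-per-year annuity over ``years`` years.

    ``(1 - (1 + rate)**-years) / rate`` for positive rates, with the
    zero-rate limit ``years``. Dividing a one-off capital cost by this
    factor yields its equivalent annual cost.
    """
    if years <= 0:
        raise InputError(f"years must be > 0, got {years}")
    if rate < 0:
        raise InputError(f"rate must be >= 0, got {rate}")
    if rate == 0:
        return float(years)
    # expm1/log1p form avoids cancellation at very small rates
    return -math.expm1(-years * math.log1p(rate)) / rate


def equivalent_annual_cost(startup_total: float, rate: float, years: float) -> float:
    """Spread a one-off start-up cost over its useful life.

    Returns the annual payment whose discounted stream over ``years`` years
    at ``rate`` equals ``startup_total``.
    """
    if startup_total < 0:
        raise InputError(f"startup_total must be >= 0, got {startup_total}")
    return startup_total / annuity_factor(rate, years)


def apply_attrition(training_cost: float, attrition_rate: float) -> float:
    """Inflate a training cost for post-training attrition.

    If a fraction ``attrition_rate`` of trained workers leaves after
    training, keeping one worker in post costs ``training_cost /
    (1 - attrition_rate)``.
    """
    if not 0 <= attrition_rate < 1:
        raise InputError(f"attrition_rate must be in [0, 1), got {attrition_rate}")
    return training_cost / (1.0 - attrition_rate)


def _effective_amount(
    comp: CostComponent, ledger: CostLedger, annualize_startup: bool
) -> float:
    amount = comp.amount
    if comp.is_training:
        amount = apply_attrition(amount, ledger.attrition_rate)
    if (
        annualize_startup
        and comp.category is CostCategory.START_UP
        and not comp.annualized
    ):
        amount = equivalent_annual_cost(
            amount, ledger.discount_rate, ledger.useful_life_years
        )
    return amount


def _category_totals(
    ledger: CostLedger, annualize_startup: bool
) -> dict[CostCategory, float]:
    totals = dict.fromkeys(CostCategory, 0.0)
    for comp in ledger.components:
        totals[comp.category] += _effective_amount(comp, ledger, annualize_startup)
    return totals


def overhead_cost(ledger: CostLedger, annualize_startup: bool = False) -> float:
    """Overhead as a percentage of recurrent (non-start-up) costs.

    The base is the sum of direct recurrent, indirect recurrent and
    volunteer costs; start-up costs are excluded.
    """
    totals = _category_totals(ledger, annualize_startup)
    base = (
        totals[CostCategory.DIRECT_RECURRENT]
        + totals[CostCategory.INDIRECT_RECURRENT]
        + totals[CostCategory.VOLUNTEER]
    )
    return ledger.overhead_pct * base


def total_annual_cost(
    ledger: CostLedger, annualize_startup: bool = False
) -> CostBreakdown:
    """Total annual programme cost with all adjustments applied.

    Training components are inflated for attrition; with
    ``annualize_startup=True``, start-up components not already expressed
    as annual equivalents are annuitized at the ledger's discount rate over
    its useful life. Overhead is then added on the recurrent base. An empty
    ledger yields an all-zero breakdown.
    """
    totals = _category_totals(ledger, annualize_startup)
    overhead = ledger.overhead_pct * (
        totals[CostCategory.DIRECT_RECURRENT]
        + totals[CostCategory.INDIRECT_RECURRENT]
        + totals[CostCategory.VOLUNTEER]
    )
    return CostBreakdown(
        startup_annual=totals[CostCategory.START_UP],
        direct_recurrent=totals[CostCategory.DIRECT_RECURRENT],
        indirect_recurrent=totals[CostCategory.INDIRECT_RECURRENT],
        volunteer=totals[CostCategory.VOLUNTEER],
        overhead=overhead,
    )
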