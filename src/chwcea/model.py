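"""The district decision model: parameters in, (cost, LYG) out.

Wires the costing and effectiveness calculations into a single callable
surface that the sensitivity analyses can perturb. The uncertain inputs
are the four cost-category subtotals (one parameter each, keeping tornado
plots readable), the overhead percentage, the attrition rate, the discount
rate, the useful life, and total life-years gained.

Cost-category parameters act as uniform multipliers on their line items,
so attrition and annuitization adjustments are re-derived at the perturbed
assumption values rather than baked into the sampled amount. The LYG
parameter likewise scales the lives-saved inputs, while the discount-rate
parameter re-discounts the underlying remaining-life-expectancy stream.
Evaluation is vectorized: any parameter may be a numpy array of draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .cost import CostCategory, CostLedger
from .effect import (
    LifeExpectancyTable,
    LivesSavedRecord,
    PopulationContext,
    discounted_lyg_per_death,
    scale_to_district,
)
from .sensitivity import ParameterRole, ParameterSpec

__all__ = ["DecisionModel", "CATEGORY_PARAMS"]

CATEGORY_PARAMS: dict[CostCategory, str] = {
    CostCategory.START_UP: "start_up_cost",
    CostCategory.DIRECT_RECURRENT: "direct_recurrent_cost",
    CostCategory.INDIRECT_RECURRENT: "indirect_recurrent_cost",
    CostCategory.VOLUNTEER: "volunteer_cost",
}


def _annuity_factor_vec(rate, years):
    r = np.asarray(rate, dtype=float)
    y = np.asarray(years, dtype=float)
    safe_r = np.where(r == 0, 1.0, r)
    return np.where(r == 0, y, -np.expm1(-y * np.log1p(safe_r)) / safe_r)


@dataclass
class DecisionModel:
    """Full cost-effectiveness pipeline for one district programme."""

    ledger: CostLedger
    lives: Sequence[LivesSavedRecord]
    life_table: LifeExpectancyTable
    context: PopulationContext
    annualize_startup: bool = False

    def __post_init__(self) -> None:
        self.lives = tuple(self.lives)
        # District-scaled lives and LE per record, frozen for vector reuse.
        self._district_lives = np.array(
            [scale_to_district(r.lives_saved, self.context) for r in self.lives]
        )
        self._le = np.array([self.life_table[r.group] for r in self.lives])

    # -- baseline ---------------------------------------------------------

    def _category_cost(self, category: CostCategory, attrition, rate, years):
        """Effective annual cost of one category at given assumption values."""
        attrition = np.asarray(attrition, dtype=float)
        total = 0.0
        af = None
        for comp in self.ledger.components:
            if comp.category is not category:
                continue
            amount = comp.amount / np.where(comp.is_training, 1.0 - attrition, 1.0)
            if (
                self.annualize_startup
                and category is CostCategory.START_UP
                and not comp.annualized
            ):
                if af is None:
                    af = _annuity_factor_vec(rate, years)
                amount = amount / af
            total = total + amount
        return total

    def _lyg_at_rate(self, rate):
        factors = discounted_lyg_per_death(
            self._le[:, None], np.atleast_1d(np.asarray(rate, dtype=float))[None, :]
        )
        out = np.sum(self._district_lives[:, None] * factors, axis=0)
        return out

    def baseline_means(self) -> dict[str, float]:
        """Baseline value of every model parameter."""
        led = self.ledger
        means = {
            name: float(
                self._category_cost(
                    cat, led.attrition_rate, led.discount_rate, led.useful_life_years
                )
            )
            for cat, name in CATEGORY_PARAMS.items()
        }
        means["overhead_pct"] = led.overhead_pct
        means["attrition_rate"] = led.attrition_rate
        means["discount_rate"] = led.discount_rate
        means["useful_life"] = led.useful_life_years
        means["lyg"] = float(self._lyg_at_rate(led.discount_rate)[0])
        return means

    def parameter_specs(
        self, dsa_fraction: float = 0.30, psa_fraction: float = 0.10
    ) -> list[ParameterSpec]:
        """Uncertain-input specs at the model's baseline means."""
        means = self.baseline_means()
        roles = {
            "start_up_cost": ParameterRole.COST_INPUT,
            "direct_recurrent_cost": ParameterRole.COST_INPUT,
            "indirect_recurrent_cost": ParameterRole.COST_INPUT,
            "volunteer_cost": ParameterRole.COST_INPUT,
            "overhead_pct": ParameterRole.OVERHEAD_PCT,
            "attrition_rate": ParameterRole.ATTRITION_RATE,
            "discount_rate": ParameterRole.DISCOUNT_RATE,
            "useful_life": ParameterRole.USEFUL_LIFE,
            "lyg": ParameterRole.LYG,
        }
        return [
            ParameterSpec(
                name=name,
                role=role,
                mean=means[name],
                dsa_fraction=dsa_fraction,
                psa_fraction=psa_fraction,
            )
            for name, role in roles.items()
        ]

    # -- evaluation -------------------------------------------------------

    def evaluate(self, values: Mapping[str, object]) -> tuple[np.ndarray, np.ndarray]:
        """Total annual cost and total LYG at the given parameter values.

        Inputs absent from ``values`` stay at baseline. Scalars and arrays
        broadcast; the outputs share the broadcast shape (0-d for all-scalar
        input).
        """
        means = self.baseline_means()
        get = lambda k: np.asarray(values.get(k, means[k]), dtype=float)

        attrition = get("attrition_rate")
        rate = get("discount_rate")
        years = get("useful_life")

        category_costs = {}
        for cat, name in CATEGORY_PARAMS.items():
            base = self._category_cost(cat, attrition, rate, years)
            mean = means[name]
            # Category parameters scale line items uniformly around their
            # baseline effective subtotal; a zero-cost category stays zero.
            multiplier = get(name) / mean if mean > 0 else 1.0
            category_costs[name] = base * multiplier

        recurrent = (
            category_costs["direct_recurrent_cost"]
            + category_costs["indirect_recurrent_cost"]
            + category_costs["volunteer_cost"]
        )
        cost = (
            category_costs["start_up_cost"] + recurrent + get("overhead_pct") * recurrent
        )

        lyg_mean = means["lyg"]
        rate_arr = np.atleast_1d(rate)
        lyg_at_rate = self._lyg_at_rate(rate_arr)
        if rate_arr.shape == (1,):
            lyg_at_rate = lyg_at_rate[0]
        lyg_scale = get("lyg") / lyg_mean if lyg_mean != 0 else 1.0
        lyg = lyg_scale * lyg_at_rate

        cost, lyg = np.broadcast_arrays(np.asarray(cost), np.asarray(lyg))
        return cost, lyg

    def baseline(self) -> tuple[float, float]:
        """(total annual cost, total discounted LYG) at baseline."""
        cost, lyg = self.evaluate({})
        return float(cost), float(lyg)
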