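"""Packaged district fixtures and synthetic scenario generation.

``load_fixture`` returns the four study districts (Shebedino in Ethiopia,
south-west Sumba and Takala in Indonesia, Kasarani in Kenya) transcribed at
published precision, with calibrated remaining-life-expectancy tables and
documented internal rounding residues.

``generate_scenario`` builds synthetic programmes with known ground truth:
random cost ledgers, lives-saved tables and life tables whose deterministic
pipeline output (total cost, total LYG, ICER) is known by construction, so
estimation and sensitivity machinery can be tested end to end without any
external data.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import yaml

from .cea import icer as _icer
from .cost import CostCategory, CostComponent, CostLedger, total_annual_cost
from .effect import (
    Group,
    LifeExpectancyTable,
    LivesSavedRecord,
    PopulationContext,
    compute_lyg,
)
from .errors import InputError
from .io import read_cost_components, read_life_table, read_lives_saved

__all__ = ["DISTRICTS", "DistrictFixture", "load_fixture", "ScenarioSpec",
           "generate_scenario", "Scenario"]

DISTRICTS = ("shebedino", "sumba", "takala", "kasarani")

# Typical remaining life expectancies (years) used when synthesizing life
# tables: at birth for stillbirths and neonates, conditional on surviving
# infancy for 1-59-month deaths, at mean maternal age for maternal deaths.
_DEFAULT_LE = {
    Group.STILLBIRTH: 62.0,
    Group.NEONATAL_UNDER_1M: 61.5,
    Group.CHILD_1_59M: 63.0,
    Group.MATERNAL: 42.0,
}


@dataclass(frozen=True)
class DistrictFixture:
    """One packaged study district: model inputs plus published metadata."""

    district_id: str
    country: str
    ledger: CostLedger
    lives: tuple[LivesSavedRecord, ...]
    life_table: LifeExpectancyTable
    context: PopulationContext
    gdp_per_capita: float
    annualize_startup: bool
    printed: Mapping[str, object]
    notes: tuple[str, ...]

    def as_inputs(self):
        """The (ledger, lives, life table, population context) tuple."""
        return self.ledger, self.lives, self.life_table, self.context


def load_fixture(district: str) -> DistrictFixture:
    """Load one of the four packaged study districts by name."""
    district = str(district).lower()
    if district not in DISTRICTS:
        raise InputError(
            f"unknown district {district!r}; expected one of {DISTRICTS}"
        )
    root = importlib.resources.files("chwcea").joinpath("data", "fixtures", district)
    meta = yaml.safe_load(root.joinpath("fixture.yaml").read_text(encoding="utf-8"))
    with importlib.resources.as_file(root.joinpath("cost_ledger.csv")) as p:
        components = read_cost_components(p)
    with importlib.resources.as_file(root.joinpath("lives_saved.csv")) as p:
        lives = read_lives_saved(p)
    with importlib.resources.as_file(root.joinpath("life_table.csv")) as p:
        life_table = read_life_table(p)
    ledger = CostLedger(
        district_id=meta["district_id"],
        components=components,
        overhead_pct=float(meta["overhead_pct"]),
        attrition_rate=float(meta["attrition_rate"]),
        discount_rate=float(meta["discount_rate"]),
        useful_life_years=float(meta["useful_life_years"]),
    )
    ctx = PopulationContext(
        district_population=float(meta["population"]["district"]),
        national_population=float(meta["population"]["national"]),
    )
    return DistrictFixture(
        district_id=meta["district_id"],
        country=meta["country"],
        ledger=ledger,
        lives=lives,
        life_table=life_table,
        context=ctx,
        gdp_per_capita=float(meta["gdp_per_capita"]),
        annualize_startup=bool(meta["annualize_startup"]),
        printed=meta["printed"],
        notes=tuple(meta.get("notes", ())),
    )


@dataclass(frozen=True)
class ScenarioSpec:
    """Recipe for a synthetic programme scenario.

    ``cost_scale`` is the (low, high) range of a log-uniform draw for line
    item amounts, in international dollars. If ``target_icer`` is set, the
    lives-saved values are rescaled so the deterministic pipeline ICER
    equals it exactly; otherwise lives are scaled to hit ``true_lyg``.
    """

    seed: int = 0
    n_cost_components: int = 3
    cost_scale: tuple[float, float] = (1_000.0, 1_000_000.0)
    true_lyg: float = 500.0
    overhead_pct: float = 0.15
    attrition_rate: float = 0.0
    discount_rate: float = 0.03
    useful_life_years: float = 10.0
    target_icer: float | None = None

    def __post_init__(self) -> None:
        if self.n_cost_components < 1:
            raise InputError("n_cost_components must be >= 1")
        lo, hi = self.cost_scale
        if not 0 < lo <= hi:
            raise InputError("cost_scale must satisfy 0 < low <= high")
        if self.target_icer is not None and self.target_icer <= 0:
            raise InputError(
                f"target_icer must be > 0, got {self.target_icer}"
            )


@dataclass(frozen=True)
class Scenario:
    """A generated scenario plus its ground truth."""

    ledger: CostLedger
    lives: tuple[LivesSavedRecord, ...]
    life_table: LifeExpectancyTable
    context: PopulationContext
    true_total_cost: float
    true_total_lyg: float
    annualize_startup: bool = True

    @property
    def true_icer(self) -> float:
        return _icer(self.true_total_cost, self.true_total_lyg)

    def as_inputs(self):
        return self.ledger, self.lives, self.life_table, self.context


def generate_scenario(spec: ScenarioSpec) -> Scenario:
    """Draw a random programme scenario with known ground truth.

    Start-up line items are generated as raw capital outlays
    (``annualized=False``) so the annuitization path is exercised; one
    start-up line is a pre-service training item subject to attrition. The
    scenario's deterministic pipeline totals are returned alongside the
    inputs; when ``target_icer`` is set, lives saved are rescaled so the
    pipeline ICER equals it to machine precision.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.cost_scale

    def draw_amounts(k: int) -> np.ndarray:
        return np.exp(rng.uniform(np.log(lo), np.log(hi), size=k))

    components: list[CostComponent] = []
    for cat in CostCategory:
        amounts = draw_amounts(spec.n_cost_components)
        for j, amount in enumerate(amounts):
            is_startup = cat is CostCategory.START_UP
            components.append(
                CostComponent(
                    name=f"{cat.value}_{j}",
                    category=cat,
                    amount=float(amount),
                    is_training=is_startup and j == 0,
                    annualized=not is_startup,
                )
            )
    ledger = CostLedger(
        district_id=f"synthetic-{spec.seed}",
        components=tuple(components),
        overhead_pct=spec.overhead_pct,
        attrition_rate=spec.attrition_rate,
        discount_rate=spec.discount_rate,
        useful_life_years=spec.useful_life_years,
    )
    total_cost = total_annual_cost(ledger, annualize_startup=True).total_annual

    national = float(rng.integers(5_000_000, 100_000_000))
    district = float(rng.uniform(0.002, 0.02)) * national
    ctx = PopulationContext(district_population=district, national_population=national)

    le = LifeExpectancyTable(
        {g: base * rng.uniform(0.9, 1.1) for g, base in _DEFAULT_LE.items()}
    )

    # Unscaled national lives; then solve the linear scaling for the target.
    raw = {g: float(rng.uniform(0.5, 50.0)) for g in Group}
    records = tuple(
        LivesSavedRecord(group=g, lives_saved=v) for g, v in raw.items()
    )
    raw_lyg = compute_lyg(records, le, ctx, spec.discount_rate).total
    if spec.target_icer is not None:
        wanted_lyg = total_cost / spec.target_icer
    else:
        wanted_lyg = spec.true_lyg
    if wanted_lyg == 0:
        scale = 0.0
    else:
        scale = wanted_lyg / raw_lyg
    records = tuple(replace(r, lives_saved=r.lives_saved * scale) for r in records)
    total_lyg = compute_lyg(records, le, ctx, spec.discount_rate).total

    return Scenario(
        ledger=ledger,
        lives=records,
        life_table=le,
        context=ctx,
        true_total_cost=total_cost,
        true_total_lyg=total_lyg,
    )
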