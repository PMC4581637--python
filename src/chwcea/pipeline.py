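"""End-to-end orchestration: inputs -> CEA -> DSA -> PSA -> CEAC -> files.

``build_model`` assembles a :class:`~chwcea.model.DecisionModel` either
from a packaged district fixture or from user-supplied delimited files;
``run_pipeline`` executes the deterministic analysis and both sensitivity
analyses, and optionally writes every result table plus a key-value summary
recording all assumptions, the seed and the configuration hash.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from . import __version__
from .cea import CEAResult, evaluate as evaluate_cea, icer
from .config import RunConfig
from .cost import CostComponent, CostLedger
from .datasets import load_fixture
from .effect import LifeExpectancyTable, LivesSavedRecord, PopulationContext
from .errors import InputError
from .io import (
    read_cost_components,
    read_life_table,
    read_lives_saved,
    write_cea_results,
    write_ceac,
    write_dsa,
    write_psa_draws,
    write_summary,
)
from .model import DecisionModel
from .sensitivity import CEACPoint, DSAEntry, PSAOutput, ceac, one_way_sa, run_psa

__all__ = ["PipelineResult", "build_model", "run_pipeline"]


@dataclass(frozen=True)
class PipelineResult:
    """Everything one pipeline run produces."""

    cea: CEAResult
    dsa: list[DSAEntry]
    psa: PSAOutput
    ceac_points: list[CEACPoint]
    summary: dict


def build_model(config: RunConfig) -> tuple[DecisionModel, RunConfig]:
    """Assemble the decision model described by a run configuration.

    With ``config.fixture`` set, the packaged district supplies inputs and
    assumptions (the fixture's attrition rate, GDP per capita, etc. override
    the config defaults; explicit config files are not allowed alongside a
    fixture). Otherwise all three input files are required, the population
    context comes from the config, and a uniform PPP conversion factor may
    be applied to ledger amounts at ingest.
    """
    if config.fixture is not None:
        if config.cost_ledger or config.lives_saved or config.life_table:
            raise InputError("provide either a fixture name or input files, not both")
        fx = load_fixture(config.fixture)
        config = config.model_copy(
            update=dict(
                district_id=fx.district_id,
                overhead_pct=fx.ledger.overhead_pct,
                attrition_rate=fx.ledger.attrition_rate,
                discount_rate=fx.ledger.discount_rate,
                useful_life_years=fx.ledger.useful_life_years,
                annualize_startup=fx.annualize_startup,
                gdp_per_capita=(
                    config.gdp_per_capita
                    if config.gdp_per_capita is not None
                    else fx.gdp_per_capita
                ),
            )
        )
        model = DecisionModel(
            ledger=fx.ledger,
            lives=fx.lives,
            life_table=fx.life_table,
            context=fx.context,
            annualize_startup=fx.annualize_startup,
        )
        return model, config

    missing = [
        name
        for name, value in (
            ("cost_ledger", config.cost_ledger),
            ("lives_saved", config.lives_saved),
            ("life_table", config.life_table),
        )
        if value is None
    ]
    if missing:
        raise InputError(f"missing required input path(s): {missing}")
    components = read_cost_components(config.cost_ledger)
    if config.ppp_factor != 1.0:
        components = tuple(
            replace(c, amount=c.amount * config.ppp_factor) for c in components
        )
    ledger = CostLedger(
        district_id=config.district_id,
        components=components,
        overhead_pct=config.overhead_pct,
        attrition_rate=config.attrition_rate,
        discount_rate=config.discount_rate,
        useful_life_years=config.useful_life_years,
    )
    lives = read_lives_saved(config.lives_saved)
    life_table = read_life_table(config.life_table)
    if config.district_population is None or config.national_population is None:
        raise InputError(
            "district_population and national_population are required when "
            "input files are supplied directly"
        )
    ctx = PopulationContext(
        district_population=config.district_population,
        national_population=config.national_population,
    )
    model = DecisionModel(
        ledger=ledger,
        lives=lives,
        life_table=life_table,
        context=ctx,
        annualize_startup=config.annualize_startup,
    )
    return model, config


def _wtp_grid(config: RunConfig, baseline_icer: float) -> np.ndarray:
    """0 to ``wtp_grid_multiplier`` x GDP per capita (or x ICER if no GDP)."""
    anchor = config.gdp_per_capita if config.gdp_per_capita else baseline_icer
    top = config.wtp_grid_multiplier * anchor
    return np.linspace(0.0, top, config.wtp_grid_points)


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Run the full analysis; optionally write all result tables to ``outdir``.

    Deterministic given (inputs, seed): two runs with the same config
    produce byte-identical output files. Every output records the config
    hash and seed in the accompanying summary document.
    """
    config_hash = config.digest()  # hash the configuration as supplied
    model, config = build_model(config)
    total_cost, total_lyg = model.baseline()

    cea_result = evaluate_cea(
        district_id=config.district_id,
        total_cost=total_cost,
        total_lyg=total_lyg,
        gdp_per_capita=config.gdp_per_capita,
        multiplier=config.wtp_multipliers[0] if config.wtp_multipliers else 1.0,
    )

    specs = model.parameter_specs(
        dsa_fraction=config.dsa_fraction, psa_fraction=config.psa_fraction
    )
    dsa = one_way_sa(model, specs)
    psa = run_psa(model, specs, n=config.psa_n, seed=config.seed)
    grid = _wtp_grid(config, cea_result.icer)
    ceac_points = ceac(psa, grid)

    verdicts = {}
    if config.gdp_per_capita is not None:
        for m in config.wtp_multipliers:
            threshold = m * config.gdp_per_capita
            verdicts[f"cost_effective_at_{m:g}x_gdp"] = bool(
                cea_result.icer <= threshold
            )

    summary = {
        "package_version": __version__,
        "config_hash": config_hash,
        "district_id": config.district_id,
        "seed": config.seed,
        "assumptions": {
            "discount_rate": config.discount_rate,
            "useful_life_years": config.useful_life_years,
            "overhead_pct": config.overhead_pct,
            "attrition_rate": config.attrition_rate,
            "annualize_startup": config.annualize_startup,
            "dsa_fraction": config.dsa_fraction,
            "psa_fraction": config.psa_fraction,
            "psa_n": config.psa_n,
            "gdp_per_capita": config.gdp_per_capita,
            "wtp_multipliers": list(config.wtp_multipliers),
            "ppp_factor": config.ppp_factor,
        },
        "results": {
            "total_annual_cost": round(total_cost, 2),
            "total_discounted_lyg": round(total_lyg, 2),
            "icer": round(cea_result.icer, 2),
            "psa_nonpositive_lyg_draws": psa.n_nonpositive_lyg,
            **verdicts,
        },
    }

    result = PipelineResult(
        cea=cea_result, dsa=dsa, psa=psa, ceac_points=ceac_points, summary=summary
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_cea_results([cea_result], outdir / "cea.csv")
        write_dsa(dsa, outdir / "dsa.csv")
        write_psa_draws(psa, outdir / "psa_draws.csv")
        write_ceac(ceac_points, outdir / "ceac.csv")
        write_summary(summary, outdir / "summary.yaml")
    return result
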