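"""Run configuration: a validated, YAML-loadable bundle of assumptions.

Defaults mirror the standard modelling assumptions: a 3% annual discount
rate for start-up costs and life-years gained, a 10-year programme useful
life, 15% overhead on recurrent costs, zero attrition unless specified,
+-30% one-way sensitivity bounds, +-10% probabilistic bounds, and 5000
Monte Carlo simulations.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .errors import InputError

__all__ = ["RunConfig", "parse_config"]


class RunConfig(BaseModel):
    """All inputs and assumptions for one pipeline run."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    # input files (optional when a packaged district fixture is used)
    cost_ledger: Path | None = None
    lives_saved: Path | None = None
    life_table: Path | None = None
    fixture: str | None = None
    district_id: str = "district"

    # population scaling; ignored when a fixture provides its own context
    district_population: float | None = Field(default=None, gt=0)
    national_population: float | None = Field(default=None, gt=0)

    # costing and discounting assumptions
    discount_rate: float = Field(default=0.03, ge=0)
    useful_life_years: float = Field(default=10.0, gt=0)
    overhead_pct: float = Field(default=0.15, ge=0, lt=1)
    attrition_rate: float = Field(default=0.0, ge=0, lt=1)
    annualize_startup: bool = False
    # optional uniform PPP conversion applied to every ledger amount at ingest
    ppp_factor: float = Field(default=1.0, gt=0)

    # sensitivity analysis settings
    dsa_fraction: float = Field(default=0.30, ge=0)
    psa_fraction: float = Field(default=0.10, ge=0)
    psa_n: int = Field(default=5000, ge=1)
    seed: int = 0

    # willingness-to-pay settings
    gdp_per_capita: float | None = Field(default=None, gt=0)
    wtp_multipliers: tuple[float, ...] = (1.0, 3.0)
    wtp_grid_multiplier: float = Field(default=4.0, gt=0)
    wtp_grid_points: int = Field(default=101, ge=2)

    def digest(self) -> str:
        """Short stable hash of the full configuration, for output provenance."""
        payload = json.dumps(
            self.model_dump(mode="json"), sort_keys=True, separators=(",", ":")
        )
        return hashlib.sha256(payload.encode("utf-8")).hexdigest()[:12]


def parse_config(source) -> RunConfig:
    """Parse a YAML config document (path or text) into a validated RunConfig.

    Unknown keys and out-of-range values raise :class:`InputError` naming
    the offending key path.
    """
    if isinstance(source, Path) or (
        isinstance(source, str) and source and Path(source).is_file()
    ):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = str(source)
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise InputError(f"malformed configuration document: {exc}") from exc
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise InputError(
            f"configuration must be a key-value mapping, got {type(doc).__name__}"
        )
    try:
        return RunConfig(**doc)
    except ValidationError as exc:
        details = "; ".join(
            f"{'.'.join(str(p) for p in err['loc']) or '<root>'}: {err['msg']}"
            for err in exc.errors()
        )
        raise InputError(f"invalid configuration: {details}") from exc
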