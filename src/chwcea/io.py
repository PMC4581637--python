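"""Delimited-text readers and writers for ledgers, tables and results.

File schemas (CSV, one header row, UTF-8):

* cost ledger: ``name,category,amount,is_training,annualized``
* lives saved: ``group,lives_saved_national[,per_100k]``
* life table:  ``group,remaining_le_years``
* DSA output:  ``parameter,icer_low,icer_high,range``
* PSA draws:   ``draw,total_cost,total_lyg,icer``
* CEAC:        ``wtp,probability``
"""

from __future__ import annotations

from os import PathLike
from pathlib import Path
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .cea import CEAResult
from .cost import CostComponent, CostLedger
from .effect import Group, LifeExpectancyTable, LivesSavedRecord
from .errors import InputError
from .sensitivity import CEACPoint, DSAEntry, PSAOutput

__all__ = [
    "read_cost_components",
    "read_lives_saved",
    "read_life_table",
    "write_cost_components",
    "write_lives_saved",
    "write_life_table",
    "write_dsa",
    "write_psa_draws",
    "write_ceac",
    "write_cea_results",
    "write_summary",
]

_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no"}

Source = str | PathLike | IO[str]


def _parse_bool(value, column: str) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().lower()
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise InputError(f"column {column!r}: cannot parse boolean from {value!r}")


def _read_csv(source: Source, required: Sequence[str], label: str) -> pd.DataFrame:
    try:
        frame = pd.read_csv(source)
    except FileNotFoundError:
        raise InputError(f"{label} file not found: {source}") from None
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise InputError(f"malformed {label} file {source}: {exc}") from exc
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise InputError(
            f"{label} file {source} is missing column(s) {missing}; "
            f"found {list(frame.columns)}"
        )
    return frame


def read_cost_components(source: Source) -> tuple[CostComponent, ...]:
    """Read ledger line items from CSV (assumption values come from config)."""
    frame = _read_csv(
        source, ["name", "category", "amount", "is_training", "annualized"], "cost ledger"
    )
    return tuple(
        CostComponent(
            name=str(row["name"]),
            category=str(row["category"]),
            amount=float(row["amount"]),
            is_training=_parse_bool(row["is_training"], "is_training"),
            annualized=_parse_bool(row["annualized"], "annualized"),
        )
        for _, row in frame.iterrows()
    )


def read_lives_saved(source: Source) -> tuple[LivesSavedRecord, ...]:
    frame = _read_csv(source, ["group", "lives_saved_national"], "lives-saved")
    return tuple(
        LivesSavedRecord(
            group=str(row["group"]),
            lives_saved=float(row["lives_saved_national"]),
            per_100k=(
                float(row["per_100k"])
                if "per_100k" in frame.columns and pd.notna(row["per_100k"])
                else None
            ),
        )
        for _, row in frame.iterrows()
    )


def read_life_table(source: Source) -> LifeExpectancyTable:
    frame = _read_csv(source, ["group", "remaining_le_years"], "life table")
    return LifeExpectancyTable(
        {
            Group(str(row["group"])): float(row["remaining_le_years"])
            for _, row in frame.iterrows()
        }
    )


def write_cost_components(components: Iterable[CostComponent], path) -> None:
    pd.DataFrame(
        [
            {
                "name": c.name,
                "category": c.category.value,
                "amount": repr(c.amount),
                "is_training": str(c.is_training).lower(),
                "annualized": str(c.annualized).lower(),
            }
            for c in components
        ]
    ).to_csv(path, index=False)


def write_lives_saved(records: Iterable[LivesSavedRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "group": r.group.value,
                "lives_saved_national": repr(r.lives_saved),
                "per_100k": "" if r.per_100k is None else repr(r.per_100k),
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def write_life_table(table: LifeExpectancyTable, path) -> None:
    pd.DataFrame(
        [
            {"group": g.value, "remaining_le_years": repr(v)}
            for g, v in table.values.items()
        ]
    ).to_csv(path, index=False)


def write_dsa(entries: Sequence[DSAEntry], path) -> None:
    pd.DataFrame(
        [
            {
                "parameter": e.parameter,
                "icer_low": e.icer_low,
                "icer_high": e.icer_high,
                "range": e.range,
            }
            for e in entries
        ]
    ).to_csv(path, index=False)


def write_psa_draws(psa: PSAOutput, path) -> None:
    pd.DataFrame(
        {
            "draw": np.arange(psa.n),
            "total_cost": psa.cost,
            "total_lyg": psa.lyg,
            "icer": psa.icer,
        }
    ).to_csv(path, index=False)


def write_ceac(points: Sequence[CEACPoint], path) -> None:
    pd.DataFrame(
        [{"wtp": p.wtp, "probability": p.probability} for p in points]
    ).to_csv(path, index=False)


def write_cea_results(results: Sequence[CEAResult], path) -> None:
    pd.DataFrame(
        [
            {
                "district_id": r.district_id,
                "total_cost": round(r.total_cost, 2),
                "total_lyg": round(r.total_lyg, 2),
                "icer": round(r.icer, 2),
                "wtp_threshold": "" if r.wtp_threshold is None else r.wtp_threshold,
                "cost_effective": "" if r.cost_effective is None else r.cost_effective,
            }
            for r in results
        ]
    ).to_csv(path, index=False)


def write_summary(summary: dict, path) -> None:
    """Key-value run summary (assumptions, seed, config hash, version)."""
    Path(path).write_text(yaml.safe_dump(summary, sort_keys=True), encoding="utf-8")
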