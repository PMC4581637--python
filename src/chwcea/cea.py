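"""Incremental cost-effectiveness ratios and willingness-to-pay verdicts.

The comparator is the null (no-programme) scenario: all programme costs and
health gains are incremental to what would have occurred in its absence, so
the ICER is simply total annual cost divided by total discounted life-years
gained. Cost-effectiveness is judged against a willingness-to-pay threshold
of one to three times national GDP per capita.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InputError, UndefinedICERError

__all__ = ["CEAResult", "icer", "wtp_verdict"]


@dataclass(frozen=True)
class CEAResult:
    """Headline cost-effectiveness result for one district programme."""

    district_id: str
    total_cost: float
    total_lyg: float
    icer: float
    wtp_threshold: float | None = None
    cost_effective: bool | None = None


def icer(total_cost: float, total_lyg: float) -> float:
    """Incremental cost per life-year gained versus the null scenario.

    Raises :class:`UndefinedICERError` when life-years gained are zero or
    negative: a ratio with a non-positive denominator has no
    cost-effectiveness interpretation and must not be returned silently.
    """
    if total_lyg == 0:
        raise UndefinedICERError("ICER undefined: total life-years gained is zero")
    if total_lyg < 0:
        raise UndefinedICERError(
            "ICER undefined: negative life-years gained "
            f"({total_lyg:g}); the programme is dominated by the null scenario"
        )
    return total_cost / total_lyg


def wtp_verdict(icer_value: float, gdp_per_capita: float, multiplier: float = 1.0) -> bool:
    """Is an ICER cost-effective at ``multiplier`` x GDP per capita?

    The comparison is inclusive: an ICER exactly at the threshold counts as
    cost-effective. ``multiplier`` is conventionally in [1, 3].
    """
    if gdp_per_capita <= 0:
        raise InputError(f"gdp_per_capita must be > 0, got {gdp_per_capita}")
    if multiplier <= 0:
        raise InputError(f"multiplier must be > 0, got {multiplier}")
    threshold = multiplier * gdp_per_capita
    if not math.isfinite(threshold):
        raise InputError("willingness-to-pay threshold must be finite")
    return icer_value <= threshold


def evaluate(
    district_id: str,
    total_cost: float,
    total_lyg: float,
    gdp_per_capita: float | None = None,
    multiplier: float = 1.0,
) -> CEAResult:
    """Bundle cost, effect, ICER and optional threshold verdict."""
    ratio = icer(total_cost, total_lyg)
    threshold = None
    verdict = None
    if gdp_per_capita is not None:
        threshold = multiplier * gdp_per_capita
        verdict = wtp_verdict(ratio, gdp_per_capita, multiplier)
    return CEAResult(
        district_id=district_id,
        total_cost=total_cost,
        total_lyg=total_lyg,
        icer=ratio,
        wtp_threshold=threshold,
        cost_effective=verdict,
    )
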