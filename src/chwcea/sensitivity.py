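"""Deterministic (tornado) and probabilistic sensitivity analysis.

One-way analysis perturbs each model input to ``mean * (1 +- dsa_fraction)``
while holding the others at baseline, recording the induced ICER range.
Probabilistic analysis fits a parametric distribution per input -- gamma for
cost inputs, beta for the attrition rate and overhead percentage, normal
for life-years gained -- interprets the ``+-psa_fraction`` bounds as a
central 95% interval (``sd = psa_fraction * mean / 1.96``), moment-matches
the family, and propagates joint uncertainty through the model by Monte
Carlo. Results are summarized as cost-effectiveness acceptability curves on
the net-monetary-benefit criterion ``lambda * E - C >= 0``, which remains
well defined for draws with non-positive life-years gained.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Protocol, Sequence

import numpy as np
from scipy import stats

from .errors import InputError

__all__ = [
    "ParameterRole",
    "ParameterSpec",
    "DSAEntry",
    "PSAOutput",
    "CEACPoint",
    "FittedDistribution",
    "one_way_sa",
    "fit_distribution",
    "run_psa",
    "ceac",
]


class ParameterRole(str, enum.Enum):
    COST_INPUT = "cost_input"
    LYG = "lyg"
    ATTRITION_RATE = "attrition_rate"
    OVERHEAD_PCT = "overhead_pct"
    DISCOUNT_RATE = "discount_rate"
    USEFUL_LIFE = "useful_life"


# Distribution family per role: gamma for non-negative money amounts, beta
# for proportions, normal for the (approximately symmetric) LYG estimate.
# Structural assumptions (discount rate, useful life) are varied in the
# one-way analysis only and carry no probabilistic family.
_FAMILY_BY_ROLE: dict[ParameterRole, str | None] = {
    ParameterRole.COST_INPUT: "gamma",
    ParameterRole.LYG: "normal",
    ParameterRole.ATTRITION_RATE: "beta",
    ParameterRole.OVERHEAD_PCT: "beta",
    ParameterRole.DISCOUNT_RATE: None,
    ParameterRole.USEFUL_LIFE: None,
}


@dataclass(frozen=True)
class ParameterSpec:
    """One uncertain model input.

    ``dsa_fraction`` is the one-way perturbation half-width (default
    +-30%); ``psa_fraction`` the probabilistic half-width (default +-10%),
    read as a central 95% interval. ``family`` defaults by role.
    """

    name: str
    role: ParameterRole
    mean: float
    dsa_fraction: float = 0.30
    psa_fraction: float = 0.10
    family: str | None = "auto"

    def __post_init__(self) -> None:
        role = ParameterRole(self.role)
        object.__setattr__(self, "role", role)
        if self.dsa_fraction < 0 or self.psa_fraction < 0:
            raise InputError("perturbation fractions must be >= 0")
        if self.family == "auto":
            object.__setattr__(self, "family", _FAMILY_BY_ROLE[role])
        elif self.family not in (None, "gamma", "beta", "normal"):
            raise InputError(f"unknown distribution family {self.family!r}")


class Model(Protocol):
    """Anything mapping parameter values to (total cost, total LYG).

    Values may be scalars or numpy arrays (broadcast elementwise); inputs
    absent from the mapping stay at their baseline means.
    """

    def evaluate(self, values: Mapping[str, object]) -> tuple[np.ndarray, np.ndarray]:
        ...


@dataclass(frozen=True)
class DSAEntry:
    """Tornado bar: ICER at the low and high bound of one parameter."""

    parameter: str
    icer_low: float
    icer_high: float
    range: float
    undefined: bool = False


@dataclass(frozen=True)
class PSAOutput:
    """Monte Carlo draws of (cost, LYG) with per-draw ICERs.

    ``icer`` is NaN for draws with non-positive LYG; those draws are kept
    (they still contribute to acceptability curves) and counted in
    ``n_nonpositive_lyg``.
    """

    cost: np.ndarray
    lyg: np.ndarray
    icer: np.ndarray
    seed: int
    n: int
    n_nonpositive_lyg: int
    parameter_means: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class CEACPoint:
    wtp: float
    probability: float


def _scalar_icer(cost: float, lyg: float) -> float:
    if lyg <= 0:
        return float("nan")
    return cost / lyg


def one_way_sa(model: Model, specs: Iterable[ParameterSpec]) -> list[DSAEntry]:
    """One-way deterministic sensitivity analysis.

    Each parameter is set to ``mean * (1 - f)`` and ``mean * (1 + f)`` in
    turn, all others at baseline. Entries are sorted by descending ICER
    range, ties broken alphabetically. A bound at which total LYG is
    non-positive makes the entry undefined: it is excluded from the sorted
    ranking (appended at the end, with a warning).
    """
    defined: list[DSAEntry] = []
    undefined: list[DSAEntry] = []
    for spec in specs:
        f = spec.dsa_fraction
        lows, highs = [], []
        icers = []
        for value in (spec.mean * (1.0 - f), spec.mean * (1.0 + f)):
            cost, lyg = model.evaluate({spec.name: value})
            icers.append(_scalar_icer(float(cost), float(lyg)))
        low, high = icers
        if np.isnan(low) or np.isnan(high):
            warnings.warn(
                f"parameter {spec.name!r}: ICER undefined at a +-{f:.0%} bound "
                "(non-positive life-years gained); excluded from tornado ranking",
                stacklevel=2,
            )
            undefined.append(
                DSAEntry(spec.name, low, high, float("nan"), undefined=True)
            )
        else:
            defined.append(DSAEntry(spec.name, low, high, abs(high - low)))
    defined.sort(key=lambda e: (-e.range, e.parameter))
    undefined.sort(key=lambda e: e.parameter)
    return defined + undefined


@dataclass(frozen=True)
class FittedDistribution:
    """A moment-matched sampling distribution for one parameter.

    ``family`` is ``"degenerate"`` when the parameter has no uncertainty
    (zero mean for a scale family, or a zero ``psa_fraction``): every draw
    then equals the mean.
    """

    name: str
    family: str
    mean: float
    sd: float
    params: Mapping[str, float]

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.family == "degenerate":
            return np.full(n, self.mean)
        if self.family == "gamma":
            return stats.gamma.rvs(
                a=self.params["shape"], scale=self.params["scale"], size=n,
                random_state=rng,
            )
        if self.family == "beta":
            return stats.beta.rvs(
                a=self.params["alpha"], b=self.params["beta"], size=n,
                random_state=rng,
            )
        if self.family == "normal":
            return stats.norm.rvs(
                loc=self.mean, scale=self.sd, size=n, random_state=rng
            )
        raise InputError(f"unknown family {self.family!r}")


def fit_distribution(spec: ParameterSpec) -> FittedDistribution:
    """Moment-match the spec's family to mean and ``+-psa_fraction`` bounds.

    The bounds ``mean * (1 +- psa_fraction)`` are read as a central 95%
    interval, so ``sd = psa_fraction * |mean| / 1.96``. Gamma:
    ``shape = (mean/sd)^2``, ``scale = sd^2/mean``. Beta:
    ``nu = mean(1-mean)/sd^2 - 1``, ``alpha = mean*nu``,
    ``beta = (1-mean)*nu``. Normal: (mean, sd) directly. The fitted
    distributions are not truncated.
    """
    family = spec.family
    if family is None:
        raise InputError(
            f"parameter {spec.name!r} has no distribution family; it does not "
            "participate in probabilistic sensitivity analysis"
        )
    sd = spec.psa_fraction * abs(spec.mean) / 1.96
    if spec.psa_fraction == 0 or (spec.mean == 0 and family in ("gamma", "beta")):
        return FittedDistribution(spec.name, "degenerate", spec.mean, 0.0, {})
    if family == "gamma":
        if spec.mean <= 0:
            raise InputError(
                f"parameter {spec.name!r}: gamma requires mean > 0, got {spec.mean}"
            )
        shape = (spec.mean / sd) ** 2
        scale = sd**2 / spec.mean
        return FittedDistribution(
            spec.name, "gamma", spec.mean, sd, {"shape": shape, "scale": scale}
        )
    if family == "beta":
        m = spec.mean
        if not 0 < m < 1:
            raise InputError(
                f"parameter {spec.name!r}: beta requires mean in (0, 1), got {m}"
            )
        if sd**2 >= m * (1 - m):
            raise InputError(
                f"parameter {spec.name!r}: beta moment matching infeasible "
                f"(sd^2 = {sd**2:g} >= mean(1-mean) = {m * (1 - m):g})"
            )
        nu = m * (1 - m) / sd**2 - 1
        return FittedDistribution(
            spec.name, "beta", m, sd, {"alpha": m * nu, "beta": (1 - m) * nu}
        )
    if family == "normal":
        return FittedDistribution(spec.name, "normal", spec.mean, sd, {})
    raise InputError(f"unknown family {family!r}")


def run_psa(
    model: Model,
    specs: Sequence[ParameterSpec],
    n: int = 5000,
    seed: int = 0,
) -> PSAOutput:
    """Propagate joint parameter uncertainty by Monte Carlo.

    Parameters with a distribution family are drawn independently (no
    correlation structure is imposed); structural parameters without a
    family stay at their means. Reproducible given ``(seed, n)``: a single
    seeded generator drives all draws, in spec order.
    """
    if n < 1:
        raise InputError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    values: dict[str, np.ndarray] = {}
    for spec in specs:
        if spec.family is None:
            continue
        values[spec.name] = fit_distribution(spec).rvs(n, rng)
    cost, lyg = model.evaluate(values)
    cost = np.broadcast_to(np.asarray(cost, dtype=float), (n,)).copy()
    lyg = np.broadcast_to(np.asarray(lyg, dtype=float), (n,)).copy()
    positive = lyg > 0
    icer = np.where(positive, cost / np.where(positive, lyg, 1.0), np.nan)
    return PSAOutput(
        cost=cost,
        lyg=lyg,
        icer=icer,
        seed=seed,
        n=n,
        n_nonpositive_lyg=int(np.count_nonzero(~positive)),
        parameter_means={s.name: s.mean for s in specs},
    )


def ceac(psa: PSAOutput, wtp_grid: Sequence[float]) -> list[CEACPoint]:
    """Cost-effectiveness acceptability curve over a willingness-to-pay grid.

    At each threshold ``lambda`` the probability is the fraction of draws
    with non-negative net monetary benefit ``lambda * E - C``. For draws
    with positive LYG this is exactly ``ICER <= lambda``; draws with
    non-positive LYG count as cost-effective only if they also save money.
    """
    grid = np.asarray(list(wtp_grid), dtype=float)
    if grid.size == 0:
        raise InputError("willingness-to-pay grid must be non-empty")
    if grid.size > 1 and not np.all(np.diff(grid) > 0):
        raise InputError("willingness-to-pay grid must be strictly increasing")
    nmb = grid[:, None] * psa.lyg[None, :] - psa.cost[None, :]
    probs = np.mean(nmb >= 0, axis=1)
    return [CEACPoint(float(w), float(p)) for w, p in zip(grid, probs)]
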