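# Methods

## Decision model

Each district programme is compared with its absence: every cost and every
health gain is incremental to the null scenario, over a one-year horizon,
from a government perspective. There is no inter-programme frontier
analysis, extended dominance or league table — each programme is evaluated
only against doing nothing, which is how community-based programmes are
typically appraised when they are the sole candidate intervention in a
district.

### Costing

A ledger holds line items in four categories: start-up, direct recurrent,
indirect recurrent and volunteer costs. Three adjustments produce the
total annual cost:

1. **Annuitization.** A start-up item flagged as a raw capital outlay
   (`annualized=False`) is divided by the annuity factor
   `A(r, L) = (1 − (1+r)^−L)/r` (limit `L` at `r = 0`). Defaults: `r = 0.03`
   per year, `L = 10` years. The factor is computed as
   `-expm1(-L·log1p(r))/r`, which is exact in the limit of very small
   rates where the naive power form cancels catastrophically.
2. **Attrition.** Items flagged `is_training` are divided by
   `1 − attrition_rate`: if a fraction of trained workers quits after
   training, the effective cost of one worker in post is higher. Default 0;
   the Ethiopian fixture uses 1.1%.
3. **Overhead.** A percentage (default 15%) of the recurrent base — direct
   + indirect + volunteer, start-up excluded — is added for costs incurred
   at higher administrative levels. This base is the only reading that
   reproduces all four published district overhead cells to the dollar,
   which is why it is fixed rather than configurable.

All arithmetic is carried at full floating precision; rounding to whole
dollars happens only at presentation. Amounts are assumed to be in
international dollars already; an optional scalar PPP factor can be
applied uniformly at ingest.

### Effectiveness

Lives saved are external inputs (e.g. Lives Saved Tool output), classified
as stillbirths, deaths under 1 month, deaths at 1–59 months, and maternal
deaths. National estimates are scaled to the district by population share,
multiplied by the remaining life expectancy at the time death is averted,
and discounted at the same 3% annual rate using the annuity form with a
continuous extension to fractional years — a single closed form rather
than a year-by-year loop. Negative lives saved (a coverage shift that
increases deaths in one group) propagate with their sign; they are never
clamped. The conversion is exactly linear in lives saved, and the total is
the plain sum of the per-group values.

Conventions for user-supplied life tables: expectancy at birth for
stillbirths and neonatal deaths, conditional on surviving infancy for
1–59-month deaths, remaining expectancy at mean maternal age for maternal
deaths.

### Decision rule

ICER = total annual cost / total discounted LYG. A zero or negative
denominator raises an error rather than returning a number, because a
ratio with non-positive health gain has no cost-effectiveness
interpretation. Threshold comparisons (1–3× GDP per capita, configurable)
are inclusive. GDP per capita values are run-configuration inputs with
external provenance (World Bank PPP series, reference year 2012 for the
packaged fixtures), never computed by the package.

## Sensitivity analysis

### One-way (tornado)

Every model input — the four cost-category subtotals, overhead percentage,
attrition rate, discount rate, useful life, and total LYG — is set to
`mean·(1 ± 0.30)` in turn, all others held at baseline. Entries are sorted
by descending ICER range, ties broken alphabetically. A bound that drives
LYG non-positive makes that entry undefined: it is flagged, excluded from
the ranking, and reported with a warning rather than a number.

Cost-category parameters act as uniform multipliers on their line items,
so the attrition and annuitization adjustments are re-derived at the
perturbed assumption values instead of being baked into the sampled
subtotal. The discount-rate parameter re-discounts both the annuitized
start-up stream and the life-years stream.

### Probabilistic

Families follow standard practice for each quantity's support: gamma for
non-negative cost inputs, beta for the attrition rate and overhead
percentage, normal for LYG. The stated ±10% bounds do not by themselves
parameterize a distribution; they are interpreted as a central 95%
interval, giving `sd = 0.10·mean/1.96`, and each family is moment-matched
(gamma: `shape = (mean/sd)²`, `scale = sd²/mean`; beta:
`ν = mean(1−mean)/sd² − 1`, `α = mean·ν`, `β = (1−mean)·ν`). Distributions
are not truncated. Parameters are drawn independently — no correlation
structure is asserted — from a single seeded generator, in declared
parameter order, so runs are bit-reproducible given `(seed, n)`. Default
`n = 5000` draws. Structural assumptions (discount rate, useful life) are
varied in the one-way analysis but carry no probability distribution.

Degenerate cases are explicit: a parameter with zero mean (an empty cost
category, a zero attrition rate) or zero uncertainty fraction samples as a
constant, so a fully degenerate PSA collapses exactly to the deterministic
baseline.

Acceptability curves use net monetary benefit: the probability at
willingness-to-pay λ is the fraction of draws with `λ·LYG − C ≥ 0`. This
equals `P(ICER ≤ λ)` for positive-LYG draws and remains well defined for
draws with non-positive LYG (they count as acceptable only if they also
save money). Draws with non-positive LYG are retained and counted, never
dropped. The default grid is 0 to 4× GDP per capita in 101 equal steps.

Cost granularity: one PSA/DSA parameter per category subtotal, not per
line item, keeping tornado output comparable across districts; the
parameter-spec list is ordinary data, so a caller wanting line-item
granularity can construct specs directly.

## Packaged district fixtures

The four study districts (Shebedino, Ethiopia; south-west Sumba and
Takala, Indonesia; Kasarani, Kenya) ship as delimited-text inputs
transcribed at published precision. Known internal inconsistencies of the
published tables are documented in each `fixture.yaml` rather than
corrected:

- Shebedino's published start-up subtotal (108 515) exceeds the sum of its
  line items (108 175) by 340, unexplained in the source; the published
  grand total is consistent with the line items, and the pipeline total
  (470 959) therefore lands within a dollar of the published 470 958.
- Sumba's direct-recurrent subtotal and Takala's indirect-recurrent
  subtotal each differ from their line-item sums by 1 (component
  rounding); Takala's published per-group LYG rows sum to 1895 against a
  published total of 1894.
- Kasarani's per-100k denominators imply a population of roughly 4 975,
  far below a plausible district population; the value is recorded
  verbatim because it is what makes the published per-100k columns
  internally consistent.
- Shebedino's pre-service training line is stored net of attrition
  (8 750.67 = 8 848 × 0.989) so the pipeline's 1.1% attrition step
  reproduces the published 8 848.

The published tables do not include the life-table values used, so the
fixture life expectancies are **calibrated**: each published lives/LYG pair
is inverted through the 3% annuity (`E = −ln(1 − 0.03·f)/ln 1.03` for
`f = LYG/lives`), yielding e.g. 61.76 years for Shebedino stillbirths.
These calibrations reproduce every published LYG row by construction; they
are provenance-documented fixture data, not demographic estimates, and the
small Kasarani rows make its calibrations coarse. Shebedino's maternal
entry is set to 0 because the published maternal LYG is 0 at printed
precision, leaving the implied expectancy unidentified. Start-up figures
in these tables are internally consistent only if treated as already
annual-equivalent, so fixtures load with `annualized=True` and
`annualize_startup=False`; raw capital inputs from users take the
annuitization path.

## Synthetic scenarios

`generate_scenario` emulates the *structure* of the study inputs: random
log-uniform cost line items per category (defaults: 3 per category,
1 000–1 000 000 international dollars, matching the order of magnitude of
the district ledgers), raw start-up outlays that exercise the
annuitization path, a training line subject to attrition, realistic
remaining life expectancies (around 62 years at birth, 42 at mean maternal
age, ±10% jitter), and lives saved rescaled so the deterministic pipeline
hits a requested total LYG or ICER exactly (the scaling is linear, so the
target is met to machine precision). It does **not** emulate the
coverage-to-deaths-averted model behind the lives-saved inputs, correlated
uncertainty between cost items, or real demographic structure — so passing
tests demonstrate that the analysis machinery is correct, not that any
particular programme is cost-effective.

## Numerical choices and limitations

- Annuity and discount factors use the `expm1`/`log1p` form throughout
  (stable for rates down to the subnormal range, exact zero-rate limit).
- Monte Carlo reproducibility is a contract: same seed, same draws, same
  bytes in every output file; the seed and a hash of the configuration are
  recorded in the run summary.
- Problem sizes used by the test-suite and the reproduction script are the
  study's own: 5 000 PSA draws per district, ±30% and ±10% perturbations,
  101-point acceptability grids. The whole suite runs in seconds.
- The package takes lives-saved estimates on trust; it has no view on the
  coverage studies or effect sizes behind them, which in the study design
  are the dominant source of uncertainty (the tornado's widest bar is LYG
  in all four districts).
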