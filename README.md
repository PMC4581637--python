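# chwcea

Cost-effectiveness analysis of community-based practitioner programmes —
the salaried or volunteer community health workers (health extension
workers, village midwives, community health volunteers) who deliver
reproductive, maternal, neonatal and child health services outside
facilities in low- and middle-income countries.

The package is for health economists and programme analysts who have (a) an
itemized programme cost ledger, (b) estimates of lives saved by population
group (for example from the Lives Saved Tool, which converts
intervention-coverage changes into deaths averted), and (c) a life table,
and who want a defensible incremental cost-effectiveness ratio with full
deterministic and probabilistic sensitivity analysis.

## The model

Costs and health gains are incremental to a no-programme comparator over a
one-year horizon, from a government perspective, in international (PPP)
dollars.

**Cost.** One-off start-up outlays *S* are annuitized over a useful life of
*L* years at discount rate *r* with the annuity factor

    A(r, L) = (1 − (1 + r)^−L) / r,

so the equivalent annual cost is *S / A(r, L)*. Pre-service training costs
are inflated by 1/(1 − *a*) for a post-training attrition rate *a*, and an
overhead percentage *h* is added on the recurrent (direct + indirect +
volunteer) base:

    C = S/A(r, L) + (1 + h)(C_direct + C_indirect + C_volunteer).

**Effect.** National lives saved per group *g* are scaled to the district by
population share, multiplied by the remaining life expectancy *E_g* at the
time death is averted, and discounted at the same rate:

    LYG = Σ_g n_g · (1 − (1 + r)^−E_g) / r.

**Decision.** ICER = *C* / LYG, judged against a willingness-to-pay
threshold of 1–3× national GDP per capita. One-way sensitivity analysis
perturbs every input ±30% (tornado); probabilistic sensitivity analysis
fits gamma (costs), beta (attrition, overhead percentage) and normal (LYG)
distributions to ±10% bounds read as 95% intervals, propagates them with
5000 Monte Carlo draws, and reports cost-effectiveness acceptability
curves on the net-monetary-benefit criterion λ·LYG − C ≥ 0.

## Worked example

Four study districts are packaged as fixtures: Shebedino (Ethiopia),
south-west Sumba and Takala (Indonesia) and Kasarani (Kenya).

```sh
$ chwcea run --fixture kasarani --seed 1 --out out/
kasarani: total annual cost 2,986, discounted LYG 36.0, ICER 82.9 $/LYG
cost-effective at threshold 2,750 $/LYG: yes
```

The programme costs 2 986 international dollars per year (start-up items
annualized, 15% overhead), gains 36 discounted life-years, and therefore
costs about 83 dollars per life-year gained — far below the one-times-GDP
threshold, so the volunteer programme is judged cost-effective. `out/`
receives the result table, the tornado table (`dsa.csv`, sorted by ICER
range — life-years gained carries the widest bar), the 5000 Monte Carlo
draws, the acceptability curve and a `summary.yaml` recording every
assumption, the seed and the config hash.

The same analysis from the library:

```python
from chwcea import DecisionModel, load_fixture

fx = load_fixture("shebedino")
model = DecisionModel(*fx.as_inputs(), fx.annualize_startup)
cost, lyg = model.baseline()
print(cost, lyg, cost / lyg)   # 470958.6  471.0  999.9 $/LYG
```

Synthetic programmes with known ground truth (for testing estimation
machinery end to end) come from `generate_scenario`:

```python
from chwcea import ScenarioSpec, generate_scenario
scenario = generate_scenario(ScenarioSpec(seed=7, target_icer=1000.0))
scenario.true_icer   # 1000.0 by construction
```

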