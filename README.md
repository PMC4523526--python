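# limbcost

Health-economic cost projection for the UK military lower-limb amputee
cohort from the Afghanistan campaign (2003–2014), for health economists and
rehabilitation planners who need long-term budget estimates for a defined
trauma cohort.

The package couples a cohort registry with a three-state Markov cohort
model. Each casualty occupies one of the states *healthy*, *chronic* or
*dead*; the model steps in 1-year cycles over a 40-year horizon with a
row-stochastic transition kernel `P` (death absorbing), occupancy
`π_t = π_{t-1} P`, and annual care costs attached to the living states.
In parallel with the health cycles, each prosthetic component of unit cost
`c_ℓ` (transtibial £9,946, through-knee/transfemoral £27,154, foot £9,747)
is replaced every `p = 2.3` years, so a limb's 40-year replacement stream is
`c_ℓ · N(T, p)` with `N` the replacement count under a selectable
convention (`T/p`, `T/p − 1`, or `⌊T/p⌋`). A casualty's first (costliest)
lower limb carries the full base package — care plus its own stream — and
every further lower limb adds a stream-only increment; upper-limb and
hindquarter amputations are registered but excluded from costing. One-way
sensitivity on the replacement cycle follows the closed form
`Δtotal% = 100 · s · (2.3/p' − 1)` where `s` is the prosthetic cost share
of the baseline, verified against a full engine re-run. Literature
comparators (1996 CHF, 2009 USD, 1965 GBP) are normalized to 2012 GBP with
composite exchange-rate × inflation factors.

Because no casualty-level registry extract is publicly deposited, the
package ships a canonical reconstruction (`limbcost.canonical_cohort()`)
that reproduces every published cohort marginal exactly, plus a seeded
synthetic generator for arbitrary marginals; reconstructed cells are
flagged in `src/limbcost/data/canonical_cohort.yaml`.

## Worked example

```python
import limbcost as lc
from limbcost.registry import AmputationLevel as L

cohort = lc.canonical_cohort()
summary = lc.summarize(cohort)
print(summary.n_casualties, summary.n_limbs,
      summary.mean_limbs_1dp, summary.sd_limbs_2dp)
# 265 416 1.6 0.68

scenario = lc.canonical_scenario()          # continuous convention, frozen
report = lc.cohort_total_cost(cohort, scenario)
print(report.cohort_total_millions)         # 288  (£ million over 40 years)

printed = lc.printed_scenario()             # count_minus_one convention
bd = lc.pattern_cost([L.TRANSTIBIAL, L.TRANSFEMORAL], printed)
print(bd.total_millions_printed)            # 1.32  (£M, sum of 0.87 + 0.45)
```

265 casualties lost 416 limbs (mean 1.6 per casualty, SD 0.68). Under the
frozen canonical scenario the cohort's 40-year cost aggregates to £288
million; under the printed-arithmetic calibration a mixed
transtibial–transfemoral double amputee costs £1.32M, the £0.87M
transtibial base package plus the £0.45M additional femoral stream.

The same pipeline is scriptable from the shell:

```sh
limbcost summarize                 # canonical cohort description as JSON
limbcost cost --out report.json    # cohort cost report
limbcost sensitivity --cycle-range 2:5:0.5
limbcost simulate --seed 7 --n 500 --out synthetic.csv
limbcost normalize --amount 9952 --from GBP 1965
```

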