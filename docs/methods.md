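# Methods

## Model

The cohort model is a standard three-state Markov cohort (state-transition)
model: states `healthy`, `chronic`, `dead`, annual cycles, a 40-year
horizon (the literature's life-expectancy point for this cohort), starting
occupancy (1, 0, 0) and an absorbing death state. Occupancy propagates as
`π_t = π_{t-1} P`; care costs attach to occupancy of the living states at
the start of each cycle (cycles 0 … 39 price the 40 years lived; no
half-cycle correction). Discounting is available (`discount_rate`) but off
by default, matching the source model's presentation in "today's currency".

Prosthetic replacement runs in parallel with the health cycles rather than
inside the kernel: a component of unit cost `c_ℓ` is re-purchased every
`p` years (2.3 at baseline), so a limb contributes `c_ℓ · N(T, p)` over
horizon `T`. Three counting conventions are implemented because the
published arithmetic is internally inconsistent about which it used:

* `continuous` — `N = T/p`. The stream scales exactly as `2.3/p'` under a
  cycle-length change, which is the algebra the published one-way
  sensitivity percentages obey.
* `count_minus_one` — `N = T/p − 1` (floored at 0): the initial fitting is
  funded outside the 40-year stream. This reproduces the published
  additional-limb costs (£0.16M tibial, £0.45M femoral).
* `floor` — whole replacements only.

Both calibrated scenario files reproduce the published base packages
(£0.87M transtibial, £1.16M through-knee/transfemoral) with a *single*
40-year care constant, which is the over-determination that validates the
base/additional decomposition: £710,000 (£17,750/yr) under
`count_minus_one`, £692,400 (£17,310/yr) under `continuous`. The two
constants differ because the base limb's own stream differs by exactly one
unit cost between conventions.

### Cost accrual

By default accrual is deterministic: every casualty survives the horizon
and the published per-pattern totals are exact sums of components, which is
how the published figures add up. Occupancy-weighted accrual
(`mortality_weighted: true`) is provided for scenario analysis; under it
care follows the kernel's occupancy and the replacement stream accrues at
intensity `1/p` per year lived (a continuous-intensity approximation used
for every convention, preserving each convention's count offset). The
baseline transition kernel shipped in the scenario files
(healthy→{healthy .96, chronic .035, dead .005}; chronic→{chronic .93,
dead .07}) is a documented placeholder for a young, fit cohort — no
baseline kernel was ever published — and no headline quantity depends on
it because deterministic accrual is the default.

### Pattern costing

The costliest lower limb (ties broken lexically; through-knee priced
identically to transfemoral, as published) is the base limb and carries
care + own stream; each further lower limb adds a stream-only increment.
Foot amputations have no published base package and are priced stream-only
in any position. Upper-limb and hindquarter/forequarter events are stored
in the registry but excluded from costing, mirroring the source's scope.
Pattern totals are presented two ways: the exact component sum, and a
"printed-style" total in which each component is first rounded to £0.01M —
the published per-pattern figures (1.03, 1.32) are sums of rounded
components, and the double through-knee/transfemoral case is reported as
the component sum £1.61M with an annotation noting the published £1.60M.

## Canonical cohort reconstruction

The canonical fixture satisfies every published marginal exactly: 265
casualties, 416 events; patterns 140/101/22/2 (triple/quadruple split is
the unique nonnegative integer solution of 3t + 4q = 74 with
2·101 + 3t = 268); 89 transtibial singles; 38 transfemoral–transfemoral
doubles; 153 transfemoral and 143 transtibial events; 134 transfemoral
events among doubles and triples (read as excluding quadruples — the only
integer-consistent reading of "268 limbs"). Level cells not pinned by any
published figure (the 32 non-TT/TF singles, the 63 non-TF-TF doubles, all
triple/quadruple levels) are a committed synthetic fill: they were chosen
once, jointly with the canonical care calibration, so that the cohort
aggregate reproduces the published £288M headline to the nearest million
(£287.91M computed), and are frozen thereafter. Per-year counts reproduce
the legible published cells and fill the suppressed ones approximately,
constrained to the stated per-year mean extremes (1.0 in 2006, 1.7 in
2010); the provenance sidecar in `canonical_cohort.yaml` flags every cell
as printed, derived or reconstruction.

## Sensitivity analysis

The cycle-length one-way analysis uses the closed form
`Δtotal% = 100 · s · (2.3/p' − 1)` with `s` the baseline report's
prosthetic cost share, and is always verified against a full engine
re-costing (agreement to 1e-9 relative under the continuous convention).
Solving the two published percentages (+2.99% at 2 years, −10.75% at
5 years) for `s` gives 0.1993 and 0.1991 — three-decimal agreement, so a
single share underlies both. That share can only be the *representative
average patient's*: the published unit costs and level totals force the
cohort-level prosthetic share above 0.34 at any total near £288M, whereas
the single transtibial patient's share under the canonical calibration is
0.1999 — inside the implied band. The canonical sensitivity baseline is
therefore the one-casualty transtibial report, consistent with the source
model being run "on an assumed average patient"; the cohort report still
computes and exposes its own (larger) share.

The equal-transition "worst case" replaces both living rows of the kernel
with (1/3, 1/3, 1/3) — exactly one third, not the truncated 0.33, so rows
stay stochastic. With deterministic accrual its effect is identically
zero; with mortality weighting on, the computed variation is reported. The
published ±6.19% band for this scenario is attached as a reference
annotation only: the baseline kernel it perturbs was never published, so
the computation behind that figure is not reconstructible.

## Disclosure control

Published count tables suppress cells with `0 < value < threshold`
(default 5 — the smallest published cell is 7 and no threshold is stated,
so 5 is the conservative conventional choice). Zeros are left visible.
Complementary suppression then iterates over rows and columns assuming
margins are published: a line whose masked cells are uniquely determined
by its total (a single masked cell, or masked remainder zero) has its
smallest unmasked cell masked as well, preferring positive cells when the
remainder is zero, until no masked positive cell is recoverable from any
single row or column total. Non-recoverability is property-tested by an
independent solution-counting check on random tables up to 6×6.

## Synthetic generator

`generate_cohort` draws each casualty's pattern class, then that many limb
levels i.i.d. from the pattern's level distribution, and an injury year —
all from configurable marginal distributions with a fixed seed
(numpy `default_rng`), giving byte-identical output for identical
config + seed. It emulates the registry's *marginals* only: it does not
model within-casualty level correlation (e.g. bilateral symmetry), injury
mechanism, demographics, or the year-by-pattern interaction, so passing
tests demonstrate correct marginal behaviour and pipeline plumbing, not
clinical realism of joint structure. Default marginals for the canonical
emulation come from `marginals_config_from_summary` of the canonical
fixture (pattern probabilities (140, 101, 22, 2)/265).

## Currency normalization

Comparator costs are mapped to 2012 GBP by composite exchange × inflation
factors. The original conversions used archive rates and an inflation
calculator whose outputs are unrecoverable, so the packaged factor table
is a reconstruction: composites calibrated from printed pairs (Hertel
24,824 CHF → £104,609 gives 4.2140; Dundee £9,952 → £0.17M gives 17.082;
Chung USD 45,500 → £27,000 gives 0.5934) plus a synthetic split of the
Hertel composite into an exchange and an inflation step so factor
composition can be exercised. Factors calibrated from printed pairs take
precedence over chained fixture rates; the one factor calibrated on the
first Hertel pair reproduces the second printed conversion within 0.01%,
a cross-consistency check with no free parameter. The 5-year civilian
comparator schedule is `91,000 + (T−2)·3,700 + (T−2)·10,200/2` USD, the
biennial prosthetic cost annualized from year 2.

## Numerical choices and limitations

* Transition rows must sum to 1 within 1e-9 on input; occupancy
  conservation holds to 1e-12 along trajectories.
* Degenerate replacement periods longer than the horizon floor the
  `count_minus_one` count at zero rather than going negative.
* Cohort moments sort limb counts before summation so summaries are exactly
  permutation-invariant.
* Problem sizes are desk-scale throughout: the cohort is 265 records, the
  horizon 40 cycles; generator-based tests use n = 10,000 draws across 20
  seeds for goodness-of-fit.
* The model prices direct prosthetic, consumable and clinical activity
  costs only — no wheelchair or home-modification costs, no upper-limb
  provision, no comorbidity treatment, no productivity losses — so totals
  are a lower bound on the full burden of care.
* Time-varying transition kernels are out of scope (the config format
  leaves room, but the engine applies a single kernel).
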