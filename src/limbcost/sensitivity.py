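"""One-way and scenario sensitivity analyses on the cost model.

Two analyses are published for this model and are implemented as separate
operations:

* :func:`one_way_cycle` — vary the prosthetic replacement cycle length.
  Under the continuous replacement convention the prosthetic stream scales
  exactly as ``baseline_period / new_period`` with non-prosthetic costs held
  fixed, so the total-cost change has the closed form

      delta_total% = 100 * share * (baseline_period / new_period - 1)

  where ``share`` is the prosthetic cost share of the baseline report.  The
  closed form is verified against a full engine re-run.

* :func:`equal_transition_scenario` — the "worst case" in which every living
  state moves to each of healthy / chronic / dead with equal probability
  (exactly 1/3) each year.  This only perturbs costs when occupancy-weighted
  accrual is enabled.  The published +/-6.19% band for this scenario is
  carried as a reference annotation, not an assertion: the computational
  path from the scenario to that figure is not reconstructible because the
  baseline kernel it perturbs was never published.

The baseline report for the published one-way results is the representative
average-patient model (a single transtibial amputee under the canonical
scenario), whose prosthetic share of 0.1999 is the value implied by solving
each published percentage for the share (0.1993 and 0.1991).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace as dc_replace
from typing import Sequence

from .costing import (
    CohortCostReport,
    CostScenario,
    cohort_total_cost,
)
from .markov import (
    ReplacementConvention,
    ReplacementRule,
    TransitionMatrix,
    equal_transition_matrix,
)
from .registry import CasualtyRecord

__all__ = [
    "OneWayResult",
    "ScenarioResult",
    "one_way_cycle",
    "one_way_cycle_engine",
    "equal_transition_scenario",
    "implied_share",
    "tornado",
    "EQUAL_TRANSITION_REFERENCE_BAND",
]

#: Published variation band for the equal-transition worst case — reference
#: annotation only; see module docstring.
EQUAL_TRANSITION_REFERENCE_BAND = 6.19


@dataclass(frozen=True)
class OneWayResult:
    parameter: str
    baseline_value: float
    tested_value: float
    delta_prosthetic_percent: float
    delta_total_percent: float


@dataclass(frozen=True)
class ScenarioResult:
    scenario: str
    baseline_total: float
    scenario_total: float
    variation_percent: float
    reference_band_percent: float | None = None


def one_way_cycle(baseline: CohortCostReport, new_period: float) -> OneWayResult:
    """Closed-form effect of changing the replacement cycle length.

    Non-prosthetic costs are held fixed; the prosthetic stream is assumed
    proportional to ``1 / period`` (continuous convention).
    """
    if new_period <= 0:
        raise ValueError("replacement period must be positive")
    p0 = baseline.baseline_period
    scale = p0 / new_period - 1.0
    share = baseline.prosthetic_share
    return OneWayResult(
        parameter="replacement_period",
        baseline_value=p0,
        tested_value=new_period,
        delta_prosthetic_percent=100.0 * scale,
        delta_total_percent=100.0 * share * scale,
    )


def one_way_cycle_engine(
    cohort: Sequence[CasualtyRecord],
    scenario: CostScenario,
    new_period: float,
) -> OneWayResult:
    """Engine re-run counterpart of :func:`one_way_cycle`.

    Recomputes the full cohort report with the new period under the
    continuous convention and measures the change directly.
    """
    if scenario.rule.convention is not ReplacementConvention.CONTINUOUS:
        raise ValueError(
            "cycle-length one-way analysis requires the continuous convention"
        )
    base_report = cohort_total_cost(cohort, scenario)
    new_rule = ReplacementRule(
        period=new_period,
        convention=scenario.rule.convention,
        mortality_weighted=scenario.rule.mortality_weighted,
    )
    new_report = cohort_total_cost(cohort, dc_replace(scenario, rule=new_rule))
    d_total = 100.0 * (new_report.cohort_total / base_report.cohort_total - 1.0)
    d_pros = 100.0 * (
        new_report.prosthetic_total / base_report.prosthetic_total - 1.0
    )
    return OneWayResult(
        parameter="replacement_period",
        baseline_value=scenario.rule.period,
        tested_value=new_period,
        delta_prosthetic_percent=d_pros,
        delta_total_percent=d_total,
    )


def implied_share(delta_total_percent: float, new_period: float, baseline_period: float = 2.3) -> float:
    """Solve a one-way result for the prosthetic share it implies."""
    scale = baseline_period / new_period - 1.0
    if scale == 0:
        raise ValueError("tested period equals the baseline; share is undefined")
    return abs(delta_total_percent) / (100.0 * abs(scale))


def equal_transition_scenario(
    cohort: Sequence[CasualtyRecord],
    scenario: CostScenario,
) -> ScenarioResult:
    """Re-cost the cohort under the equal-transition worst-case kernel.

    With mortality weighting off the model accrues costs deterministically
    and the scenario changes nothing (variation exactly 0); with weighting
    on, occupancy collapses quickly toward death and costs fall.  The
    published band is attached as a reference annotation either way.
    """
    baseline = cohort_total_cost(cohort, scenario)
    perturbed = dc_replace(scenario, transitions=equal_transition_matrix())
    result = cohort_total_cost(cohort, perturbed)
    variation = (
        100.0 * (result.cohort_total / baseline.cohort_total - 1.0)
        if baseline.cohort_total
        else 0.0
    )
    return ScenarioResult(
        scenario="equal_transition_probability",
        baseline_total=baseline.cohort_total,
        scenario_total=result.cohort_total,
        variation_percent=variation,
        reference_band_percent=EQUAL_TRANSITION_REFERENCE_BAND,
    )


def tornado(
    baseline: CohortCostReport,
    periods: Sequence[float],
) -> list[OneWayResult]:
    """One-way results for a set of cycle lengths, ranked by |total effect|.

    Duplicate periods are dropped with a warning; an empty range is an error.
    """
    if len(periods) == 0:
        raise ValueError("tornado requires at least one tested period")
    seen: list[float] = []
    for p in periods:
        if p in seen:
            warnings.warn(f"duplicate tested period {p} dropped", stacklevel=2)
        else:
            seen.append(p)
    results = [one_way_cycle(baseline, p) for p in seen]
    return sorted(results, key=lambda r: abs(r.delta_total_percent), reverse=True)
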