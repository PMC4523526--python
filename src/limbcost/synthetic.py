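"""Canonical fixture cohort and seeded synthetic cohort generation.

No casualty-level registry extract is publicly deposited, so the package
carries two substitutes:

* :func:`canonical_cohort` — a deterministic reconstruction that reproduces
  every published cohort marginal exactly (casualty and limb totals, pattern
  counts, the quoted level cells).  Level assignments the publication does
  not pin down are a committed synthetic fill, documented cell-by-cell in
  ``data/canonical_cohort.yaml`` with a provenance flag.
* :func:`generate_cohort` — a seeded stochastic generator drawing casualty
  patterns, per-limb levels and injury years from configurable marginal
  distributions, for property testing and what-if cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import yaml

from .registry import (
    AmputationEvent,
    AmputationLevel,
    CasualtyRecord,
    Cohort,
    CohortSummary,
    CohortValidationError,
    PatternClass,
    Side,
)

__all__ = [
    "GeneratorConfig",
    "canonical_cohort",
    "canonical_composition",
    "generate_cohort",
    "marginals_config_from_summary",
]

_DIST_TOL = 1e-9


def _check_distribution(dist: Mapping, what: str) -> None:
    total = float(sum(dist.values()))
    if any(p < 0 for p in dist.values()):
        raise ValueError(f"{what} has a negative probability")
    if abs(total - 1.0) > _DIST_TOL:
        raise ValueError(f"{what} sums to {total!r}, expected 1")


@dataclass(frozen=True)
class GeneratorConfig:
    """Marginal distributions for the stochastic cohort generator.

    ``level_distribution_by_pattern`` maps each pattern class to the level
    distribution from which that casualty's limbs are drawn independently.
    """

    n_casualties: int
    pattern_distribution: Mapping[PatternClass, float]
    level_distribution_by_pattern: Mapping[PatternClass, Mapping[AmputationLevel, float]]
    year_distribution: Mapping[int, float]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_casualties < 1:
            raise ValueError("n_casualties must be >= 1")
        _check_distribution(self.pattern_distribution, "pattern_distribution")
        _check_distribution(self.year_distribution, "year_distribution")
        for pc, dist in self.level_distribution_by_pattern.items():
            _check_distribution(dist, f"level distribution for {PatternClass(pc).label}")


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Draw a synthetic cohort; identical config and seed give identical output."""
    rng = np.random.default_rng(config.seed)

    patterns = sorted(config.pattern_distribution, key=int)
    p_pattern = np.array([config.pattern_distribution[pc] for pc in patterns])
    years = sorted(config.year_distribution)
    p_year = np.array([config.year_distribution[y] for y in years])

    cohort: Cohort = []
    width = len(str(config.n_casualties))
    for i in range(config.n_casualties):
        cid = f"S{i + 1:0{width}d}"
        pc = patterns[rng.choice(len(patterns), p=p_pattern)]
        year = years[rng.choice(len(years), p=p_year)]
        level_dist = config.level_distribution_by_pattern[pc]
        levels = sorted(level_dist, key=lambda l: l.value)
        p_level = np.array([level_dist[l] for l in levels])
        events = tuple(
            AmputationEvent(
                casualty_id=cid,
                level=levels[rng.choice(len(levels), p=p_level)],
                year=year,
            )
            for _ in range(int(pc))
        )
        cohort.append(CasualtyRecord(cid, year, events))
    return cohort


def marginals_config_from_summary(
    summary: CohortSummary, n_casualties: int | None = None, seed: int = 0
) -> GeneratorConfig:
    """Empirical generator config whose expected marginals equal a summary's."""
    if summary.n_casualties == 0:
        raise CohortValidationError("summary has zero casualties")
    n = summary.n_casualties
    pattern_dist = {pc: c / n for pc, c in summary.by_pattern.items()}
    # Without per-pattern level detail in the summary, every pattern shares
    # the cohort-wide empirical level distribution.
    level_dist = {
        lvl: c / summary.n_limbs for lvl, c in summary.by_level.items()
    }
    year_dist = {y: c["total"] / n for y, c in summary.by_year.items()}
    return GeneratorConfig(
        n_casualties=n_casualties or n,
        pattern_distribution=pattern_dist,
        level_distribution_by_pattern={pc: level_dist for pc in pattern_dist},
        year_distribution=year_dist,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Canonical fixture
# ---------------------------------------------------------------------------


def canonical_composition() -> dict:
    """The committed canonical composition document (parsed YAML)."""
    ref = resources.files("limbcost.data").joinpath("canonical_cohort.yaml")
    return yaml.safe_load(ref.read_text())


def canonical_cohort() -> Cohort:
    """Deterministic reconstruction of the 2003-2014 amputee cohort.

    Satisfies every published marginal: 265 casualties / 416 events, pattern
    counts 140/101/22/2, 89 transtibial singles, 38 double transfemorals,
    153 transfemoral and 143 transtibial events, 134 transfemoral events
    among double and triple amputees.
    """
    doc = canonical_composition()
    cohort: Cohort = []
    counter = 0
    for klass in ("single", "double", "triple", "quadruple"):
        pattern_list: list[tuple[AmputationLevel, ...]] = []
        for entry in doc["patterns"][klass]:
            levels = tuple(AmputationLevel(l) for l in entry["levels"])
            pattern_list.extend([levels] * int(entry["count"]))
        year_list: list[int] = []
        for year, count in sorted(doc["years"][klass].items()):
            year_list.extend([int(year)] * int(count))
        if len(pattern_list) != len(year_list):
            raise CohortValidationError(
                f"canonical composition: {klass} pattern and year counts differ"
            )
        for levels, year in zip(pattern_list, year_list):
            counter += 1
            cid = f"C{counter:03d}"
            events = tuple(
                AmputationEvent(casualty_id=cid, level=lvl, year=year, side=Side.UNKNOWN)
                for lvl in levels
            )
            cohort.append(CasualtyRecord(cid, year, events))
    return cohort
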