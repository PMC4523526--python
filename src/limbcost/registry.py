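"""Amputee cohort registry: loading, validation, classification and summaries.

The registry holds one record per casualty, each carrying the per-limb
amputation events (level, side, injury year) sustained between 2003 and 2014.
Casualties are classified by amputation *pattern* (single, double, triple,
quadruple) and summarised into the per-year / per-level / per-pattern count
tables used downstream by the costing stages.  Published count tables pass
through small-cell suppression (statistical disclosure control) before
rendering, mirroring the Defence Statistics practice of masking cells that
could identify an individual.
"""

from __future__ import annotations

import enum
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AmputationLevel",
    "Side",
    "PatternClass",
    "AmputationEvent",
    "CasualtyRecord",
    "CohortSummary",
    "SuppressionPolicy",
    "SchemaError",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "classify_pattern",
    "summarize",
    "level_marginals",
    "LevelMarginals",
    "apply_suppression",
    "LOWER_LIMB_LEVELS",
    "DEFAULT_YEAR_RANGE",
]

DEFAULT_YEAR_RANGE = (2003, 2014)


class SchemaError(ValueError):
    """Raised when an input table is missing a required column."""


class CohortValidationError(ValueError):
    """Raised when cohort data violates a domain invariant."""


class AmputationLevel(str, enum.Enum):
    """Anatomical level of a single amputation."""

    TRANSFEMORAL = "transfemoral"
    THROUGH_KNEE = "through_knee"
    TRANSTIBIAL = "transtibial"
    FOOT = "foot"
    HIND_OR_FOREQUARTER = "hind_or_forequarter"
    UPPER_LIMB = "upper_limb"


#: Levels that belong to the lower limb and are in scope for prosthetic costing.
LOWER_LIMB_LEVELS = frozenset(
    {
        AmputationLevel.TRANSFEMORAL,
        AmputationLevel.THROUGH_KNEE,
        AmputationLevel.TRANSTIBIAL,
        AmputationLevel.FOOT,
    }
)


class Side(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"
    UNKNOWN = "unknown"


class PatternClass(enum.IntEnum):
    """Number of limbs lost by a casualty, clamped to the published classes."""

    SINGLE = 1
    DOUBLE = 2
    TRIPLE = 3
    QUADRUPLE = 4

    @property
    def label(self) -> str:
        return self.name.lower()


@dataclass(frozen=True)
class AmputationEvent:
    """One amputation sustained by one casualty."""

    casualty_id: str
    level: AmputationLevel
    year: int
    side: Side = Side.UNKNOWN

    def __post_init__(self) -> None:
        if not isinstance(self.level, AmputationLevel):
            object.__setattr__(self, "level", AmputationLevel(self.level))
        if not isinstance(self.side, Side):
            object.__setattr__(self, "side", Side(self.side))
        if int(self.year) != self.year:
            raise CohortValidationError(f"year must be an integer, got {self.year!r}")


@dataclass(frozen=True)
class CasualtyRecord:
    """One casualty and the amputation events they sustained."""

    casualty_id: str
    injury_year: int
    events: tuple[AmputationEvent, ...]

    def __post_init__(self) -> None:
        if len(self.events) == 0:
            raise CohortValidationError(
                f"casualty {self.casualty_id!r} has no amputation events"
            )
        for ev in self.events:
            if ev.casualty_id != self.casualty_id:
                raise CohortValidationError(
                    f"event casualty_id {ev.casualty_id!r} does not match "
                    f"record {self.casualty_id!r}"
                )

    @property
    def n_limbs(self) -> int:
        return len(self.events)

    @property
    def levels(self) -> tuple[AmputationLevel, ...]:
        return tuple(ev.level for ev in self.events)

    @property
    def lower_limb_levels(self) -> tuple[AmputationLevel, ...]:
        return tuple(ev.level for ev in self.events if ev.level in LOWER_LIMB_LEVELS)


Cohort = list[CasualtyRecord]


def classify_pattern(record: CasualtyRecord) -> PatternClass:
    """Classify a casualty by number of limbs lost (1-4).

    More than four amputations per casualty is rejected: it is anatomically
    impossible for major limb loss and always indicates duplicated rows.
    """
    n = record.n_limbs
    if n < 1 or n > 4:
        raise CohortValidationError(
            f"casualty {record.casualty_id!r} has {n} events; expected 1-4"
        )
    return PatternClass(n)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ("casualty_id", "injury_year", "level", "side")


def read_cohort(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    year_range: tuple[int, int] = DEFAULT_YEAR_RANGE,
) -> Cohort:
    """Read a casualty-level cohort CSV (one row per amputation event).

    Parameters
    ----------
    path
        CSV with header ``casualty_id,injury_year,level,side``.
    schema
        Optional mapping from the required logical column names to the
        names actually present in the file.
    year_range
        Inclusive bounds for valid injury years.

    Returns
    -------
    list of :class:`CasualtyRecord`, one per distinct casualty id, in order
    of first appearance.
    """
    schema = dict(schema or {})
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    colmap = {logical: schema.get(logical, logical) for logical in _REQUIRED_COLUMNS}
    for logical, actual in colmap.items():
        if logical == "side" and actual not in df.columns:
            df[actual] = Side.UNKNOWN.value  # laterality is never used downstream
            continue
        if actual not in df.columns:
            raise SchemaError(f"missing required column {actual!r} (for {logical!r})")

    records: dict[str, list[AmputationEvent]] = {}
    injury_years: dict[str, int] = {}
    lo, hi = year_range
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        cid = getattr(row, colmap["casualty_id"])
        raw_level = getattr(row, colmap["level"])
        raw_year = getattr(row, colmap["injury_year"])
        raw_side = getattr(row, colmap["side"]) or Side.UNKNOWN.value
        try:
            level = AmputationLevel(raw_level)
        except ValueError:
            raise CohortValidationError(
                f"line {i}: unknown amputation level {raw_level!r}"
            ) from None
        try:
            year = int(raw_year)
        except ValueError:
            raise CohortValidationError(
                f"line {i}: injury_year {raw_year!r} is not an integer"
            ) from None
        if not (lo <= year <= hi):
            raise CohortValidationError(
                f"line {i}: injury_year {year} outside [{lo}, {hi}]"
            )
        try:
            side = Side(raw_side)
        except ValueError:
            raise CohortValidationError(f"line {i}: unknown side {raw_side!r}") from None
        records.setdefault(cid, []).append(
            AmputationEvent(casualty_id=cid, level=level, year=year, side=side)
        )
        injury_years.setdefault(cid, year)

    return [
        CasualtyRecord(cid, injury_years[cid], tuple(events))
        for cid, events in records.items()
    ]


def write_cohort(cohort: Iterable[CasualtyRecord], path: str | Path) -> None:
    """Write a cohort back to the event-level CSV format read by read_cohort."""
    rows = [
        {
            "casualty_id": rec.casualty_id,
            "injury_year": ev.year,
            "level": ev.level.value,
            "side": ev.side.value,
        }
        for rec in cohort
        for ev in rec.events
    ]
    pd.DataFrame(rows, columns=list(_REQUIRED_COLUMNS)).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class YearCounts:
    single: int
    double: int
    triple_plus: int

    @property
    def total(self) -> int:
        return self.single + self.double + self.triple_plus

    # limbs is not derivable from the triple_plus aggregate alone; stored
    # explicitly by summarize.


@dataclass(frozen=True)
class CohortSummary:
    """Descriptive statistics of a cohort.

    ``sd_limbs`` is the presentation value (sample, ``ddof`` as requested);
    the population form is retained alongside because both round to the same
    published 2-dp figure and the choice is cosmetic.
    """

    n_casualties: int
    n_limbs: int
    mean_limbs: float
    sd_limbs: float
    sd_limbs_population: float
    by_year: dict[int, dict[str, int]]
    by_level: dict[AmputationLevel, int]
    by_pattern: dict[PatternClass, int]
    double_subpatterns: dict[tuple[AmputationLevel, ...], int]
    ddof: int = 1

    @property
    def mean_limbs_1dp(self) -> float:
        return round(self.mean_limbs, 1)

    @property
    def sd_limbs_2dp(self) -> float:
        return round(self.sd_limbs, 2)

    def to_json(self, *, indent: int | None = None) -> str:
        payload = {
            "n_casualties": self.n_casualties,
            "n_limbs": self.n_limbs,
            "mean_limbs": self.mean_limbs,
            "mean_limbs_1dp": self.mean_limbs_1dp,
            "sd_limbs": self.sd_limbs,
            "sd_limbs_population": self.sd_limbs_population,
            "sd_limbs_2dp": self.sd_limbs_2dp,
            "by_year": {
                str(y): dict(c) for y, c in sorted(self.by_year.items())
            },
            "by_level": {lvl.value: n for lvl, n in self.by_level.items()},
            "by_pattern": {pc.label: n for pc, n in self.by_pattern.items()},
            "double_subpatterns": {
                "+".join(l.value for l in pair): n
                for pair, n in sorted(
                    self.double_subpatterns.items(),
                    key=lambda kv: (-kv[1], kv[0]),
                )
            },
        }
        return json.dumps(payload, indent=indent)


def summarize(cohort: Sequence[CasualtyRecord], ddof: int = 1) -> CohortSummary:
    """Summarise a cohort: counts by year/level/pattern and limb-count moments."""
    if len(cohort) == 0:
        raise CohortValidationError("cannot summarise an empty cohort")

    # sorted so the moments are exactly permutation-invariant
    limbs = np.sort(np.array([rec.n_limbs for rec in cohort], dtype=float))
    by_pattern: Counter = Counter(classify_pattern(rec) for rec in cohort)
    by_level: Counter = Counter(ev.level for rec in cohort for ev in rec.events)

    by_year: dict[int, dict[str, int]] = {}
    for rec in cohort:
        pc = classify_pattern(rec)
        y = by_year.setdefault(
            rec.injury_year,
            {"single": 0, "double": 0, "triple_plus": 0, "total": 0, "limbs": 0},
        )
        key = "triple_plus" if pc >= PatternClass.TRIPLE else pc.label
        y[key] += 1
        y["total"] += 1
        y["limbs"] += rec.n_limbs

    double_subpatterns: Counter = Counter(
        tuple(sorted(rec.levels, key=lambda l: l.value))
        for rec in cohort
        if rec.n_limbs == 2
    )

    n = len(limbs)
    mean = float(limbs.mean())
    sd_pop = float(limbs.std(ddof=0))
    sd = float(limbs.std(ddof=ddof)) if n > ddof else 0.0
    return CohortSummary(
        n_casualties=n,
        n_limbs=int(limbs.sum()),
        mean_limbs=mean,
        sd_limbs=sd,
        sd_limbs_population=sd_pop,
        by_year={y: dict(c) for y, c in sorted(by_year.items())},
        by_level=dict(by_level),
        by_pattern=dict(by_pattern),
        double_subpatterns=dict(double_subpatterns),
        ddof=ddof,
    )


@dataclass(frozen=True)
class LevelMarginals:
    """Level counts and level-by-pattern cross-tabulation."""

    by_level: dict[AmputationLevel, int]
    level_by_pattern: pd.DataFrame  # rows: level value, columns: pattern label
    transtibial_singles: int
    transfemoral_in_doubles_and_triples: int
    double_subpatterns: dict[tuple[AmputationLevel, ...], int]


def level_marginals(cohort: Sequence[CasualtyRecord]) -> LevelMarginals:
    """Cross-tabulate amputation levels against casualty pattern class.

    Also surfaces the derived cells quoted in cohort descriptions: transtibial
    events among single amputees, transfemoral events among double and triple
    amputees, and the per-pair breakdown of double amputees.
    """
    rows = [
        {"level": ev.level.value, "pattern": classify_pattern(rec).label}
        for rec in cohort
        for ev in rec.events
    ]
    df = pd.DataFrame(rows, columns=["level", "pattern"])
    xtab = (
        pd.crosstab(df["level"], df["pattern"])
        if len(df)
        else pd.DataFrame()
    )

    by_level: Counter = Counter(ev.level for rec in cohort for ev in rec.events)
    tt_singles = sum(
        1
        for rec in cohort
        if rec.n_limbs == 1 and rec.events[0].level is AmputationLevel.TRANSTIBIAL
    )
    tf_multi = sum(
        1
        for rec in cohort
        if rec.n_limbs in (2, 3)
        for ev in rec.events
        if ev.level is AmputationLevel.TRANSFEMORAL
    )
    double_subpatterns: Counter = Counter(
        tuple(sorted(rec.levels, key=lambda l: l.value))
        for rec in cohort
        if rec.n_limbs == 2
    )
    return LevelMarginals(
        by_level=dict(by_level),
        level_by_pattern=xtab,
        transtibial_singles=tt_singles,
        transfemoral_in_doubles_and_triples=tf_multi,
        double_subpatterns=dict(double_subpatterns),
    )


# ---------------------------------------------------------------------------
# Statistical disclosure control
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SuppressionPolicy:
    """Small-cell suppression policy.

    Cells with ``0 < value < threshold`` are replaced by ``marker``.  Zero
    cells are left visible (a zero carries no disclosure risk); cells at or
    above the threshold are published.  The published row and column totals
    are then checked for residual disclosure and complementary cells are
    suppressed until no masked positive cell is recoverable from a single
    row or column total.
    """

    threshold: int = 5
    marker: str = "#"

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValueError("suppression threshold must be >= 0")


def _line_recoverable(values: np.ndarray, suppressed: np.ndarray) -> bool:
    """True if the suppressed cells of one line are forced by its total.

    With the line total published and the visible cells known, the masked
    cells are uniquely determined iff only one cell is masked, or the masked
    remainder is zero (every masked cell forced to 0).
    """
    k = int(suppressed.sum())
    if k == 0:
        return False
    remainder = int(values[suppressed].sum())
    return k == 1 or remainder == 0


def apply_suppression(
    table: pd.DataFrame, policy: SuppressionPolicy = SuppressionPolicy()
) -> pd.DataFrame:
    """Apply primary and complementary small-cell suppression to a count table.

    Returns an object-dtype frame in which masked cells carry the policy
    marker.  Idempotent: a frame that already contains markers is returned
    unchanged apart from any still-unmasked small cells (markers are treated
    as already-suppressed cells of unknown value, and lines containing them
    are not re-examined for complementary disclosure).
    """
    marker_mask = table.apply(
        lambda col: col.map(lambda v: isinstance(v, str))
    ).to_numpy(dtype=bool)
    values = np.where(marker_mask, 0, table.to_numpy(dtype=object)).astype(np.int64)
    if (values < 0).any():
        raise ValueError("count table contains negative cells")

    suppressed = marker_mask | ((values > 0) & (values < policy.threshold))

    if not marker_mask.any():
        # Complementary suppression against the published margins.
        nrow, ncol = values.shape
        changed = True
        while changed:
            changed = False
            lines = [("r", i) for i in range(nrow)] + [("c", j) for j in range(ncol)]
            for axis, idx in lines:
                vals = values[idx, :] if axis == "r" else values[:, idx]
                supp = suppressed[idx, :] if axis == "r" else suppressed[:, idx]
                if not _line_recoverable(vals, supp):
                    continue
                candidates = np.flatnonzero(~supp)
                if candidates.size == 0:
                    continue  # fully masked all-zero line: nothing sensitive left
                remainder = int(vals[supp].sum())
                if remainder == 0:
                    positive = candidates[vals[candidates] > 0]
                    pick = (
                        positive[np.argmin(vals[positive])]
                        if positive.size
                        else candidates[0]
                    )
                else:
                    pick = candidates[np.argmin(vals[candidates])]
                if axis == "r":
                    suppressed[idx, pick] = True
                else:
                    suppressed[pick, idx] = True
                changed = True

    out = table.copy().astype(object)
    out_vals = out.to_numpy(dtype=object)
    out_vals[suppressed] = policy.marker
    return pd.DataFrame(out_vals, index=table.index, columns=table.columns)
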