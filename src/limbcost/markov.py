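"""Three-state Markov cohort engine with a parallel prosthetic cost stream.

The health model has three states — ``healthy``, ``chronic`` and ``dead`` —
stepped in one-year cycles over a 40-year horizon.  Care costs attach to
state occupancy per cycle.  Prosthetic replacement costs run in parallel to
the health cycles: a component is re-purchased every ``period`` years
(2.3 years at baseline), under one of three counting conventions:

``continuous``
    ``horizon / period`` replacements — the replacement *rate* integrated
    over the horizon.  Under this convention the stream scales exactly as
    ``baseline_period / new_period`` when the cycle length changes, which is
    the algebra behind the one-way cycle-length sensitivity.
``count_minus_one``
    ``horizon / period - 1`` — the initial fitting is funded outside the
    40-year stream and only subsequent exchanges are counted.  This is the
    convention that reproduces the published additional-limb costs.
``floor``
    ``floor(horizon / period)`` whole replacements.

By default cost accrual is deterministic (every casualty survives the
horizon); occupancy-weighted accrual is available for scenario analyses.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "STATES",
    "ReplacementConvention",
    "TransitionMatrix",
    "MarkovConfig",
    "CareCostSchedule",
    "ReplacementRule",
    "TransitionValidationError",
    "validate_transitions",
    "run_occupancy",
    "expected_care_cost",
    "replacement_count",
    "prosthetic_stream_cost",
    "stay_healthy_matrix",
    "equal_transition_matrix",
    "DEFAULT_TRANSITIONS",
]

#: Ordered state space; ``dead`` is absorbing.
STATES = ("healthy", "chronic", "dead")
_HEALTHY, _CHRONIC, _DEAD = 0, 1, 2

_ROW_TOL = 1e-12


class TransitionValidationError(ValueError):
    """Raised when a transition matrix is not a valid 3-state kernel."""


class ReplacementConvention(str, enum.Enum):
    CONTINUOUS = "continuous"
    COUNT_MINUS_ONE = "count_minus_one"
    FLOOR = "floor"


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic 3x3 annual transition kernel with absorbing death."""

    p: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "p", np.asarray(self.p, dtype=float))
        _check_transitions(self.p)

    def __array__(self, dtype=None, copy=None):
        return np.array(self.p, dtype=dtype)


def _check_transitions(p: np.ndarray) -> None:
    if p.shape != (3, 3):
        raise TransitionValidationError(f"expected a 3x3 matrix, got shape {p.shape}")
    if (p < 0).any() or (p > 1).any():
        bad = int(np.argwhere((p < 0) | (p > 1))[0][0])
        raise TransitionValidationError(
            f"row {STATES[bad]!r} has an entry outside [0, 1]"
        )
    for i, s in enumerate(p.sum(axis=1)):
        if abs(s - 1.0) > 1e-9:
            raise TransitionValidationError(
                f"row {STATES[i]!r} sums to {s:.6g}, expected 1"
            )
    if not np.array_equal(p[_DEAD], [0.0, 0.0, 1.0]):
        raise TransitionValidationError("dead state must be absorbing: row (0, 0, 1)")


def validate_transitions(m: TransitionMatrix | np.ndarray) -> TransitionMatrix:
    """Validate a 3x3 row-stochastic matrix with an absorbing dead state.

    Returns the validated :class:`TransitionMatrix`; raises
    :class:`TransitionValidationError` naming the offending row otherwise.
    """
    if isinstance(m, TransitionMatrix):
        _check_transitions(m.p)
        return m
    return TransitionMatrix(np.asarray(m, dtype=float))


def stay_healthy_matrix() -> TransitionMatrix:
    """Degenerate kernel with no morbidity or mortality (identity transitions)."""
    return TransitionMatrix(np.eye(3))


def equal_transition_matrix() -> TransitionMatrix:
    """The worst-case scenario kernel: each living state moves to each of the
    three states with equal probability (exactly 1/3, not the truncated 0.33,
    so rows remain stochastic)."""
    third = 1.0 / 3.0
    return TransitionMatrix(
        np.array([[third, third, third], [third, third, third], [0.0, 0.0, 1.0]])
    )


#: Placeholder baseline transitions for a young, fit amputee cohort; the
#: source model never publishes its baseline kernel, and every headline
#: quantity is computed under deterministic accrual, which is insensitive
#: to this choice.  Overridable in any scenario file.
DEFAULT_TRANSITIONS = np.array(
    [
        [0.960, 0.035, 0.005],
        [0.000, 0.930, 0.070],
        [0.000, 0.000, 1.000],
    ]
)


@dataclass(frozen=True)
class MarkovConfig:
    """Cycle structure of the cohort model.

    cycle_length is fixed at one year; ``horizon`` counts cycles.  Costs are
    undiscounted by default and no half-cycle correction is applied.
    """

    horizon: int = 40
    cycle_length: float = 1.0
    initial_occupancy: tuple[float, float, float] = (1.0, 0.0, 0.0)
    discount_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")
        occ = np.asarray(self.initial_occupancy, dtype=float)
        if occ.shape != (3,) or (occ < 0).any() or abs(occ.sum() - 1.0) > 1e-9:
            raise ValueError("initial_occupancy must be a probability 3-vector")


@dataclass(frozen=True)
class CareCostSchedule:
    """Annual care cost (GBP) attached to each year lived in a state."""

    healthy: float
    chronic: float | None = None  # defaults to healthy (no published excess)

    def __post_init__(self) -> None:
        if self.chronic is None:
            object.__setattr__(self, "chronic", self.healthy)
        if self.healthy < 0 or self.chronic < 0:
            raise ValueError("care costs must be nonnegative")

    @property
    def vector(self) -> np.ndarray:
        return np.array([self.healthy, self.chronic, 0.0])


@dataclass(frozen=True)
class ReplacementRule:
    """Prosthetic replacement-cycle rule run in parallel with health cycles."""

    period: float = 2.3
    convention: ReplacementConvention = ReplacementConvention.CONTINUOUS
    mortality_weighted: bool = False

    def __post_init__(self) -> None:
        if not isinstance(self.convention, ReplacementConvention):
            object.__setattr__(
                self, "convention", ReplacementConvention(self.convention)
            )
        if self.period <= 0:
            raise ValueError("replacement period must be positive")


def run_occupancy(m: TransitionMatrix, cfg: MarkovConfig) -> np.ndarray:
    """Propagate cohort occupancy through the horizon.

    Returns an array of shape ``(horizon + 1, 3)``; row ``t`` is the state
    distribution after ``t`` cycles (row 0 is the initial occupancy).
    """
    if not isinstance(m, TransitionMatrix):
        m = TransitionMatrix(m)
    traj = np.empty((cfg.horizon + 1, 3))
    traj[0] = cfg.initial_occupancy
    for t in range(1, cfg.horizon + 1):
        traj[t] = traj[t - 1] @ m.p
    return traj


def expected_care_cost(
    trajectory: np.ndarray,
    schedule: CareCostSchedule,
    cfg: MarkovConfig,
) -> float:
    """Expected discounted care cost over the horizon.

    Each cycle's cost is the living-state occupancy at the *start* of the
    cycle (cycles 0 .. horizon-1) times the annual state cost, discounted at
    ``cfg.discount_rate``; the final trajectory row prices no further cycle.
    With identity transitions this is exactly ``horizon * healthy_cost``.
    """
    traj = np.asarray(trajectory, dtype=float)
    costs = traj[: cfg.horizon] @ schedule.vector
    if cfg.discount_rate:
        costs = costs / (1.0 + cfg.discount_rate) ** np.arange(cfg.horizon)
    return float(costs.sum())


def replacement_count(horizon: float, rule: ReplacementRule) -> float:
    """Number of prosthetic replacements over the horizon under a rule.

    ``count_minus_one`` is floored at zero so a degenerate period longer than
    the horizon never produces a negative replacement count.
    """
    if rule.period <= 0:
        raise ValueError("replacement period must be positive")
    ratio = horizon / rule.period
    if rule.convention is ReplacementConvention.CONTINUOUS:
        return ratio
    if rule.convention is ReplacementConvention.COUNT_MINUS_ONE:
        return max(ratio - 1.0, 0.0)
    return float(np.floor(ratio))


def prosthetic_stream_cost(
    components: Sequence[float],
    rule: ReplacementRule,
    horizon: float,
    trajectory: np.ndarray | None = None,
) -> float:
    """Cost of the prosthetic replacement stream over the horizon.

    ``components`` are the per-level unit costs replaced each cycle.  When
    ``rule.mortality_weighted`` is set and a trajectory is supplied, the
    replacement intensity ``1/period`` per year is prorated by the living
    occupancy of each year (a continuous-intensity approximation applied to
    every convention, with the convention's count offset preserved).
    """
    components = np.asarray(list(components), dtype=float)
    if (components < 0).any():
        raise ValueError("component costs must be nonnegative")
    unit = float(components.sum())
    if unit == 0.0:
        return 0.0
    count = replacement_count(horizon, rule)
    if rule.mortality_weighted and trajectory is not None:
        traj = np.asarray(trajectory, dtype=float)
        alive = traj[: int(horizon), :_DEAD].sum(axis=1)
        weighted = float(alive.sum()) / rule.period
        offset = horizon / rule.period - count  # 0, 1, or fractional remainder
        count = max(weighted - offset, 0.0)
    return unit * count
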