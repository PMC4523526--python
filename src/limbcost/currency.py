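"""Currency and inflation normalization for literature cost comparators.

Costs quoted by comparator studies (1996 Swiss Francs, 2009 US dollars,
1965 pounds) are placed on a common 2012-GBP basis through composite
exchange-rate x inflation factors.  The original conversions were produced
with the Bank of England's archive rates and inflation calculator, whose
exact outputs are not recoverable; the packaged factor table is therefore a
reconstruction calibrated against the printed conversion pairs (the
provenance column says which), and factors calibrated directly from a
printed pair take precedence over chained fixture rates.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

__all__ = [
    "CurrencyFactor",
    "LiteratureCostRecord",
    "calibrate_factor",
    "convert",
    "compose_factors",
    "chung_cost_schedule",
    "load_factor_table",
    "packaged_factor_table",
]


@dataclass(frozen=True)
class CurrencyFactor:
    """Composite multiplier mapping (currency, year) -> (currency, year)."""

    source: tuple[str, int]
    target: tuple[str, int]
    factor: float
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise ValueError("conversion factor must be positive")


@dataclass(frozen=True)
class LiteratureCostRecord:
    """One literature comparator cost and its normalized 2012-GBP value."""

    study: str
    native_amount: float
    native_currency: str
    native_year: int
    normalized_gbp: float
    schedule: str = "one_off"  # one_off | annual | biennial


def calibrate_factor(
    native: float,
    normalized: float,
    source: tuple[str, int] = ("", 0),
    target: tuple[str, int] = ("GBP", 2012),
) -> CurrencyFactor:
    """Back out the composite factor from a printed (native, normalized) pair."""
    if native <= 0 or normalized <= 0:
        raise ValueError("amounts must be positive to calibrate a factor")
    return CurrencyFactor(
        source=source,
        target=target,
        factor=normalized / native,
        provenance="calibrated from printed pair",
    )


def convert(amount: float, factor: CurrencyFactor) -> float:
    """Apply a composite factor; rounding happens only at presentation."""
    if amount < 0:
        raise ValueError("amount must be nonnegative")
    return amount * factor.factor


def compose_factors(a: CurrencyFactor, b: CurrencyFactor) -> CurrencyFactor:
    """Chain two factors (e.g. exchange then inflation); endpoints must meet."""
    if a.target != b.source:
        raise ValueError(
            f"cannot compose: first factor targets {a.target}, "
            f"second starts from {b.source}"
        )
    return CurrencyFactor(
        source=a.source,
        target=b.target,
        factor=a.factor * b.factor,
        provenance=f"composed({a.provenance}; {b.provenance})",
    )


def chung_cost_schedule(
    horizon: float,
    first_two_years: float = 91_000.0,
    annual_ongoing: float = 3_700.0,
    biennial_prosthetic: float = 10_200.0,
) -> float:
    """Cumulative per-patient cost (USD) under the cited civilian schedule.

    A fixed total covers the first two years; thereafter an annual ongoing
    cost accrues for life, plus a biennial prosthetic cost annualized at
    half its value per year from year 2 onward.
    """
    if horizon < 2:
        raise ValueError("the schedule is defined from year 2 onward")
    tail = horizon - 2.0
    return first_two_years + tail * annual_ongoing + tail * (biennial_prosthetic / 2.0)


def load_factor_table(path: str | Path) -> list[CurrencyFactor]:
    """Load a factor table CSV: source_currency,source_year,target_currency,
    target_year,factor,provenance."""
    out: list[CurrencyFactor] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                CurrencyFactor(
                    source=(row["source_currency"], int(row["source_year"])),
                    target=(row["target_currency"], int(row["target_year"])),
                    factor=float(row["factor"]),
                    provenance=row.get("provenance", ""),
                )
            )
    return out


def packaged_factor_table() -> list[CurrencyFactor]:
    """The committed reconstruction of the normalization factor table."""
    ref = resources.files("limbcost.data").joinpath("currency_factors.csv")
    with resources.as_file(ref) as path:
        return load_factor_table(path)


def find_factor(
    table: list[CurrencyFactor], source: tuple[str, int], target: tuple[str, int]
) -> CurrencyFactor:
    """Look up a factor by endpoints, composing a two-step chain if needed."""
    for f in table:
        if f.source == source and f.target == target:
            return f
    for f in table:
        if f.source == source:
            for g in table:
                if g.source == f.target and g.target == target:
                    return compose_factors(f, g)
    raise KeyError(f"no factor chain from {source} to {target}")
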