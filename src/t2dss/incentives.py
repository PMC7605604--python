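"""LAP score aggregation and economic remuneration.

GPs joining the integrated-management program receive a base remuneration
of 50 EUR per enrolled patient.  On top of that, the overall LAP score —
the sum of the LAP points awarded for each indicator whose target was
reached or exceeded — maps, through a tiered schedule, to a further bonus
of 30, 40 or 50 EUR per patient per year.

The score-to-tier schedule is project configuration.  The default tiers
shipped here are synthetic (expressed as fractions of the maximum
attainable LAP score): >= 0.5 -> 30, >= 0.7 -> 40, >= 0.9 -> 50.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

from .indicators import IndicatorResult

__all__ = [
    "BASE_RATE_EUR",
    "LAP_TIER_RATES_EUR",
    "DEFAULT_TIERS",
    "IncentiveStatement",
    "lap_score",
    "tier_rate",
    "incentive_statement",
    "load_tiers",
]

#: Base remuneration, EUR per enrolled patient.
BASE_RATE_EUR = 50.0

#: Admissible LAP bonus rates, EUR per patient per year.
LAP_TIER_RATES_EUR = (0.0, 30.0, 40.0, 50.0)

#: Synthetic default tier schedule: (min fraction of max attainable LAP, rate).
DEFAULT_TIERS: tuple[tuple[float, float], ...] = ((0.5, 30.0), (0.7, 40.0), (0.9, 50.0))


@dataclass(frozen=True)
class IncentiveStatement:
    gp_id: str
    n_enrolled: int
    base_rate: float
    base_pay: float
    lap_score: float
    lap_tier_rate: float
    lap_pay: float
    total: float


def lap_score(results: list[IndicatorResult]) -> float:
    """Overall LAP score: sum of the points awarded across indicators."""
    return float(sum(r.lap_awarded for r in results))


def _check_tiers(tiers) -> list[tuple[float, float]]:
    tiers = sorted((float(f), float(r)) for f, r in tiers)
    rates = [r for _, r in tiers]
    if rates != sorted(rates):
        raise ValueError("tier table must be monotone: higher score fraction, higher rate")
    for _, r in tiers:
        if r not in LAP_TIER_RATES_EUR:
            raise ValueError(f"tier rate must be one of {LAP_TIER_RATES_EUR}, got {r}")
    return tiers


def tier_rate(score: float, max_score: float, tiers=DEFAULT_TIERS) -> float:
    """EUR/patient/year bonus rate for a LAP score out of ``max_score``."""
    tiers = _check_tiers(tiers)
    frac = 0.0 if max_score <= 0 else score / max_score
    rate = 0.0
    for threshold, r in tiers:
        if frac >= threshold:
            rate = r
    return rate


def incentive_statement(
    gp_id: str,
    n_enrolled: int,
    score: float,
    max_score: float,
    tiers=DEFAULT_TIERS,
    *,
    base_rate: float = BASE_RATE_EUR,
) -> IncentiveStatement:
    """Full remuneration statement for one GP."""
    if n_enrolled < 0:
        raise ValueError("n_enrolled must be >= 0")
    rate = tier_rate(score, max_score, tiers)
    base_pay = n_enrolled * base_rate
    lap_pay = n_enrolled * rate
    return IncentiveStatement(
        gp_id, int(n_enrolled), base_rate, base_pay, float(score), rate, lap_pay,
        base_pay + lap_pay,
    )


def load_tiers(path) -> tuple[tuple[float, float], ...]:
    """Load a tier schedule from YAML: list of ``{min_fraction, rate}``."""
    raw = yaml.safe_load(Path(path).read_text("utf-8"))
    return tuple((float(t["min_fraction"]), float(t["rate"])) for t in raw)
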