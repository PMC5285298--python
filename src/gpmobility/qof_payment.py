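"""Quality and Outcomes Framework (QOF) revenue engine.

The QOF rewards UK general practices on clinical indicators. For each
indicator a practice reports a numerator (eligible patients for whom the
quality measure was met) and a denominator (eligible patients); the resulting
achievement rate ``A = numerator/denominator`` maps to points through a
piecewise-linear ramp: nothing at or below the lower threshold, the indicator's
maximum points at or above the upper threshold, linear in between. Points
convert to money at a yearly price per point (£76 in 2004, £125 in 2005).

The module also constructs the exogenous price shock used to identify effort
responses: the counterfactual revenue change a practice would face if it
carried its 2005 achievement unchanged into 2006, when upper thresholds rose
on a subset of cardiovascular-disease (CVD) indicators.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Indicator",
    "IndicatorRegistry",
    "AchievementRecord",
    "PriceShock",
    "UndefinedAchievementError",
    "achievement_rate",
    "points_earned",
    "practice_revenue",
    "proportion_total_points",
    "price_shock",
    "default_registry",
    "CVD_SUBSET",
    "N_DEFAULT_INDICATORS",
    "registry_to_json",
    "registry_from_json",
    "records_to_csv",
    "records_from_csv",
]

PRICE_PER_POINT = {2004: 76.0, 2005: 125.0, 2006: 125.0, 2007: 125.0}
N_DEFAULT_INDICATORS = 146
#: ids of the four CVD-control indicators whose thresholds tighten in 2006
CVD_SUBSET = ("IND005", "IND041", "IND077", "IND113")


class UndefinedAchievementError(ValueError):
    """Achievement is undefined when an indicator has no eligible patients."""


@dataclass(frozen=True)
class Indicator:
    id: str
    disease_domain: str
    max_points: float
    lower_threshold: float
    upper_threshold: float

    def __post_init__(self) -> None:
        if self.max_points <= 0:
            raise ValueError("max_points must be > 0")
        if not (0.0 <= self.lower_threshold < self.upper_threshold <= 1.0):
            raise ValueError(
                f"require 0 <= lower < upper <= 1, got ({self.lower_threshold}, {self.upper_threshold})"
            )


@dataclass(frozen=True)
class IndicatorRegistry:
    """The payment scheme in force for one year."""

    year: int
    indicators: tuple[Indicator, ...]
    price_per_point: float
    _by_id: dict = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        if self.price_per_point <= 0:
            raise ValueError("price_per_point must be > 0")
        ids = [ind.id for ind in self.indicators]
        if len(set(ids)) != len(ids):
            raise ValueError("indicator ids must be unique within a year")
        object.__setattr__(self, "_by_id", {ind.id: ind for ind in self.indicators})

    def __len__(self) -> int:
        return len(self.indicators)

    def __getitem__(self, indicator_id: str) -> Indicator:
        try:
            return self._by_id[indicator_id]
        except KeyError:
            raise KeyError(f"indicator {indicator_id!r} not in the {self.year} registry") from None

    def __contains__(self, indicator_id: str) -> bool:
        return indicator_id in self._by_id

    @property
    def total_points(self) -> float:
        return float(sum(ind.max_points for ind in self.indicators))


@dataclass(frozen=True)
class AchievementRecord:
    """One practice's reported coverage on one indicator in one year."""

    practice_id: str
    year: int
    indicator_id: str
    numerator: int
    denominator: int

    def __post_init__(self) -> None:
        if self.numerator < 0 or self.denominator < 0:
            raise ValueError("counts must be >= 0")
        if self.numerator > self.denominator:
            raise ValueError("numerator cannot exceed denominator")


@dataclass(frozen=True)
class PriceShock:
    """Counterfactual revenue change from carrying old achievement into a new scheme.

    ``shock_money`` is negative when the new scheme pays less for unchanged
    performance; ``shock_pct_of_revenue`` expresses it as a percentage of the
    practice's total revenue under the old scheme (the empirical variable).
    """

    practice_id: str
    shock_money: float
    shock_pct_of_revenue: float
    indicator_subset: tuple[str, ...]


def achievement_rate(record: AchievementRecord) -> float:
    """Achievement ``A = numerator/denominator`` in [0, 1]."""
    if record.denominator == 0:
        raise UndefinedAchievementError(
            f"practice {record.practice_id}, indicator {record.indicator_id}: denominator is 0"
        )
    return record.numerator / record.denominator


def points_earned(achievement, indicator: Indicator):
    """Points for an achievement level under the indicator's linear ramp.

    Zero at or below the lower threshold, ``max_points`` at or above the upper
    threshold, linear in between; continuous in the achievement level. Accepts
    a scalar or an ndarray of achievement levels.
    """
    a = np.asarray(achievement, dtype=float)
    if np.any((a < 0.0) | (a > 1.0)):
        raise ValueError("achievement must lie in [0, 1]")
    lo, hi = indicator.lower_threshold, indicator.upper_threshold
    frac = np.clip((a - lo) / (hi - lo), 0.0, 1.0)
    pts = indicator.max_points * frac
    return float(pts) if np.isscalar(achievement) else pts


def practice_revenue(
    records: list[AchievementRecord],
    registry: IndicatorRegistry,
) -> tuple[float, dict[str, float]]:
    """Total QOF revenue and its per-indicator breakdown for one practice.

    Records with a zero denominator are excluded (their achievement is
    undefined and they can earn no points). The breakdown sums to the total
    exactly.
    """
    breakdown: dict[str, float] = {}
    for rec in records:
        ind = registry[rec.indicator_id]
        if rec.denominator == 0:
            continue
        breakdown[rec.indicator_id] = points_earned(achievement_rate(rec), ind) * registry.price_per_point
    return sum(breakdown.values()), breakdown


def proportion_total_points(
    records: list[AchievementRecord],
    registry: IndicatorRegistry,
) -> float:
    """Percent of available points achieved: 100 x sum(points) / sum(max_points).

    Indicators with a zero denominator are dropped from both numerator and
    denominator (undefined achievement cannot earn points).
    """
    if len(registry) == 0:
        raise ValueError("registry is empty")
    earned = 0.0
    available = 0.0
    for rec in records:
        ind = registry[rec.indicator_id]
        if rec.denominator == 0:
            continue
        earned += points_earned(achievement_rate(rec), ind)
        available += ind.max_points
    if available == 0.0:
        return 0.0
    return 100.0 * earned / available


def price_shock(
    records_2005: list[AchievementRecord],
    registry_2005: IndicatorRegistry,
    registry_2006: IndicatorRegistry,
    subset: tuple[str, ...] = CVD_SUBSET,
) -> PriceShock:
    """Exogenous price shock from the threshold changes on ``subset``.

    Revenue the practice would earn on the subset indicators if it carried its
    2005 achievement unchanged into the 2006 scheme, minus what the 2005 scheme
    actually paid on those indicators; expressed in money and as a percentage
    of the practice's total 2005 revenue. Zero when the two schemes agree on
    the subset.
    """
    for ind_id in subset:
        if ind_id not in registry_2005 or ind_id not in registry_2006:
            raise KeyError(f"subset indicator {ind_id!r} missing from a registry")
    if not records_2005:
        raise ValueError("no 2005 achievement records supplied")
    practice_id = records_2005[0].practice_id
    sub = [r for r in records_2005 if r.indicator_id in subset]
    rev_new, _ = practice_revenue(sub, registry_2006)
    rev_old, _ = practice_revenue(sub, registry_2005)
    total_2005, _ = practice_revenue(records_2005, registry_2005)
    shock = rev_new - rev_old
    pct = 100.0 * shock / total_2005 if total_2005 > 0 else 0.0
    return PriceShock(
        practice_id=practice_id,
        shock_money=shock,
        shock_pct_of_revenue=pct,
        indicator_subset=tuple(subset),
    )


# ---------------------------------------------------------------------------
# Default synthetic registries
# ---------------------------------------------------------------------------

def default_registry(year: int) -> IndicatorRegistry:
    """The 146-indicator synthetic scheme for one year.

    All indicators share the 0.40 lower threshold. Upper thresholds cycle
    deterministically through 0.70/0.75/0.85/0.90; maximum points cycle through
    3..12 so that the scheme totals roughly a thousand points. In 2006 the four
    CVD-control indicators (``CVD_SUBSET``) have their upper thresholds raised
    to 0.90 — the only change, making unchanged performance pay weakly less.
    """
    if year not in PRICE_PER_POINT:
        raise ValueError(f"no default registry for {year}")
    uppers = (0.70, 0.75, 0.85, 0.90)
    cvd_points = {"IND005": 10.0, "IND041": 12.0, "IND077": 17.0, "IND113": 17.0}
    indicators = []
    for k in range(N_DEFAULT_INDICATORS):
        ind_id = f"IND{k + 1:03d}"
        if ind_id in cvd_points:
            domain = "CVD-control"
            max_points = cvd_points[ind_id]
            upper = 0.90 if year >= 2006 else 0.70
        else:
            domain = f"domain{k % 10}"
            max_points = float(3 + k % 10)
            upper = uppers[k % 4]
        indicators.append(
            Indicator(
                id=ind_id,
                disease_domain=domain,
                max_points=max_points,
                lower_threshold=0.40,
                upper_threshold=upper,
            )
        )
    return IndicatorRegistry(
        year=year, indicators=tuple(indicators), price_per_point=PRICE_PER_POINT[year]
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def registry_to_json(registry: IndicatorRegistry, path: str | Path) -> None:
    payload = {
        "year": registry.year,
        "price_per_point": registry.price_per_point,
        "indicators": [
            {
                "id": ind.id,
                "disease_domain": ind.disease_domain,
                "max_points": ind.max_points,
                "lower_threshold": ind.lower_threshold,
                "upper_threshold": ind.upper_threshold,
            }
            for ind in registry.indicators
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def registry_from_json(path: str | Path) -> IndicatorRegistry:
    payload = json.loads(Path(path).read_text())
    return IndicatorRegistry(
        year=int(payload["year"]),
        indicators=tuple(Indicator(**ind) for ind in payload["indicators"]),
        price_per_point=float(payload["price_per_point"]),
    )


def records_to_csv(records: list[AchievementRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "practice_id": r.practice_id,
                "year": r.year,
                "indicator_id": r.indicator_id,
                "numerator": r.numerator,
                "denominator": r.denominator,
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def records_from_csv(path: str | Path) -> list[AchievementRecord]:
    df = pd.read_csv(path)
    return [
        AchievementRecord(
            practice_id=str(row.practice_id),
            year=int(row.year),
            indicator_id=str(row.indicator_id),
            numerator=int(row.numerator),
            denominator=int(row.denominator),
        )
        for row in df.itertuples()
    ]
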