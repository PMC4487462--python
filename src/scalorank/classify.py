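"""Five-tier development classification of composite scores.

The class interval comes from the Sturges rule, i = R / (1 + 3.3·log10 N),
where R is the score-range amplitude and N the number of items classified.
Five contiguous tiers are laid from the range minimum upward in steps of one
interval; each tier is half-open [low, next_low) except the top, which is
closed at the range maximum and therefore absorbs any remainder when five
widths fall short of R.

The interval width is rounded to the reporting precision (default one
decimal) *before* the bounds are accumulated, so the printed bounds are
exact multiples of the printed width — the convention that makes published
five-tier tables internally consistent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scoring import AggregateScores

#: Development tiers from worst to best.
TIER_LABELS = (
    "under_development",
    "less_development",
    "moderate_development",
    "semi_development",
    "development",
)


@dataclass(frozen=True)
class SturgesParams:
    """Inputs and result of the Sturges class-interval rule."""

    R: float  # range amplitude, score units
    N: int  # number of items classified
    width: float  # R / (1 + 3.3 log10 N)


@dataclass
class ClassScheme:
    """Five ordered development tiers with numeric interval bounds."""

    lower_bounds: list[float]  # ascending; lowest = score_min
    score_min: float
    score_max: float
    labels: tuple[str, ...] = TIER_LABELS
    params: SturgesParams | None = None
    decimals: int = 1

    def __post_init__(self) -> None:
        if len(self.lower_bounds) != len(self.labels):
            raise ValueError("one lower bound per tier label required")
        bounds = list(self.lower_bounds)
        if any(b >= c for b, c in zip(bounds, bounds[1:])):
            raise ValueError("lower bounds must be strictly increasing")
        if bounds[-1] >= self.score_max:
            raise ValueError("top tier lower bound must be below score_max")

    @property
    def n_classes(self) -> int:
        return len(self.labels)

    def interval(self, tier_index: int) -> tuple[float, float]:
        """Exact [low, high) bounds of a tier (top tier closed at score_max)."""
        low = self.lower_bounds[tier_index]
        if tier_index == self.n_classes - 1:
            return low, self.score_max
        return low, self.lower_bounds[tier_index + 1]

    def interval_display(self, tier_index: int) -> str:
        """Render an interval in the conventional "(upper-lower)" table style.

        Non-top tiers print their upper end one reporting unit below the next
        tier's lower bound (e.g. 53.9 below 54), making printed intervals
        visibly disjoint even though the stored bounds are exactly half-open.
        """
        low, high = self.interval(tier_index)
        if tier_index < self.n_classes - 1:
            high = round(high - 10 ** (-self.decimals), self.decimals)
        return f"({high:g}-{low:g})"


@dataclass
class ClassifiedRegion:
    region: str
    total_score: float
    tier: str
    rank: int  # 1 = highest total; ties share the smaller rank


def sturges_width(R: float, N: int) -> float:
    """Class-interval width i = R / (1 + 3.3·log10 N)."""
    if not R > 0:
        raise ValueError("R must be > 0")
    if int(N) < 2:
        raise ValueError("N must be >= 2")
    return float(R) / (1.0 + 3.3 * math.log10(int(N)))


def build_class_scheme(
    score_min: float,
    score_max: float,
    N: int,
    n_classes: int = 5,
    decimals: int = 1,
) -> ClassScheme:
    """Construct the tiered scheme for scores in [score_min, score_max].

    The Sturges width for R = score_max − score_min is rounded to
    ``decimals`` and lower bounds are score_min + k·width for k = 0..4. The
    top tier is closed at score_max, absorbing any remainder.
    """
    if not score_max > score_min:
        raise ValueError("score_max must exceed score_min")
    if n_classes != len(TIER_LABELS):
        raise ValueError(f"n_classes must be {len(TIER_LABELS)} (one per tier label)")
    R = float(score_max) - float(score_min)
    raw = sturges_width(R, N)
    width = round(raw, decimals)
    if width <= 0:
        raise ValueError(
            f"interval width rounds to {width} at {decimals} decimals; "
            "increase decimals"
        )
    bounds = [round(score_min + k * width, decimals) for k in range(n_classes)]
    if any(b >= c for b, c in zip(bounds, bounds[1:])) or bounds[-1] >= score_max:
        raise ValueError(
            "rounded bounds are not strictly increasing below score_max; "
            "increase decimals"
        )
    return ClassScheme(
        lower_bounds=bounds,
        score_min=float(score_min),
        score_max=float(score_max),
        params=SturgesParams(R=R, N=int(N), width=raw),
        decimals=decimals,
    )


def assign_class(total_score: float, scheme: ClassScheme) -> str:
    """Tier label of the unique interval containing ``total_score``."""
    s = float(total_score)
    if s < scheme.lower_bounds[0] or s > scheme.score_max:
        raise ValueError(
            f"score {s} outside scheme range "
            f"[{scheme.lower_bounds[0]}, {scheme.score_max}]"
        )
    idx = int(np.searchsorted(scheme.lower_bounds, s, side="right")) - 1
    return scheme.labels[idx]


def rank_regions(totals: pd.Series, scheme: ClassScheme) -> list[ClassifiedRegion]:
    """Classify and rank all regions, highest composite first.

    Ties use competition ranking (1, 2, 2, 4).
    """
    if totals.empty:
        raise ValueError("at least one region required")
    ranks = totals.rank(method="min", ascending=False).astype(int)
    order = totals.sort_values(ascending=False, kind="mergesort")
    return [
        ClassifiedRegion(
            region=str(r),
            total_score=float(order[r]),
            tier=assign_class(order[r], scheme),
            rank=int(ranks[r]),
        )
        for r in order.index
    ]


def tier_summary(classified: list[ClassifiedRegion], scheme: ClassScheme) -> pd.DataFrame:
    """Per-tier membership, count and percentage (2 decimals), best tier first."""
    n = len(classified)
    rows = []
    for idx in range(scheme.n_classes - 1, -1, -1):
        label = scheme.labels[idx]
        members = [c.region for c in classified if c.tier == label]
        rows.append(
            {
                "tier": label,
                "members": ", ".join(members),
                "count": len(members),
                "percent": round(100.0 * len(members) / n, 2),
                "interval": scheme.interval_display(idx),
            }
        )
    return pd.DataFrame(rows)


def rank_and_summarize(
    aggregates: AggregateScores, scheme: ClassScheme
) -> tuple[list[ClassifiedRegion], pd.DataFrame]:
    """Rank every region and summarize tier occupancy."""
    classified = rank_regions(aggregates.total, scheme)
    return classified, tier_summary(classified, scheme)
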