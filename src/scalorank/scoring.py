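"""Ordinal 1–4 scoring of indicator rates and per-cluster aggregation.

Each indicator column is scored independently: the observed rates are cut
into four classes and each region receives a score from 1 (worst observed
condition) to 4 (best). Scores are summed per cluster and overall, so a
study with n indicators yields composite totals bounded by [n, 4n] — e.g.
30 indicators give the familiar 30–120 band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CLUSTERS, IndicatorMatrix, IndicatorSpec, SchemaError

BINNINGS = ("equal_width", "quartile")


@dataclass
class ScoreMatrix:
    """Region × indicator grid of ordinal scores in {1, 2, 3, 4}."""

    scores: pd.DataFrame
    schema: list[IndicatorSpec] = field(default_factory=list)
    binning: str = "equal_width"

    def __post_init__(self) -> None:
        vals = self.scores.to_numpy()
        if not np.isin(vals, (1, 2, 3, 4)).all():
            raise ValueError("every score must be in {1, 2, 3, 4}")

    @property
    def regions(self) -> list[str]:
        return list(self.scores.index)


@dataclass
class AggregateScores:
    """Per-region cluster sums and composite total, with theoretical bounds."""

    cluster_scores: pd.DataFrame  # regions × clusters (integer sums)
    total: pd.Series  # region -> integer composite
    bounds: tuple[int, int]  # (n_indicators, 4 * n_indicators)

    def __post_init__(self) -> None:
        lo, hi = self.bounds
        if ((self.total < lo) | (self.total > hi)).any():
            raise ValueError("composite total outside theoretical bounds")
        if not (self.cluster_scores.sum(axis=1) == self.total).all():
            raise ValueError("cluster sums do not add up to the composite total")


def theoretical_bounds(n_indicators: int) -> tuple[int, int]:
    """Smallest and largest composite total for ``n_indicators`` indicators.

    Every indicator contributes a score in {1, …, 4}, so the total lies in
    [n, 4n]; 30 indicators give (30, 120).
    """
    n = int(n_indicators)
    if n < 1:
        raise ValueError("n_indicators must be >= 1")
    return n, 4 * n


def score_indicator(
    values,
    orientation: str = "higher_is_better",
    binning: str = "equal_width",
) -> np.ndarray:
    """Score one indicator's per-region rates on the ordinal 1–4 scale.

    equal_width (default): the observed [min, max] range is split into four
    equal sub-intervals, half-open [low, high) with the top bin closed, and
    a value in the k-th bin from the low end scores k.

    quartile: empirical quartile classes — values ≤ Q1 score 1, ≤ median 2,
    ≤ Q3 score 3, else 4.

    For ``higher_is_worse`` indicators the scale is reflected (s → 5 − s).
    A constant column cannot discriminate between regions; every region
    scores 4 and a warning is emitted.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise ValueError("values must be a nonempty 1-D array")
    if not np.isfinite(v).all():
        raise ValueError("values must all be finite")
    if binning not in BINNINGS:
        raise ValueError(f"binning must be one of {BINNINGS}")

    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        warnings.warn(
            "constant indicator column does not discriminate; scoring all "
            "regions 4",
            stacklevel=2,
        )
        return np.full(v.shape, 4, dtype=int)

    if binning == "equal_width":
        edges = lo + (hi - lo) * np.array([0.25, 0.5, 0.75])
        score = 1 + (v >= edges[0]).astype(int) + (v >= edges[1]) + (v >= edges[2])
    else:
        q1, q2, q3 = np.percentile(v, [25, 50, 75])
        score = 1 + (v > q1).astype(int) + (v > q2) + (v > q3)

    if orientation == "higher_is_worse":
        score = 5 - score
    elif orientation != "higher_is_better":
        raise ValueError(f"unknown orientation {orientation!r}")
    return score.astype(int)


def score_matrix(matrix: IndicatorMatrix, binning: str = "equal_width") -> ScoreMatrix:
    """Apply :func:`score_indicator` to every indicator column independently."""
    cols = {}
    for spec in matrix.schema:
        cols[spec.id] = score_indicator(
            matrix.values[spec.id].to_numpy(), spec.orientation, binning
        )
    scores = pd.DataFrame(cols, index=matrix.values.index)[matrix.indicator_ids]
    return ScoreMatrix(scores=scores, schema=list(matrix.schema), binning=binning)


def aggregate(scores: ScoreMatrix) -> AggregateScores:
    """Sum scores per cluster and in total for each region."""
    by_cluster: dict[str, list[str]] = {}
    for spec in scores.schema:
        if spec.cluster not in CLUSTERS:
            raise SchemaError(f"indicator {spec.id!r} has unknown cluster {spec.cluster!r}")
        by_cluster.setdefault(spec.cluster, []).append(spec.id)
    cluster_scores = pd.DataFrame(
        {c: scores.scores[ids].sum(axis=1) for c, ids in by_cluster.items()},
        index=scores.scores.index,
    )
    total = scores.scores.sum(axis=1).astype(int)
    return AggregateScores(
        cluster_scores=cluster_scores.astype(int),
        total=total.rename("total_score"),
        bounds=theoretical_bounds(scores.scores.shape[1]),
    )
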