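"""Report and map outputs: ranked tables, tier summaries, GeoJSON choropleth.

`run_pipeline` drives the whole analysis on a validated matrix; the writers
emit deterministic delimited-text and JSON artifacts so a run is fully
reproducible from its inputs and recorded metadata.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Union

import pandas as pd

from .classify import (
    ClassifiedRegion,
    ClassScheme,
    build_class_scheme,
    rank_and_summarize,
)
from .io import IndicatorMatrix
from .scoring import AggregateScores, aggregate, score_matrix

logger = logging.getLogger(__name__)


@dataclass
class ReportBundle:
    """Everything a run produces: ranked table, tier summary, metadata."""

    ranked: pd.DataFrame  # region, cluster scores, total, tier, rank
    tiers: pd.DataFrame  # tier, members, count, percent, interval
    scheme: ClassScheme
    classified: list[ClassifiedRegion]
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if int(self.tiers["count"].sum()) != len(self.ranked):
            raise ValueError("tier counts must sum to the number of regions")


def run_pipeline(
    matrix: IndicatorMatrix,
    binning: str = "equal_width",
    sturges_n: int | None = None,
    range_min: float | None = None,
    range_max: float | None = None,
    decimals: int = 1,
    metadata: dict[str, Any] | None = None,
) -> ReportBundle:
    """Score, aggregate, classify and rank a validated indicator matrix.

    By default the Sturges item count N is the number of regions and the
    class range spans the observed composite totals; both are overridable to
    pin a published scheme.
    """
    scores = score_matrix(matrix, binning=binning)
    aggregates = aggregate(scores)
    lo = float(aggregates.total.min()) if range_min is None else float(range_min)
    hi = float(aggregates.total.max()) if range_max is None else float(range_max)
    N = len(matrix.regions) if sturges_n is None else int(sturges_n)
    scheme = build_class_scheme(lo, hi, N, decimals=decimals)
    classified, tiers = rank_and_summarize(aggregates, scheme)

    ranked = aggregates.cluster_scores.copy()
    ranked.insert(0, "region", ranked.index)
    ranked.index.name = None  # region lives in the column from here on
    ranked["total_score"] = aggregates.total
    by_region = {c.region: c for c in classified}
    ranked["tier"] = [by_region[r].tier for r in ranked.index]
    ranked["rank"] = [by_region[r].rank for r in ranked.index]
    ranked = ranked.sort_values(
        ["rank", "region"], kind="mergesort"
    ).reset_index(drop=True)

    meta = {
        "binning": binning,
        "n_regions": len(matrix.regions),
        "n_indicators": len(matrix.indicator_ids),
        "score_bounds": list(aggregates.bounds),
        "sturges": {
            "R": scheme.params.R,
            "N": scheme.params.N,
            "width": scheme.params.width,
            "width_rounded": round(scheme.params.width, decimals),
        },
        "class_lower_bounds": scheme.lower_bounds,
        "range": [lo, hi],
    }
    meta.update(metadata or {})
    return ReportBundle(
        ranked=ranked,
        tiers=tiers,
        scheme=scheme,
        classified=classified,
        metadata=meta,
    )


def file_digest(path: Union[str, Path]) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_report(bundle: ReportBundle, out_dir: Union[str, Path]) -> dict[str, Path]:
    """Write ranked.csv, tier_summary.csv and run.json under ``out_dir``.

    Output is deterministic: fixed column order, percentages to 2 decimals,
    no timestamps.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "ranked": out / "ranked.csv",
        "tiers": out / "tier_summary.csv",
        "run": out / "run.json",
    }
    bundle.ranked.to_csv(paths["ranked"], index=False)
    bundle.tiers.to_csv(paths["tiers"], index=False)
    paths["run"].write_text(
        json.dumps(bundle.metadata, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    logger.info("report written to %s", out)
    return paths


def read_ranked(path: Union[str, Path]) -> pd.DataFrame:
    """Re-read a ranked.csv written by :func:`write_report`."""
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# choropleth export


def _norm_name(name: str) -> str:
    return str(name).strip().casefold()


def write_choropleth(
    bundle: ReportBundle,
    geometries: Union[dict, str, Path],
    out_path: Union[str, Path] | None = None,
) -> dict:
    """Tag a GeoJSON FeatureCollection with scores, tiers and ranks.

    Features join to regions by their ``name`` (or ``region``) property,
    exact after whitespace trimming and case folding. Features with no
    matching region are kept but tiered ``not_assessed``; regions with no
    geometry are dropped from the file and listed in the returned
    collection's ``properties.regions_without_geometry``.
    """
    if not isinstance(geometries, dict):
        geometries = json.loads(Path(geometries).read_text(encoding="utf-8"))
    if geometries.get("type") != "FeatureCollection" or "features" not in geometries:
        raise ValueError("geometries must be a GeoJSON FeatureCollection")

    cluster_cols = [
        c
        for c in bundle.ranked.columns
        if c not in ("region", "total_score", "tier", "rank")
    ]
    by_region = {
        _norm_name(row.region): row for row in bundle.ranked.itertuples()
    }
    matched = set()
    features = []
    for feat in geometries["features"]:
        props = dict(feat.get("properties") or {})
        raw = props.get("name", props.get("region"))
        key = _norm_name(raw) if raw is not None else None
        row = by_region.get(key)
        if row is None:
            props["tier"] = "not_assessed"
        else:
            matched.add(key)
            props["total_score"] = float(row.total_score)
            props["tier"] = row.tier
            props["rank"] = int(row.rank)
            for c in cluster_cols:
                props[f"score_{c}"] = int(getattr(row, c))
        features.append({**feat, "properties": props})

    missing = sorted(
        str(r) for r in bundle.ranked["region"] if _norm_name(r) not in matched
    )
    if missing:
        logger.warning("regions without geometry: %s", ", ".join(missing))
    out = {
        "type": "FeatureCollection",
        "properties": {"regions_without_geometry": missing},
        "features": features,
    }
    if out_path is not None:
        Path(out_path).write_text(
            json.dumps(out, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
    return out
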