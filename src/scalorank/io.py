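"""Reading, validation and normalization of region × indicator tables.

The central container is :class:`IndicatorMatrix`: an ordered grid of
nonnegative per-capita rates (one row per region, one column per indicator),
paired with an indicator schema that records each indicator's cluster
(institutional / human_resource / rural_institutional), its original
denominator (persons per rate unit, e.g. 1000 or 10000) and its orientation
(whether a higher rate is better). After validation all rates are expressed
per 1,000 persons.
"""

from __future__ import annotations

import io as _io
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Sequence, Union

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

CLUSTERS = ("institutional", "human_resource", "rural_institutional")
ORIENTATIONS = ("higher_is_better", "higher_is_worse")

#: Denominator every stored rate is expressed against after validation.
STANDARD_DENOMINATOR = 1000.0

PathOrBuffer = Union[str, Path, IO[str]]


class SchemaError(ValueError):
    """The indicator schema is malformed or inconsistent with the table."""


class ValidationError(ValueError):
    """A table cell, region name or population value fails validation."""


@dataclass(frozen=True)
class IndicatorSpec:
    """One indicator: identity, cluster membership, units and direction."""

    id: str
    label: str = ""
    cluster: str = "institutional"
    denominator: float = STANDARD_DENOMINATOR
    orientation: str = "higher_is_better"

    def __post_init__(self) -> None:
        if not self.id or not str(self.id).strip():
            raise SchemaError("indicator id must be a nonempty string")
        if self.cluster not in CLUSTERS:
            raise SchemaError(
                f"indicator {self.id!r}: cluster {self.cluster!r} is not one of {CLUSTERS}"
            )
        if not self.denominator > 0:
            raise SchemaError(f"indicator {self.id!r}: denominator must be > 0")
        if self.orientation not in ORIENTATIONS:
            raise SchemaError(
                f"indicator {self.id!r}: orientation {self.orientation!r} "
                f"is not one of {ORIENTATIONS}"
            )
        if not self.label:
            object.__setattr__(self, "label", self.id)


@dataclass
class IndicatorMatrix:
    """Region × indicator grid of validated per-1,000 rates.

    ``values`` is a DataFrame indexed by region name with one column per
    indicator id, in schema order. Every cell is finite and ≥ 0.
    """

    values: pd.DataFrame
    schema: list[IndicatorSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.schema]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise SchemaError(f"duplicate indicator id(s): {dup}")
        if list(self.values.columns) != ids:
            raise SchemaError("value columns do not match schema indicator order")
        regions = list(self.values.index)
        if any((not isinstance(r, str)) or not r.strip() for r in regions):
            raise ValidationError("region names must be nonempty strings")
        if len(set(regions)) != len(regions):
            dup = sorted({r for r in regions if regions.count(r) > 1})
            raise ValidationError(f"duplicate region name(s): {dup}")
        self.values = self.values.rename_axis("region")
        self._check_cells()

    def _check_cells(self) -> None:
        vals = self.values.to_numpy(dtype=float)
        import numpy as np

        bad = ~np.isfinite(vals) | (vals < 0)
        if bad.any():
            r, c = map(int, next(zip(*bad.nonzero())))
            raise ValidationError(
                f"invalid cell at region {self.values.index[r]!r}, "
                f"indicator {self.values.columns[c]!r}: value must be finite and >= 0"
            )

    @property
    def regions(self) -> list[str]:
        return list(self.values.index)

    @property
    def indicator_ids(self) -> list[str]:
        return list(self.values.columns)

    def spec(self, indicator_id: str) -> IndicatorSpec:
        for s in self.schema:
            if s.id == indicator_id:
                return s
        raise KeyError(indicator_id)

    @property
    def clusters(self) -> dict[str, list[str]]:
        """Indicator ids grouped by cluster, in schema order."""
        out: dict[str, list[str]] = {c: [] for c in CLUSTERS}
        for s in self.schema:
            out[s.cluster].append(s.id)
        return out


# ---------------------------------------------------------------------------
# schema handling


def read_schema(source: PathOrBuffer) -> list[IndicatorSpec]:
    """Load an indicator schema from a YAML (or JSON) config.

    The document is either a list of indicator entries or a mapping with an
    ``indicators`` key holding that list. Each entry needs ``id`` and
    ``cluster``; ``label``, ``denominator`` (default 1000) and
    ``orientation`` (default higher_is_better) are optional.
    """
    if hasattr(source, "read"):
        doc = yaml.safe_load(source.read())
    else:
        doc = yaml.safe_load(Path(source).read_text(encoding="utf-8"))
    if isinstance(doc, dict):
        doc = doc.get("indicators")
    if not isinstance(doc, list) or not doc:
        raise SchemaError("schema must contain a nonempty list of indicators")
    specs = []
    for entry in doc:
        if not isinstance(entry, dict) or "id" not in entry:
            raise SchemaError(f"malformed schema entry: {entry!r}")
        specs.append(
            IndicatorSpec(
                id=str(entry["id"]),
                label=str(entry.get("label", "") or ""),
                cluster=str(entry.get("cluster", "institutional")),
                denominator=float(entry.get("denominator", STANDARD_DENOMINATOR)),
                orientation=str(entry.get("orientation", "higher_is_better")),
            )
        )
    ids = [s.id for s in specs]
    if len(set(ids)) != len(ids):
        raise SchemaError("duplicate indicator ids in schema")
    return specs


def write_schema(schema: Sequence[IndicatorSpec], path: Union[str, Path]) -> None:
    doc = {
        "indicators": [
            {
                "id": s.id,
                "label": s.label,
                "cluster": s.cluster,
                "denominator": s.denominator,
                "orientation": s.orientation,
            }
            for s in schema
        ]
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")


# ---------------------------------------------------------------------------
# table reading / writing


def _sniff_sep(first_line: str) -> str:
    return "\t" if "\t" in first_line else ","


def read_indicator_table(
    table_source: PathOrBuffer,
    schema: Union[PathOrBuffer, Sequence[IndicatorSpec]],
    *,
    strict: bool = True,
) -> IndicatorMatrix:
    """Read a delimited region × indicator table against a schema.

    The table is UTF-8 comma- or tab-separated (auto-detected from the
    header) with a first ``region`` column and one column per schema
    indicator id. Rates declared per a denominator other than 1,000 are
    rescaled to per-1,000 on read.

    In strict mode (default) a missing or non-numeric cell is an error; with
    ``strict=False`` missing cells are imputed with the indicator's observed
    minimum — the conservative worst-observed-condition reading — and a
    warning is emitted.
    """
    if isinstance(schema, (str, Path)) or hasattr(schema, "read"):
        specs = read_schema(schema)  # type: ignore[arg-type]
    else:
        specs = list(schema)

    if hasattr(table_source, "read"):
        text = table_source.read()
    else:
        text = Path(table_source).read_text(encoding="utf-8")
    sep = _sniff_sep(text.splitlines()[0] if text else "")
    df = pd.read_csv(_io.StringIO(text), sep=sep, dtype={0: str})

    first = df.columns[0]
    if first.strip().lower() != "region":
        raise SchemaError(
            f"first column must be 'region', found {first!r}"
        )
    df = df.rename(columns={first: "region"})
    df["region"] = df["region"].astype(str).str.strip()

    want = [s.id for s in specs]
    extra = [c for c in df.columns[1:] if c not in want]
    if extra:
        raise SchemaError(f"table column(s) not in schema: {extra}")
    missing_cols = [c for c in want if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"schema indicator(s) missing from table: {missing_cols}")

    regions = df["region"].tolist()
    if any(not r for r in regions):
        raise ValidationError("empty region name in table")
    if len(set(regions)) != len(regions):
        dup = sorted({r for r in regions if regions.count(r) > 1})
        raise ValidationError(f"duplicate region name(s): {dup}")

    values = df.set_index("region")[want].apply(pd.to_numeric, errors="coerce")
    na = values.isna()
    if na.to_numpy().any():
        if strict:
            r = na.any(axis=1).idxmax()
            c = na.loc[r].idxmax()
            raise ValidationError(
                f"missing or non-numeric cell at region {r!r}, indicator {c!r}"
            )
        for c in values.columns[na.any(axis=0)]:
            fill = values[c].min()
            warnings.warn(
                f"imputing {int(na[c].sum())} missing cell(s) in indicator "
                f"{c!r} with the observed minimum {fill}",
                stacklevel=2,
            )
            values[c] = values[c].fillna(fill)

    # rescale everything to the common per-1,000 denominator
    for s in specs:
        if s.denominator != STANDARD_DENOMINATOR:
            values[s.id] = values[s.id] * (STANDARD_DENOMINATOR / s.denominator)
    normalized = [
        IndicatorSpec(s.id, s.label, s.cluster, STANDARD_DENOMINATOR, s.orientation)
        for s in specs
    ]
    return IndicatorMatrix(values=values.astype(float), schema=normalized)


def write_indicator_table(matrix: IndicatorMatrix, path: Union[str, Path]) -> None:
    """Write the per-1,000 rate grid as CSV, full float precision."""
    matrix.values.to_csv(path, float_format=None)


def normalize_counts(
    counts: pd.DataFrame,
    population: pd.Series,
    schema: Sequence[IndicatorSpec] | None = None,
) -> IndicatorMatrix:
    """Convert raw facility/staff counts to rates per 1,000 population.

    ``counts`` is region × indicator; ``population`` gives persons per
    region.  value(r, j) = count(r, j) × 1000 / population(r).
    """
    pop = population.reindex(counts.index)
    bad = pop.isna() | (pop <= 0)
    if bad.any():
        raise ValidationError(
            f"population must be > 0 for every region; offending region(s): "
            f"{list(pop.index[bad])}"
        )
    values = counts.astype(float).mul(STANDARD_DENOMINATOR, axis=0).div(pop, axis=0)
    if schema is None:
        schema = [IndicatorSpec(id=str(c)) for c in counts.columns]
    return IndicatorMatrix(values=values, schema=list(schema))


# ---------------------------------------------------------------------------
# packaged Fars province fixture (indicator labels, clusters, province totals)


def load_fars_schema(with_totals: bool = False):
    """The packaged 31-indicator Fars-province schema.

    Eight institutional, twenty human-resource and three rural-institutional
    indicators, with each indicator's published province-wide total. Returns
    the schema list, or ``(schema, totals)`` where totals is a Series keyed
    by indicator id.
    """
    with resources.files("scalorank.data").joinpath("fars_indicators.csv").open(
        "r", encoding="utf-8"
    ) as fh:
        df = pd.read_csv(fh)
    schema = [
        IndicatorSpec(
            id=row.id,
            label=row.label,
            cluster=row.cluster,
            denominator=float(row.denominator),
            orientation=row.orientation,
        )
        for row in df.itertuples()
    ]
    if with_totals:
        return schema, df.set_index("id")["province_total"].astype(float)
    return schema
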