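"""Data model, validation, I/O, and packaged reference tables for adoption surveys.

A survey dataset holds one row per respondent: demographic attributes drawn
from a declared schema, an optional positive sampling weight, and, for each
service, three binary stage indicators — aware / want / adopt — the three
hierarchical stages of the innovation-adoption funnel.  Aggregation turns
respondent rows into per-segment stage counts and rates, the shape in which
the packaged reference tables (a 2012 nationwide Taiwanese telephone survey
of two eHealth services, n = 3074) are shipped.

Respondent CSV layout::

    respondent_id,weight,<attr1>,...,<attrK>,<svc>_aware,<svc>_want,<svc>_adopt

Segment CSV layout::

    service,variable,item_id,label,n,aware_count,want_count,adopt_count,
    aware_rate,want_rate,adopt_rate

Count cells may be empty ("rate-only" rows): absent counts are ``None``,
never zero.  "Don't know/no answer" and "Other" are ordinary category
labels, analyzed as segments in their own right — they are not missing data.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import pandas as pd
import yaml

from .errors import SchemaError, UnknownNameError, ValidationError

STAGES = ("aware", "want", "adopt")

#: item_id used for the whole-sample row of an aggregated table
TOTAL_ID = "T"

_FIXTURE_TABLES = ("sample_profile", "dms", "dhcs")


# ---------------------------------------------------------------------------
# schema
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AttributeSchema:
    """Ordered attributes with their ordered category labels.

    ``prefixes`` maps attribute name -> one/two-letter item-id prefix used
    when rendering aggregated tables (e.g. geographic_area -> "L", so its
    categories become L1..L6).
    """

    attributes: tuple[tuple[str, tuple[str, ...]], ...]
    prefixes: Mapping[str, str] = field(default_factory=dict)
    services: tuple[str, ...] = ()

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.attributes)

    def categories(self, name: str) -> tuple[str, ...]:
        for attr, cats in self.attributes:
            if attr == name:
                return cats
        raise UnknownNameError(f"unknown attribute {name!r}")

    def prefix(self, name: str) -> str:
        pre = dict(self.prefixes).get(name)
        if pre:
            return pre
        return name[0].upper()

    def item_id(self, name: str, label: str) -> str:
        return f"{self.prefix(name)}{self.categories(name).index(label) + 1}"

    def to_mapping(self) -> dict:
        prefixes = dict(self.prefixes)
        return {
            "attributes": [
                {"name": name, "categories": list(cats)}
                | ({"prefix": prefixes[name]} if name in prefixes else {})
                for name, cats in self.attributes
            ],
            "services": list(self.services),
        }

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_mapping(), fh, sort_keys=False)

    @classmethod
    def from_mapping(cls, data: Mapping) -> "AttributeSchema":
        attrs = tuple(
            (a["name"], tuple(str(c) for c in a["categories"]))
            for a in data["attributes"]
        )
        prefixes = {a["name"]: a["prefix"] for a in data["attributes"] if "prefix" in a}
        return cls(attrs, prefixes, tuple(data.get("services", ())))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AttributeSchema":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_mapping(yaml.safe_load(fh))


def default_schema() -> AttributeSchema:
    """Schema of the packaged reference survey (9 attributes, 2 services)."""
    with resources.files("awag.fixtures").joinpath("schema.yaml").open(
        "r", encoding="utf-8"
    ) as fh:
        return AttributeSchema.from_mapping(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# respondent-level model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StageTriple:
    """Binary indicators for the three funnel stages of one respondent."""

    aware: int
    want: int
    adopt: int

    def __post_init__(self) -> None:
        for name in STAGES:
            v = getattr(self, name)
            if v not in (0, 1):
                raise ValidationError(f"stage {name!r} must be 0 or 1, got {v!r}")


@dataclass(frozen=True)
class RespondentRecord:
    respondent_id: str
    attributes: Mapping[str, str]
    stages: Mapping[str, StageTriple]
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not self.weight > 0:
            raise ValidationError(
                f"respondent {self.respondent_id}: weight must be > 0"
            )


@dataclass
class SurveyDataset:
    """Respondent-level survey stored columnar.

    ``frame`` columns: respondent_id, weight, one column per schema
    attribute, and ``<service>_aware/_want/_adopt`` per service.
    """

    frame: pd.DataFrame
    schema: AttributeSchema
    services: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.frame)

    def validate(self) -> "SurveyDataset":
        cols = set(self.frame.columns)
        for required in ("respondent_id", "weight"):
            if required not in cols:
                raise SchemaError(f"missing required column {required!r}")
        for name in self.schema.names:
            if name not in cols:
                raise SchemaError(f"missing attribute column {name!r}")
            allowed = set(self.schema.categories(name))
            bad = ~self.frame[name].isin(allowed)
            if bad.any():
                row = int(bad.idxmax())
                raise ValidationError(
                    f"row {row}: {name}={self.frame[name].iloc[row]!r} "
                    f"not in declared categories"
                )
        for svc in self.services:
            for stage in STAGES:
                col = f"{svc}_{stage}"
                if col not in cols:
                    raise SchemaError(f"missing stage column {col!r}")
                vals = self.frame[col]
                bad = ~vals.isin((0, 1))
                if bad.any():
                    row = int(bad.idxmax())
                    raise ValidationError(
                        f"row {row}: stage column {col!r} has non-binary "
                        f"value {vals.iloc[row]!r}"
                    )
        if not (self.frame["weight"] > 0).all():
            row = int((~(self.frame["weight"] > 0)).idxmax())
            raise ValidationError(f"row {row}: weight must be > 0")
        return self

    # -- access -----------------------------------------------------------

    def stage_frame(self, service: str) -> pd.DataFrame:
        """The three stage columns of one service, renamed aware/want/adopt."""
        if service not in self.services:
            raise UnknownNameError(f"unknown service {service!r}")
        cols = {f"{service}_{s}": s for s in STAGES}
        return self.frame[list(cols)].rename(columns=cols)

    def subset(self, variable: str, label: str) -> "SurveyDataset":
        if variable not in self.schema.names:
            raise UnknownNameError(f"unknown variable {variable!r}")
        mask = self.frame[variable] == label
        return SurveyDataset(
            self.frame[mask].reset_index(drop=True), self.schema, self.services
        )

    @property
    def records(self) -> Iterator[RespondentRecord]:
        for _, row in self.frame.iterrows():
            yield RespondentRecord(
                respondent_id=str(row["respondent_id"]),
                attributes={n: row[n] for n in self.schema.names},
                weight=float(row["weight"]),
                stages={
                    svc: StageTriple(
                        *(int(row[f"{svc}_{s}"]) for s in STAGES)
                    )
                    for svc in self.services
                },
            )


# ---------------------------------------------------------------------------
# aggregated model
# ---------------------------------------------------------------------------

@dataclass
class SegmentSummary:
    """Stage counts and rates for one segment of one service.

    Rates are stored as proportions in [0, 1]; percentages appear only at
    I/O boundaries.  Counts may be absent (``None``) in rate-only rows —
    then the stored rates are authoritative (e.g. transcribed printed
    rates), not recomputable.  ``printed_gap_pct`` / ``printed_region_code``
    carry the reference tables' own annotations for cross-checking.
    """

    service: str
    variable: str
    item_id: str
    label: str
    n: int
    aware_count: int | None = None
    want_count: int | None = None
    adopt_count: int | None = None
    aware_rate: float | None = None
    want_rate: float | None = None
    adopt_rate: float | None = None
    printed_gap_pct: float | None = None
    printed_region_code: str | None = None

    def __post_init__(self) -> None:
        for stage in STAGES:
            count = getattr(self, f"{stage}_count")
            rate = getattr(self, f"{stage}_rate")
            if count is not None:
                if not (0 <= count <= self.n):
                    raise ValidationError(
                        f"{self.service}/{self.item_id}: {stage}_count {count} "
                        f"outside [0, n={self.n}]"
                    )
                if rate is None and self.n > 0:
                    setattr(self, f"{stage}_rate", count / self.n)
            if rate is not None and not (0.0 <= rate <= 1.0):
                raise ValidationError(
                    f"{self.service}/{self.item_id}: {stage}_rate {rate} "
                    f"outside [0, 1]"
                )

    @property
    def has_counts(self) -> bool:
        return all(
            getattr(self, f"{s}_count") is not None for s in STAGES
        )

    def count_rate_deviation_pp(self) -> float | None:
        """Max |count/n − stored rate| over the stages, in percentage points.

        Nonzero deviations beyond printing precision occur in the packaged
        reference tables (up to ~0.7 pp on the smallest segments),
        consistent with an undisclosed weighting in the source analysis;
        the stored rates are authoritative.
        """
        if not self.has_counts or self.n == 0:
            return None
        return max(
            abs(getattr(self, f"{s}_count") / self.n - getattr(self, f"{s}_rate"))
            * 100.0
            for s in STAGES
        )


@dataclass(frozen=True)
class ProfileRow:
    """One row of the sample-composition profile (counts and % of sample)."""

    variable: str
    item_id: str
    label: str
    n: int
    pct: float


# ---------------------------------------------------------------------------
# respondent I/O
# ---------------------------------------------------------------------------

def _infer_services(columns: Sequence[str]) -> tuple[str, ...]:
    services = []
    for col in columns:
        if col.endswith("_aware"):
            services.append(col[: -len("_aware")])
    for svc in services:
        for stage in STAGES:
            if f"{svc}_{stage}" not in columns:
                raise SchemaError(
                    f"service {svc!r}: missing stage column {svc}_{stage}"
                )
    return tuple(services)


def read_respondents(path: str | Path, schema: AttributeSchema) -> SurveyDataset:
    """Read and validate a respondent-level CSV against ``schema``.

    The header must declare ``respondent_id``, one column per schema
    attribute, and a complete aware/want/adopt column triple per service;
    ``weight`` is optional and defaults to 1.
    """
    frame = pd.read_csv(path, dtype={"respondent_id": str})
    if "respondent_id" not in frame.columns:
        raise SchemaError("missing required column 'respondent_id'")
    if "weight" not in frame.columns:
        frame["weight"] = 1.0
    services = _infer_services(list(frame.columns))
    dataset = SurveyDataset(frame, schema, services)
    return dataset.validate()


def write_respondents(dataset: SurveyDataset, path: str | Path) -> None:
    cols = (
        ["respondent_id", "weight"]
        + list(dataset.schema.names)
        + [f"{svc}_{s}" for svc in dataset.services for s in STAGES]
    )
    dataset.frame[cols].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def _summary_from_block(
    block: pd.DataFrame,
    service: str,
    variable: str,
    item_id: str,
    label: str,
    weighted: bool,
) -> SegmentSummary:
    n = len(block)
    counts = {s: int(block[f"{service}_{s}"].sum()) for s in STAGES}
    if weighted:
        wsum = float(block["weight"].sum())
        rates = {
            s: float((block[f"{service}_{s}"] * block["weight"]).sum()) / wsum
            if wsum > 0
            else None
            for s in STAGES
        }
    else:
        rates = {s: counts[s] / n if n > 0 else None for s in STAGES}
    return SegmentSummary(
        service=service,
        variable=variable,
        item_id=item_id,
        label=label,
        n=n,
        **{f"{s}_count": counts[s] for s in STAGES},
        **{f"{s}_rate": rates[s] for s in STAGES},
    )


def aggregate_segments(
    data: SurveyDataset,
    service: str,
    variable: str,
    weighted: bool = False,
) -> list[SegmentSummary]:
    """Per-category stage counts/rates for one variable, plus a Total row.

    Unweighted mode (default, matching the reference analysis contract)
    reports ``count / n``.  Weighted mode keeps raw counts and n but uses
    weight sums as pseudo-counts for the rates.
    """
    if service not in data.services:
        raise UnknownNameError(f"unknown service {service!r}")
    if variable not in data.schema.names:
        raise UnknownNameError(f"unknown variable {variable!r}")
    out = [
        _summary_from_block(data.frame, service, "total", TOTAL_ID, "Total", weighted)
    ]
    for label in data.schema.categories(variable):
        block = data.frame[data.frame[variable] == label]
        out.append(
            _summary_from_block(
                block,
                service,
                variable,
                data.schema.item_id(variable, label),
                label,
                weighted,
            )
        )
    return out


# ---------------------------------------------------------------------------
# segment CSV I/O
# ---------------------------------------------------------------------------

_SEGMENT_COLUMNS = [
    "service", "variable", "item_id", "label", "n",
    "aware_count", "want_count", "adopt_count",
    "aware_rate", "want_rate", "adopt_rate",
]


def write_segments(summaries: Sequence[SegmentSummary], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=_SEGMENT_COLUMNS)
        writer.writeheader()
        for s in summaries:
            writer.writerow(
                {
                    "service": s.service, "variable": s.variable,
                    "item_id": s.item_id, "label": s.label, "n": s.n,
                    **{
                        f"{st}_count": ("" if getattr(s, f"{st}_count") is None
                                        else getattr(s, f"{st}_count"))
                        for st in STAGES
                    },
                    **{
                        f"{st}_rate": ("" if getattr(s, f"{st}_rate") is None
                                       else repr(getattr(s, f"{st}_rate")))
                        for st in STAGES
                    },
                }
            )


def read_segments(path: str | Path) -> list[SegmentSummary]:
    """Read a segment CSV; empty count cells become ``None`` (rate-only)."""
    out = []
    with open(path, "r", newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out.append(
                SegmentSummary(
                    service=row["service"], variable=row["variable"],
                    item_id=row["item_id"], label=row["label"], n=int(row["n"]),
                    **{
                        f"{st}_count": (int(row[f"{st}_count"])
                                        if row.get(f"{st}_count") else None)
                        for st in STAGES
                    },
                    **{
                        f"{st}_rate": (float(row[f"{st}_rate"])
                                       if row.get(f"{st}_rate") else None)
                        for st in STAGES
                    },
                )
            )
    return out


# ---------------------------------------------------------------------------
# packaged reference tables
# ---------------------------------------------------------------------------

def load_fixture(table: str) -> list[SegmentSummary] | list[ProfileRow]:
    """Load a packaged reference table.

    ``"dms"`` / ``"dhcs"`` return 45 :class:`SegmentSummary` rows each (the
    established digital medical service and the newly introduced digital
    home care service), carrying both the printed stage counts and the
    printed rates, plus the printed adoption-gap-ratio percentage and
    matrix region code as expected-value annotations.  The stored rates are
    the printed ones (authoritative), not ``count/n``.

    ``"sample_profile"`` returns :class:`ProfileRow` entries: the sample's
    demographic composition.
    """
    if table not in _FIXTURE_TABLES:
        raise UnknownNameError(
            f"unknown fixture {table!r}; expected one of {_FIXTURE_TABLES}"
        )
    path = resources.files("awag.fixtures").joinpath(f"{table}.csv")
    with path.open("r", encoding="utf-8") as fh:
        rows = list(csv.DictReader(fh))
    if table == "sample_profile":
        return [
            ProfileRow(
                variable=r["variable"], item_id=r["item_id"], label=r["label"],
                n=int(r["n"]), pct=float(r["pct"]),
            )
            for r in rows
        ]
    return [
        SegmentSummary(
            service=r["service"], variable=r["variable"], item_id=r["item_id"],
            label=r["label"], n=int(r["n"]),
            aware_count=int(r["aware_count"]),
            want_count=int(r["want_count"]),
            adopt_count=int(r["adopt_count"]),
            aware_rate=float(r["aware_pct"]) / 100.0,
            want_rate=float(r["want_pct"]) / 100.0,
            adopt_rate=float(r["adopt_pct"]) / 100.0,
            printed_gap_pct=float(r["gap_pct"]),
            printed_region_code=r["region_code"],
        )
        for r in rows
    ]
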