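"""The AWAG segment matrix: bands, regions, gap ratio, and prescriptions.

A segment is positioned in the unit square by its (awareness, want) rate
pair.  The 50% midpoint splits each axis into low/high, yielding four
categories:

* **opened** — high awareness, high want: open to the innovation;
* **desire-deficiency** — high awareness, low want: informed but uninterested;
* **perception-deficiency** — low awareness, high want: interested but
  under-informed (the priority promotion target);
* **closed** — low on both.

Within each category, the technology-adoption-lifecycle cumulative cut
points 15% and 85% refine the axes into four bands (B0 = [0, .15),
B1 = [.15, .50), B2 = [.50, .85), B3 = [.85, 1]; a cut value belongs to the
upper band), giving subcategories strong / awareness-bias / want-bias /
generic and a compact region code such as ``O_Wb``.  Each region carries a
marketing prescription (hold / improve / evaluate / leave) and an
improvement direction (whether awareness and/or want still has head-room).

The **adoption gap ratio** g measures, among those already convertible, the
share not yet converted to adoption.  Two variants are implemented:

* ``want_based`` (default): g = (want − adopt) / want — this is the
  arithmetic that reproduces the reference tables' printed gap column;
* ``min_based``: g = (min(aware, want) − adopt) / min(aware, want) — the
  narrative definition "0% when adoption equals the minimum of awareness
  and want"; it provably disagrees with the printed values whenever
  awareness < want (the DHCS rows), a documented source inconsistency.

Negative raw gaps clamp to 0 with a flag; g is always in [0, 1].
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from ._utils import format_pct
from .errors import InvalidRegionError, UndefinedGapError
from .survey_data import SegmentSummary


# ---------------------------------------------------------------------------
# bands
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassificationBands:
    """Three strictly increasing cut points splitting [0, 1] into four bands."""

    cuts: tuple[float, float, float] = (0.15, 0.50, 0.85)

    def __post_init__(self) -> None:
        lo, mid, hi = self.cuts
        if not (0.0 < lo < mid < hi < 1.0):
            raise ValueError(
                f"cuts must be strictly increasing within (0, 1), got {self.cuts}"
            )


DEFAULT_BANDS = ClassificationBands()


def assign_band(rate: float, bands: ClassificationBands = DEFAULT_BANDS) -> int:
    """Band index 0..3 for a rate; cut values belong to the upper band."""
    if not (0.0 <= rate <= 1.0):
        raise ValueError(f"rate must be in [0, 1], got {rate}")
    band = 0
    for cut in bands.cuts:
        if rate >= cut:
            band += 1
    return band


# ---------------------------------------------------------------------------
# regions
# ---------------------------------------------------------------------------

class Category(enum.Enum):
    OPENED = "O"
    DESIRE_DEFICIENCY = "D"
    PERCEPTION_DEFICIENCY = "P"
    CLOSED = "C"


class Subcategory(enum.Enum):
    STRONG = "S"
    AWARENESS_BIAS = "Ab"
    WANT_BIAS = "Wb"
    GENERIC = "G"


#: the 14 valid (category, subcategory) pairs; desire-deficiency has no
#: awareness-bias cell and perception-deficiency no want-bias cell (their
#: two off-diagonal band cells collapse into the named bias subcategory).
VALID_REGIONS: tuple[tuple[Category, Subcategory], ...] = tuple(
    (cat, sub)
    for cat in Category
    for sub in Subcategory
    if not (cat is Category.DESIRE_DEFICIENCY and sub is Subcategory.AWARENESS_BIAS)
    and not (cat is Category.PERCEPTION_DEFICIENCY and sub is Subcategory.WANT_BIAS)
)


@dataclass(frozen=True)
class AwagRegion:
    """A cell of the segment matrix, optionally carrying its band pair."""

    category: Category
    subcategory: Subcategory
    aware_band: int | None = None
    want_band: int | None = None

    def __post_init__(self) -> None:
        if (self.category, self.subcategory) not in VALID_REGIONS:
            raise InvalidRegionError(
                f"invalid region {self.category.name}/{self.subcategory.name}"
            )

    @property
    def code(self) -> str:
        return f"{self.category.value}_{self.subcategory.value}"

    @classmethod
    def from_code(cls, code: str) -> "AwagRegion":
        try:
            cat_code, sub_code = code.split("_")
            category = Category(cat_code)
            subcategory = Subcategory(sub_code)
        except ValueError as exc:
            raise InvalidRegionError(f"malformed region code {code!r}") from exc
        return cls(category, subcategory)


# subcategory lookup per category, keyed by (aware_band, want_band)
_OPENED = {
    (3, 3): Subcategory.STRONG,
    (3, 2): Subcategory.WANT_BIAS,
    (2, 3): Subcategory.AWARENESS_BIAS,
    (2, 2): Subcategory.GENERIC,
}
_CLOSED = {
    (0, 0): Subcategory.STRONG,
    (0, 1): Subcategory.AWARENESS_BIAS,
    (1, 0): Subcategory.WANT_BIAS,
    (1, 1): Subcategory.GENERIC,
}
_DESIRE = {
    (3, 0): Subcategory.STRONG,
    (2, 1): Subcategory.GENERIC,
    (3, 1): Subcategory.WANT_BIAS,
    (2, 0): Subcategory.WANT_BIAS,
}
_PERCEPTION = {
    (0, 3): Subcategory.STRONG,
    (1, 2): Subcategory.GENERIC,
    (1, 3): Subcategory.AWARENESS_BIAS,
    (0, 2): Subcategory.AWARENESS_BIAS,
}


def classify_region(
    aware_rate: float,
    want_rate: float,
    bands: ClassificationBands = DEFAULT_BANDS,
) -> AwagRegion:
    """Classify a segment by its (awareness, want) rate pair.

    The midpoint cut decides the category; the band pair within the
    quadrant decides the subcategory ("strong" sits at the quadrant's
    extreme corner, "generic" at its least extreme cell).
    """
    a_band = assign_band(aware_rate, bands)
    w_band = assign_band(want_rate, bands)
    high_a, high_w = a_band >= 2, w_band >= 2
    if high_a and high_w:
        category, table = Category.OPENED, _OPENED
    elif high_a:
        category, table = Category.DESIRE_DEFICIENCY, _DESIRE
    elif high_w:
        category, table = Category.PERCEPTION_DEFICIENCY, _PERCEPTION
    else:
        category, table = Category.CLOSED, _CLOSED
    return AwagRegion(category, table[(a_band, w_band)], a_band, w_band)


# ---------------------------------------------------------------------------
# adoption gap ratio
# ---------------------------------------------------------------------------

GAP_VARIANTS = ("want_based", "min_based")


@dataclass(frozen=True)
class GapRatio:
    value: float
    variant: str
    clamped: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.value <= 1.0):
            raise ValueError(f"gap ratio {self.value} outside [0, 1]")

    @property
    def pct(self) -> float:
        """Percentage rendering, half-up to one decimal."""
        return format_pct(self.value)


def gap_ratio(
    aware_rate: float,
    want_rate: float,
    adopt_rate: float,
    variant: str = "want_based",
) -> GapRatio:
    """Share of the reference rate not yet converted to adoption."""
    if variant not in GAP_VARIANTS:
        raise ValueError(f"unknown gap variant {variant!r}")
    for name, rate in (
        ("aware", aware_rate), ("want", want_rate), ("adopt", adopt_rate)
    ):
        if not (0.0 <= rate <= 1.0):
            raise ValueError(f"{name}_rate must be in [0, 1], got {rate}")
    reference = want_rate if variant == "want_based" else min(aware_rate, want_rate)
    if reference == 0:
        raise UndefinedGapError(
            f"gap ratio undefined: reference rate is 0 ({variant})"
        )
    raw = (reference - adopt_rate) / reference
    if raw < 0:
        return GapRatio(0.0, variant, clamped=True)
    return GapRatio(raw, variant)


# ---------------------------------------------------------------------------
# prescriptions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Prescription:
    strategy: str
    action: str
    market_tier: str  # primary | secondary | tertiary | potential | nontarget


_EVAL = "Evaluate the potential of the segment then choose an action between "

PRESCRIPTIONS: dict[tuple[Category, Subcategory], Prescription] = {
    (Category.OPENED, Subcategory.STRONG): Prescription(
        "Hold", "Keep up the good work.", "primary"),
    (Category.OPENED, Subcategory.AWARENESS_BIAS): Prescription(
        "Hold and improve (raise)",
        "Keep up the good work and keep raising the awareness.", "secondary"),
    (Category.OPENED, Subcategory.WANT_BIAS): Prescription(
        "Hold and improve (raise)",
        "Keep up the good work and keep raising the want.", "tertiary"),
    (Category.OPENED, Subcategory.GENERIC): Prescription(
        "Hold and improve (raise)",
        "Keep up the good work and keep raising the awareness and want.",
        "tertiary"),
    (Category.CLOSED, Subcategory.STRONG): Prescription(
        "Evaluate then leave or evaluate then improve (spread and create)",
        _EVAL + "“maintain status quo” and “keep spreading the "
        "awareness or creating the want.”", "nontarget"),
    (Category.CLOSED, Subcategory.AWARENESS_BIAS): Prescription(
        "Evaluate then leave or evaluate then improve (spread)",
        _EVAL + "“maintain status quo” and “keep spreading the "
        "awareness.”", "nontarget"),
    (Category.CLOSED, Subcategory.WANT_BIAS): Prescription(
        "Evaluate then leave or evaluate then improve (create)",
        _EVAL + "“maintain status quo” and “keep creating the "
        "want.”", "nontarget"),
    (Category.CLOSED, Subcategory.GENERIC): Prescription(
        "Evaluate then leave or evaluate then improve (raise)",
        _EVAL + "“maintain status quo” and “keep raising the "
        "awareness or want.”", "nontarget"),
    (Category.DESIRE_DEFICIENCY, Subcategory.STRONG): Prescription(
        "Evaluate then leave or evaluate then improve (create)",
        _EVAL + "“maintain status quo” and “keep creating the "
        "want.”", "nontarget"),
    (Category.DESIRE_DEFICIENCY, Subcategory.WANT_BIAS): Prescription(
        "Evaluate then leave or evaluate then improve (create)",
        _EVAL + "“maintain status quo” and “keep creating the "
        "want.”", "nontarget"),
    (Category.DESIRE_DEFICIENCY, Subcategory.GENERIC): Prescription(
        "Improve (create)", "Keep creating the want.", "nontarget"),
    (Category.PERCEPTION_DEFICIENCY, Subcategory.STRONG): Prescription(
        "Improve (spread)", "Keep spreading the awareness.", "potential"),
    (Category.PERCEPTION_DEFICIENCY, Subcategory.AWARENESS_BIAS): Prescription(
        "Improve (spread)", "Keep spreading the awareness.", "potential"),
    (Category.PERCEPTION_DEFICIENCY, Subcategory.GENERIC): Prescription(
        "Improve (spread)", "Keep spreading the awareness.", "potential"),
}


def prescribe(region: AwagRegion) -> Prescription:
    """The strategy/action/target-market row for a matrix region."""
    return PRESCRIPTIONS[(region.category, region.subcategory)]


# ---------------------------------------------------------------------------
# improvement direction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImprovementDirection:
    """Whether a segment should still be pulled up in awareness and/or want."""

    raise_awareness: bool
    raise_want: bool


# representative band pairs for regions constructed from a bare code; the
# two collapsed cells (D_Wb, P_Ab) conservatively flag both directions
_CODE_BANDS: dict[str, tuple[int | None, int | None]] = {
    "O_S": (3, 3), "O_Ab": (2, 3), "O_Wb": (3, 2), "O_G": (2, 2),
    "C_S": (0, 0), "C_Ab": (0, 1), "C_Wb": (1, 0), "C_G": (1, 1),
    "D_S": (3, 0), "D_Wb": (None, 1), "D_G": (2, 1),
    "P_S": (0, 3), "P_Ab": (1, None), "P_G": (1, 2),
}


def improvement_direction(region: AwagRegion) -> ImprovementDirection:
    """Head-room rule: raise a dimension iff its band is below the top band.

    Only the strong-opened cell has no head-room on either axis; movement
    is always toward the high-awareness/high-want corner, step by step.
    """
    a_band, w_band = region.aware_band, region.want_band
    if a_band is None or w_band is None:
        a_band, w_band = _CODE_BANDS[region.code]
    return ImprovementDirection(
        raise_awareness=(a_band is None or a_band < 3),
        raise_want=(w_band is None or w_band < 3),
    )


# ---------------------------------------------------------------------------
# table annotation
# ---------------------------------------------------------------------------

def classify_table(
    summaries: Sequence[SegmentSummary],
    bands: ClassificationBands = DEFAULT_BANDS,
    variant: str = "want_based",
) -> pd.DataFrame:
    """Annotate segment summaries with region, gap ratio, and prescription.

    Uses each summary's stored rates (exact ``count/n`` for aggregated
    data; authoritative printed rates for the packaged tables).  Per-row
    gap-ratio failures (zero reference rate, missing rates) are recorded in
    the ``note`` column without aborting the table.
    """
    rows = []
    for s in summaries:
        row: dict = {
            "service": s.service, "variable": s.variable,
            "item_id": s.item_id, "label": s.label, "n": s.n,
            "aware_rate": s.aware_rate, "want_rate": s.want_rate,
            "adopt_rate": s.adopt_rate,
            "region_code": None, "gap_ratio_pct": None, "gap_variant": variant,
            "strategy": None, "action": None, "market_tier": None,
            "raise_awareness": None, "raise_want": None, "note": "",
        }
        notes = []
        if s.aware_rate is None or s.want_rate is None:
            notes.append("missing rates; row left unclassified")
        else:
            region = classify_region(s.aware_rate, s.want_rate, bands)
            rx = prescribe(region)
            direction = improvement_direction(region)
            row.update(
                region_code=region.code, strategy=rx.strategy, action=rx.action,
                market_tier=rx.market_tier,
                raise_awareness=direction.raise_awareness,
                raise_want=direction.raise_want,
            )
            if s.adopt_rate is None:
                notes.append("missing adoption rate; gap ratio skipped")
            else:
                try:
                    g = gap_ratio(s.aware_rate, s.want_rate, s.adopt_rate, variant)
                except UndefinedGapError as exc:
                    notes.append(str(exc))
                else:
                    row["gap_ratio_pct"] = g.pct
                    if g.clamped:
                        notes.append("negative raw gap clamped to 0")
        row["note"] = "; ".join(notes)
        rows.append(row)
    columns = [
        "service", "variable", "item_id", "label", "n",
        "aware_rate", "want_rate", "adopt_rate",
        "region_code", "gap_ratio_pct", "gap_variant",
        "strategy", "action", "market_tier",
        "raise_awareness", "raise_want", "note",
    ]
    return pd.DataFrame(rows, columns=columns)
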