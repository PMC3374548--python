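"""Marginal and conditional stage-rate estimation.

The funnel stages are interrelated: want is typically created by awareness
and adoption requires want, so besides the marginal awareness/want/adoption
rates, the divide analysis compares conditional rates — e.g. the want rate
among the aware versus among the unaware.  Every estimate carries its
numerator and denominator; a conditional whose conditioning event never
occurs is explicitly *undefined* (never silently 0), since small segments
make empty cells reachable in practice.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import DegenerateInputError
from .survey_data import STAGES, SegmentSummary, SurveyDataset, TOTAL_ID


@dataclass(frozen=True)
class RateEstimate:
    """A proportion with its exact counts and conditioning event."""

    numerator: int
    denominator: int
    condition: str = "marginal"

    def __post_init__(self) -> None:
        if self.numerator < 0 or self.denominator < 0:
            raise ValueError("counts must be nonnegative")
        if self.numerator > self.denominator:
            raise ValueError("numerator exceeds denominator")

    @property
    def defined(self) -> bool:
        return self.denominator > 0

    @property
    def rate(self) -> float | None:
        return self.numerator / self.denominator if self.defined else None


@dataclass(frozen=True)
class ConditionalRateSet:
    """The six conditional estimates used by the divide comparisons.

    Complementary pairs (e.g. want|aware and want|unaware) have
    denominators summing to the subset size.
    """

    want_given_aware: RateEstimate
    want_given_unaware: RateEstimate
    adopt_given_want: RateEstimate
    adopt_given_not_want: RateEstimate
    aware_given_want: RateEstimate
    aware_given_not_want: RateEstimate


def _stage_frame(data: SurveyDataset | pd.DataFrame, service: str) -> pd.DataFrame:
    if isinstance(data, SurveyDataset):
        return data.stage_frame(service)
    cols = {f"{service}_{s}": s for s in STAGES}
    if set(cols).issubset(data.columns):
        return data[list(cols)].rename(columns=cols)
    return data[list(STAGES)]


def marginal_rates(
    data: SurveyDataset | pd.DataFrame,
    service: str,
    variable: str = "total",
    item_id: str = TOTAL_ID,
    label: str = "Total",
) -> SegmentSummary:
    """Stage counts and rates over a (sub)set of respondents."""
    frame = _stage_frame(data, service)
    n = len(frame)
    if n == 0:
        raise DegenerateInputError("cannot estimate rates on an empty subset")
    counts = {s: int(frame[s].sum()) for s in STAGES}
    return SegmentSummary(
        service=service, variable=variable, item_id=item_id, label=label, n=n,
        **{f"{s}_count": counts[s] for s in STAGES},
    )


def conditional_rates(
    data: SurveyDataset | pd.DataFrame, service: str
) -> ConditionalRateSet:
    """All six conditional stage rates over a (sub)set of respondents."""
    frame = _stage_frame(data, service)
    if len(frame) == 0:
        raise DegenerateInputError("cannot estimate rates on an empty subset")

    def cond(target: str, given: str, value: int) -> RateEstimate:
        sub = frame[frame[given] == value]
        event = "" if value else "no "
        return RateEstimate(
            numerator=int(sub[target].sum()),
            denominator=len(sub),
            condition=f"{target} | {event}{given}",
        )

    return ConditionalRateSet(
        want_given_aware=cond("want", "aware", 1),
        want_given_unaware=cond("want", "aware", 0),
        adopt_given_want=cond("adopt", "want", 1),
        adopt_given_not_want=cond("adopt", "want", 0),
        aware_given_want=cond("aware", "want", 1),
        aware_given_not_want=cond("aware", "want", 0),
    )
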