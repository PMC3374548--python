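"""The nine-hypothesis digital-divide testing battery.

Three families of hypotheses are tested for a service over any set of
segmentation variables:

* **H1–H3** (divide across segments): a chi-square test of independence on
  the segments × (stage yes/no) contingency table, one per stage —
  awareness, want, adoption.
* **H4–H6** (within-respondent stage comparisons): a paired-proportion
  (McNemar) test on the 2×2 of two stage indicators within respondents.
  H4/H5 assert adoption trails awareness/want; H6 asks which of awareness
  and want leads — for an established service awareness usually leads,
  while for a newly introduced service want can exceed awareness
  (consumer pull ahead of technology push).
* **H7–H9** (conditional comparisons): an independent two-proportion
  z-test of a target stage rate between respondents with and without a
  conditioning stage — want|aware vs want|unaware, adopt|want vs
  adopt|no-want, aware|want vs aware|no-want.

All verdicts are reported at a configurable alpha (default .05); no
multiple-testing correction is applied by default, with optional
Benjamini–Hochberg q-values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.contingency_tables import mcnemar
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

from .survey_data import (
    STAGES,
    SegmentSummary,
    SurveyDataset,
    TOTAL_ID,
    aggregate_segments,
)
from .errors import UnsupportedInputError
from .rate_estimation import _stage_frame

#: switch from the exact binomial to the continuity-corrected chi-square
#: McNemar test at this many discordant pairs
EXACT_DISCORDANT_THRESHOLD = 25

DEFAULT_ALPHA = 0.05


@dataclass
class TestResult:
    """Outcome of one hypothesis test."""

    hypothesis_id: str
    test_name: str
    statistic: float | None
    df: int | None
    p_value: float | None
    direction: str  # greater | less | none
    significant: bool
    alpha: float = DEFAULT_ALPHA
    verdict: str = ""
    note: str = ""
    skipped: bool = False
    min_expected: float | None = None
    q_value: float | None = None

    def to_dict(self) -> dict:
        return {
            "hypothesis_id": self.hypothesis_id,
            "test": self.test_name,
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "direction": self.direction,
            "significant": self.significant,
            "alpha": self.alpha,
            "verdict": self.verdict,
            "note": self.note,
            "skipped": self.skipped,
            "q_value": self.q_value,
        }


# ---------------------------------------------------------------------------
# H1-H3: divide across segments
# ---------------------------------------------------------------------------

def divide_test(
    summaries: Sequence[SegmentSummary],
    stage: str,
    alpha: float = DEFAULT_ALPHA,
    correction: bool = False,
    hypothesis_id: str | None = None,
) -> TestResult:
    """Chi-square independence test of one stage across segments.

    The Total row is excluded; remaining segments form a k×2 table of
    (stage yes, stage no) counts.  ``correction`` applies the Yates
    continuity correction (only meaningful for 2×2; default off).
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    segs = [s for s in summaries if s.item_id != TOTAL_ID and s.n > 0]
    if len(segs) < 2:
        raise UnsupportedInputError("need at least two non-empty segments")
    for s in segs:
        if getattr(s, f"{stage}_count") is None:
            raise UnsupportedInputError(
                f"segment {s.item_id}: rate-only row has no {stage} count; "
                "the divide test requires counts"
            )
    table = np.array(
        [
            [getattr(s, f"{stage}_count"), s.n - getattr(s, f"{stage}_count")]
            for s in segs
        ]
    )
    res = stats.chi2_contingency(table, correction=correction)
    min_expected = float(res.expected_freq.min())
    note = ""
    if min_expected < 5:
        note = f"minimum expected cell count {min_expected:.2f} < 5"
    p = float(res.pvalue)
    return TestResult(
        hypothesis_id=hypothesis_id or f"divide[{segs[0].variable}:{stage}]",
        test_name="chi_square_independence",
        statistic=float(res.statistic),
        df=int(res.dof),
        p_value=p,
        direction="none",
        significant=p < alpha,
        alpha=alpha,
        note=note,
        min_expected=min_expected,
    )


# ---------------------------------------------------------------------------
# H4-H6: paired stage comparison
# ---------------------------------------------------------------------------

def paired_stage_test(
    data: SurveyDataset | pd.DataFrame,
    service: str,
    stage_a: str,
    stage_b: str,
    alpha: float = DEFAULT_ALPHA,
    hypothesis_id: str | None = None,
) -> TestResult:
    """McNemar test of two stage indicators within respondents.

    Uses the exact binomial test on the discordant pairs when they number
    fewer than ``EXACT_DISCORDANT_THRESHOLD``, otherwise the
    continuity-corrected chi-square.  ``direction`` reports which stage's
    marginal rate is higher ("greater" = stage_a's).
    """
    frame = _stage_frame(data, service)
    a = frame[stage_a].to_numpy()
    b = frame[stage_b].to_numpy()
    n10 = int(((a == 1) & (b == 0)).sum())
    n01 = int(((a == 0) & (b == 1)).sum())
    hid = hypothesis_id or f"paired[{stage_a} vs {stage_b}]"
    if n10 + n01 == 0:
        return TestResult(
            hypothesis_id=hid, test_name="paired_proportion",
            statistic=0.0, df=None, p_value=1.0, direction="none",
            significant=False, alpha=alpha,
            note="no discordant pairs",
        )
    exact = (n10 + n01) < EXACT_DISCORDANT_THRESHOLD
    n11 = int(((a == 1) & (b == 1)).sum())
    n00 = int(((a == 0) & (b == 0)).sum())
    res = mcnemar([[n11, n10], [n01, n00]], exact=exact, correction=True)
    if n10 > n01:
        direction = "greater"
    elif n10 < n01:
        direction = "less"
    else:
        direction = "none"
    p = float(res.pvalue)
    return TestResult(
        hypothesis_id=hid, test_name="paired_proportion",
        statistic=float(res.statistic),
        df=None if exact else 1,
        p_value=p,
        direction=direction,
        significant=p < alpha,
        alpha=alpha,
        note="exact binomial on discordant pairs" if exact
        else "continuity-corrected chi-square",
    )


# ---------------------------------------------------------------------------
# H7-H9: conditional comparison
# ---------------------------------------------------------------------------

def conditional_test(
    data: SurveyDataset | pd.DataFrame,
    service: str,
    target_stage: str,
    conditioning_stage: str,
    alpha: float = DEFAULT_ALPHA,
    hypothesis_id: str | None = None,
) -> TestResult:
    """Two-proportion z-test of a target rate with vs without a stage.

    ``direction`` = "greater" when the target rate is higher given the
    conditioning stage.  An empty conditioning arm yields a skipped result
    with the reason recorded, never a silent 0/0.
    """
    frame = _stage_frame(data, service)
    hid = hypothesis_id or f"conditional[{target_stage} | {conditioning_stage}]"
    arm1 = frame[frame[conditioning_stage] == 1]
    arm0 = frame[frame[conditioning_stage] == 0]
    if len(arm1) == 0 or len(arm0) == 0:
        empty = conditioning_stage if len(arm1) == 0 else f"no-{conditioning_stage}"
        return TestResult(
            hypothesis_id=hid, test_name="independent_two_proportion",
            statistic=None, df=None, p_value=None, direction="none",
            significant=False, alpha=alpha, skipped=True,
            verdict="skipped",
            note=f"conditional undefined: empty {empty} arm",
        )
    x1, n1 = int(arm1[target_stage].sum()), len(arm1)
    x0, n0 = int(arm0[target_stage].sum()), len(arm0)
    pooled = (x1 + x0) / (n1 + n0)
    if pooled in (0.0, 1.0):
        # degenerate pooled proportion: z undefined, rates identical
        stat, p = 0.0, 1.0
    else:
        stat, p = proportions_ztest([x1, x0], [n1, n0])
        stat, p = float(stat), float(p)
    r1, r0 = x1 / n1, x0 / n0
    direction = "greater" if r1 > r0 else ("less" if r1 < r0 else "none")
    return TestResult(
        hypothesis_id=hid, test_name="independent_two_proportion",
        statistic=stat, df=None, p_value=p,
        direction=direction, significant=p < alpha, alpha=alpha,
    )


# ---------------------------------------------------------------------------
# battery
# ---------------------------------------------------------------------------

#: expected direction per pairwise/conditional hypothesis family
_H_EXPECT = {
    "H4": "less",      # adoption < awareness
    "H5": "less",      # adoption < want
    "H7": "greater",   # want|aware > want|unaware
    "H8": "greater",   # adopt|want > adopt|no-want
    "H9": "greater",   # aware|want > aware|no-want
}


@dataclass
class BatteryReport:
    """Structured outcome of a full H1–H9 run for one service."""

    service: str
    alpha: float
    results: list[TestResult] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_dict() for r in self.results])

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(
            {
                "service": self.service,
                "alpha": self.alpha,
                "results": [r.to_dict() for r in self.results],
            },
            indent=indent,
        )

    def to_text(self) -> str:
        lines = [
            f"Hypothesis battery — service {self.service!r}, "
            f"alpha {self.alpha:g}",
            "",
        ]
        for r in self.results:
            stat = "NA" if r.statistic is None else f"{r.statistic:.3f}"
            p = "NA" if r.p_value is None else f"{r.p_value:.4g}"
            lines.append(
                f"{r.hypothesis_id:34s} {r.test_name:28s} "
                f"stat={stat:>9s} p={p:>9s} dir={r.direction:7s} "
                f"{r.verdict}{'  [' + r.note + ']' if r.note else ''}"
            )
        return "\n".join(lines)

    def supported(self, prefix: str) -> list[TestResult]:
        return [
            r
            for r in self.results
            if r.hypothesis_id.startswith(prefix) and r.verdict == "supported"
        ]

    def result(self, hypothesis_id: str) -> TestResult:
        for r in self.results:
            if r.hypothesis_id == hypothesis_id:
                return r
        raise KeyError(hypothesis_id)


def _verdict_divide(r: TestResult) -> str:
    return "supported" if r.significant else "not supported"


def _verdict_directional(r: TestResult, expected: str) -> str:
    if r.skipped:
        return "skipped"
    return (
        "supported"
        if r.significant and r.direction == expected
        else "not supported"
    )


def run_battery(
    data: SurveyDataset,
    service: str,
    variables: Sequence[str] | None = None,
    alpha: float = DEFAULT_ALPHA,
    adjust: bool = False,
    per_segment_conditionals: bool = True,
) -> BatteryReport:
    """Run H1–H9 for one service over respondent-level data.

    Per-test failures (empty arms, degenerate cells) are recorded as
    skipped rows; the battery never aborts.  ``adjust=True`` annotates
    Benjamini–Hochberg q-values across all non-skipped tests (verdicts
    still use raw p-values, matching the uncorrected reference analysis).
    """
    if variables is None:
        variables = list(data.schema.names)
    report = BatteryReport(service=service, alpha=alpha)

    # H1-H3: one chi-square per variable and stage
    for h_id, stage in zip(("H1", "H2", "H3"), STAGES):
        for variable in variables:
            summaries = aggregate_segments(data, service, variable)
            try:
                r = divide_test(
                    summaries, stage, alpha=alpha,
                    hypothesis_id=f"{h_id}[{variable}]",
                )
                r.verdict = _verdict_divide(r)
            except UnsupportedInputError as exc:
                r = TestResult(
                    hypothesis_id=f"{h_id}[{variable}]",
                    test_name="chi_square_independence",
                    statistic=None, df=None, p_value=None, direction="none",
                    significant=False, alpha=alpha, skipped=True,
                    verdict="skipped", note=str(exc),
                )
            report.results.append(r)

    # H4/H5: adoption vs awareness / want (paired within respondents)
    for h_id, other in (("H4", "aware"), ("H5", "want")):
        r = paired_stage_test(
            data, service, "adopt", other, alpha=alpha,
            hypothesis_id=f"{h_id}[adopt vs {other}]",
        )
        r.verdict = _verdict_directional(r, _H_EXPECT[h_id])
        report.results.append(r)

    # H6: awareness vs want; either significant direction supports the
    # claim that want is not bound to awareness
    r = paired_stage_test(
        data, service, "aware", "want", alpha=alpha,
        hypothesis_id="H6[aware vs want]",
    )
    if r.significant and r.direction == "greater":
        r.verdict = "supported (H6-1: awareness > want)"
    elif r.significant and r.direction == "less":
        r.verdict = "supported (H6-2: want > awareness)"
    else:
        r.verdict = "not supported"
    report.results.append(r)

    # H7-H9: conditional comparisons, overall and per segment
    cond_specs = (
        ("H7", "want", "aware"),
        ("H8", "adopt", "want"),
        ("H9", "aware", "want"),
    )
    for h_id, target, given in cond_specs:
        r = conditional_test(
            data, service, target, given, alpha=alpha,
            hypothesis_id=f"{h_id}[overall]",
        )
        r.verdict = _verdict_directional(r, _H_EXPECT[h_id])
        report.results.append(r)
        if not per_segment_conditionals:
            continue
        for variable in variables:
            for label in data.schema.categories(variable):
                seg = data.subset(variable, label)
                item = data.schema.item_id(variable, label)
                if len(seg) == 0:
                    report.results.append(
                        TestResult(
                            hypothesis_id=f"{h_id}[{variable}:{item}]",
                            test_name="independent_two_proportion",
                            statistic=None, df=None, p_value=None,
                            direction="none", significant=False, alpha=alpha,
                            skipped=True, verdict="skipped",
                            note="empty segment",
                        )
                    )
                    continue
                r = conditional_test(
                    seg, service, target, given, alpha=alpha,
                    hypothesis_id=f"{h_id}[{variable}:{item}]",
                )
                r.verdict = _verdict_directional(r, _H_EXPECT[h_id])
                report.results.append(r)

    if adjust:
        tested = [r for r in report.results if r.p_value is not None]
        if tested:
            q = multipletests(
                [r.p_value for r in tested], method="fdr_bh"
            )[1]
            for r, qv in zip(tested, q):
                r.q_value = float(qv)
    return report
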