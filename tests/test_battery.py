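"""Hypothesis battery: oracles for each test family and battery verdicts."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from awag import (
    GeneratorConfig,
    SegmentSpec,
    conditional_test,
    divide_test,
    generate,
    load_fixture,
    paired_stage_test,
    run_battery,
)
from awag.errors import UnsupportedInputError
from awag.survey_data import STAGES, SegmentSummary

from conftest import make_dataset, two_service_config


def brute_force_chi_square(table: np.ndarray) -> float:
    """Independent oracle: sum (O-E)^2/E from row/column margins."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    stat = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            expected = table[i].sum() * table[:, j].sum() / total
            stat += (table[i, j] - expected) ** 2 / expected
    return stat


# ---------------------------------------------------------------------------
# H1-H3: chi-square divide test
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("table_name", ["dms", "dhcs"])
@pytest.mark.parametrize("stage", STAGES)
def test_divide_test_matches_brute_force(table_name, stage):
    """The statistic equals sum (O-E)^2/E on every reference 2xk table
    (k up to 9 segments)."""
    rows = load_fixture(table_name)
    by_var: dict[str, list] = {}
    for s in rows:
        if s.item_id != "T":
            by_var.setdefault(s.variable, []).append(s)
    for variable, segs in by_var.items():
        result = divide_test(segs, stage)
        table = np.array(
            [
                [getattr(s, f"{stage}_count"), s.n - getattr(s, f"{stage}_count")]
                for s in segs
            ]
        )
        assert result.statistic == pytest.approx(brute_force_chi_square(table))
        assert result.df == len(segs) - 1


def test_divide_test_computer_ownership_significant():
    """Computer owners vs nonowners show an awareness divide for the
    established service (counts 2496/2787 vs 170/286)."""
    segs = [
        SegmentSummary("dms", "computer_ownership", "C1", "Yes", 2787,
                       aware_count=2496, want_count=2259, adopt_count=1305),
        SegmentSummary("dms", "computer_ownership", "C2", "No", 286,
                       aware_count=170, want_count=132, adopt_count=65),
    ]
    r = divide_test(segs, "aware")
    assert r.p_value < 0.05 and r.significant
    assert r.statistic == pytest.approx(
        brute_force_chi_square([[2496, 291], [170, 116]])
    )


def test_divide_test_identical_segments_null():
    segs = [
        SegmentSummary("s", "v", "X1", "a", 100, 50, 50, 50),
        SegmentSummary("s", "v", "X2", "b", 100, 50, 50, 50),
    ]
    r = divide_test(segs, "aware")
    assert r.statistic == pytest.approx(0.0)
    assert r.p_value == pytest.approx(1.0)


def test_divide_test_requires_counts():
    segs = [
        SegmentSummary("s", "v", "X1", "a", 100, aware_rate=0.5,
                       want_rate=0.5, adopt_rate=0.1),
        SegmentSummary("s", "v", "X2", "b", 100, aware_rate=0.6,
                       want_rate=0.5, adopt_rate=0.1),
    ]
    with pytest.raises(UnsupportedInputError):
        divide_test(segs, "aware")


def test_divide_test_small_expected_flagged():
    segs = [
        SegmentSummary("s", "v", "X1", "a", 8, 1, 1, 1),
        SegmentSummary("s", "v", "X2", "b", 8, 2, 2, 2),
    ]
    r = divide_test(segs, "aware")
    assert r.min_expected < 5 and "expected" in r.note


# ---------------------------------------------------------------------------
# H4-H6: paired proportion test
# ---------------------------------------------------------------------------

def test_paired_same_stage_no_discordance(four_records):
    r = paired_stage_test(four_records, "svc", "aware", "aware")
    assert r.p_value == 1.0 and r.direction == "none"
    assert "no discordant" in r.note


def test_paired_exact_matches_binomial_oracle():
    """Below the discordant-pair threshold the p-value equals the exact
    two-sided binomial test on the discordant counts."""
    # 8 aware-only, 3 want-only, plus concordant filler
    triples = [(1, 0, 0)] * 8 + [(0, 1, 0)] * 3 + [(1, 1, 0)] * 50
    r = paired_stage_test(make_dataset(triples), "svc", "aware", "want")
    oracle = stats.binomtest(8, 11, 0.5).pvalue
    assert r.p_value == pytest.approx(oracle)
    assert r.direction == "greater"
    assert r.df is None  # exact route


def test_paired_nested_awareness_dominates():
    """When awareness strictly contains want (30% aware-only), the paired
    test detects awareness > want at n = 1000."""
    triples = [(1, 1, 1)] * 400 + [(1, 0, 0)] * 300 + [(0, 0, 0)] * 300
    r = paired_stage_test(make_dataset(triples), "svc", "aware", "want")
    assert r.direction == "greater" and r.p_value < 0.05
    oracle = stats.binomtest(300, 300, 0.5).pvalue
    # asymptotic route; exact oracle is astronomically small too
    assert r.p_value < 1e-10 and oracle < 1e-10


def test_paired_exact_and_asymptotic_agree_at_scale():
    """With >= 100 discordant pairs the two McNemar routes agree to 0.01."""
    from statsmodels.stats.contingency_tables import mcnemar

    for b, c in ((60, 55), (70, 50), (52, 48)):
        table = [[10, b], [c, 10]]
        exact = mcnemar(table, exact=True).pvalue
        asymptotic = mcnemar(table, exact=False, correction=True).pvalue
        assert abs(exact - asymptotic) < 0.01


# ---------------------------------------------------------------------------
# H7-H9: conditional two-proportion test
# ---------------------------------------------------------------------------

def test_conditional_test_detects_generated_gap():
    spec = SegmentSpec(
        label="s", n=2000, p_aware=0.5,
        p_want_given_aware=0.8, p_want_given_unaware=0.2,
        p_adopt_given_aware_want=0.3,
    )
    data = generate(GeneratorConfig(segments=(spec,), seed=2))
    r = conditional_test(data, "service", "want", "aware")
    assert r.direction == "greater" and r.significant


def test_conditional_test_z_statistic_oracle():
    """The statistic equals the pooled two-proportion z computed by hand."""
    triples = [(1, 1, 0)] * 30 + [(1, 0, 0)] * 10 + [(0, 1, 0)] * 5 + [(0, 0, 0)] * 25
    r = conditional_test(make_dataset(triples), "svc", "want", "aware")
    x1, n1, x0, n0 = 30, 40, 5, 30
    p_pool = (x1 + x0) / (n1 + n0)
    z = (x1 / n1 - x0 / n0) / np.sqrt(p_pool * (1 - p_pool) * (1 / n1 + 1 / n0))
    assert r.statistic == pytest.approx(z)
    assert r.p_value == pytest.approx(2 * stats.norm.sf(abs(z)))


def test_conditional_test_empty_arm_skipped():
    data = make_dataset([(1, 1, 0), (1, 0, 0)])  # nobody unaware
    r = conditional_test(data, "svc", "want", "aware")
    assert r.skipped and r.p_value is None and "empty" in r.note


# ---------------------------------------------------------------------------
# full battery
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def battery_reports(two_service_dataset):
    return {
        svc: run_battery(two_service_dataset, svc, ["gender"])
        for svc in ("dms", "dhcs")
    }


def test_battery_adoption_bound_hypotheses(battery_reports):
    """Adoption trails both awareness and want for both services."""
    for svc in ("dms", "dhcs"):
        rep = battery_reports[svc]
        assert rep.result("H4[adopt vs aware]").verdict == "supported"
        assert rep.result("H5[adopt vs want]").verdict == "supported"


def test_battery_want_awareness_order_flips_between_services(battery_reports):
    """Awareness leads want for the established service; want leads
    awareness for the newly introduced one (consumer pull)."""
    h6_dms = battery_reports["dms"].result("H6[aware vs want]")
    h6_dhcs = battery_reports["dhcs"].result("H6[aware vs want]")
    assert h6_dms.direction == "greater" and h6_dms.significant
    assert h6_dhcs.direction == "less" and h6_dhcs.significant
    assert "H6-1" in h6_dms.verdict and "H6-2" in h6_dhcs.verdict


def test_battery_no_gender_divide_when_rates_equal():
    """Identical stage probabilities across gender leave H1 unsupported."""
    seg = dict(
        n=1500, p_aware=0.87, p_want_given_aware=0.9,
        p_want_given_unaware=0.0, p_adopt_given_aware_want=0.5,
    )
    config = GeneratorConfig(
        segments=(
            SegmentSpec(label={"gender": "Male"}, **seg),
            SegmentSpec(label={"gender": "Female"}, **seg),
        ),
        services={"dms": {}},
        seed=19,
    )
    rep = run_battery(generate(config), "dms", ["gender"])
    assert rep.result("H1[gender]").verdict == "not supported"


def test_battery_structure_and_json(battery_reports):
    rep = battery_reports["dms"]
    ids = [r.hypothesis_id for r in rep.results]
    for prefix in ("H1[", "H2[", "H3[", "H4[", "H5[", "H6[",
                   "H7[overall]", "H8[overall]", "H9[overall]"):
        assert any(i.startswith(prefix) for i in ids)
    payload = rep.to_json()
    assert '"H4[adopt vs aware]"' in payload
    text = rep.to_text()
    assert "H6[aware vs want]" in text


def test_battery_bh_adjustment_annotates_q_values(two_service_dataset):
    rep = run_battery(
        two_service_dataset, "dms", ["gender"], adjust=True,
        per_segment_conditionals=False,
    )
    qs = [r.q_value for r in rep.results if r.p_value is not None]
    assert all(q is not None for q in qs)
    # BH never lowers a p-value's rank position below the raw p
    for r in rep.results:
        if r.p_value is not None:
            assert r.q_value >= r.p_value - 1e-12


def test_battery_alpha_one_everything_significant(two_service_dataset):
    rep = run_battery(
        two_service_dataset, "dms", ["gender"], alpha=1.0,
        per_segment_conditionals=False,
    )
    assert all(r.significant for r in rep.results if not r.skipped)
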