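# Methods

This note documents the models, numerical choices, and design decisions
behind the package, in the order a user meets them.

## The three-stage funnel

Every respondent carries, per service, three binary indicators: aware,
want, adopt.  The analysis treats them as the hierarchical stages of the
innovation-adoption funnel — want is typically created by awareness, and
adoption presupposes want — but **no structural constraint among the three
is imposed on input data**: readers accept any 0/1 combination, because
observed surveys contain respondents who want a service they have never
heard of (consumer pull running ahead of technology push).  The hierarchy
is enforced only where it belongs, in the synthetic generator's default
parameterization.

Rates are stored as proportions in [0, 1] throughout; percentages appear
only at I/O boundaries (CSV columns, logs, plots).  Rendering rounds
half-up (44.35 → 44.4), matching survey-table convention rather than
banker's rounding, at 1 decimal by default and 2 where the source prints 2.

## Segment matrix

Classification takes a segment's (awareness, want) pair in the unit
square.  Cuts at 15%, 50%, 85% (the technology-adoption-lifecycle
cumulative rates after the innovator and early/late-majority breakpoints)
split each axis into bands B0–B3.  Conventions, each load-bearing:

* **A cut value belongs to the upper band** (0.85 → B3, 0.50 → B2).  The
  ≥ convention is required to reproduce the reference classification of
  segments whose want rate is exactly 85.1…85.9 with awareness ≥ 85
  (strong-opened), and is applied uniformly at all three cuts.
* The 50% cut decides the category (opened / desire-deficiency /
  perception-deficiency / closed); the band pair inside the quadrant
  decides the subcategory.  In the opened and closed quadrants the four
  cells map to strong / awareness-bias / want-bias / generic with
  "strong" at the extreme corner.  The desire- and
  perception-deficiency quadrants have four band cells but only three
  named subcategories: "strong" is the farthest corner (B3 awareness with
  B0 want, and vice versa), "generic" the least extreme cell, and the two
  off-diagonal cells collapse into the quadrant's bias subcategory
  (want-bias for desire-deficiency, awareness-bias for
  perception-deficiency).  No reference row contradicts this collapse.
* Classification uses unrounded `count/n` rates when a summary was built
  from counts, and the stored (printed) rates for rate-only rows —
  concretely, whatever `SegmentSummary` holds in its rate fields, which
  is exactly one of those two things by construction.

The partition property (201×201 grid, 16 cells, no gaps or overlaps) is
asserted in the test suite.

**Improvement direction.**  A segment should keep raising awareness iff
its awareness band is below B3, and likewise for want; only the
strong-opened cell is settled.  When a region is constructed from a bare
code rather than from rates, the two collapsed cells (`D_Wb`, `P_Ab`)
are ambiguous in one band; the code-only path then conservatively flags
both directions, while the rate-based path uses the exact bands.

**Prescriptions** (strategy, action text, target-market tier) are a fixed
14-row lookup keyed by (category, subcategory); the two impossible pairs
(desire-deficiency × awareness-bias, perception-deficiency × want-bias)
raise rather than silently mapping to a neighbor.

## Adoption gap ratio

Two variants are implemented:

* `want_based` (default): g = (want − adopt) / want;
* `min_based`: g = (min(aware, want) − adopt) / min(aware, want).

The narrative definition of the statistic — zero when adoption equals the
minimum of awareness and want — describes the min-based form, but the
reference tables' printed gap column follows the want-based arithmetic on
every row of both tables (e.g. the new service's full-sample row:
(69.6 − 4.9)/69.6 = 93.0, where the min-based form gives 90.4).  The two
coincide whenever awareness ≥ want, which holds on nearly all
established-service rows; they diverge exactly where awareness < want.
The want-based form is therefore the default, both are exposed, and the
CLI logs the discrepancy when min-based is requested against annotated
tables.  The acceptance suite asserts both the agreement (want-based,
±0.2 pp on all 90 rows) and the disagreement (min-based, every
awareness < want row).

A negative raw gap (adoption above the reference rate — possible in
inputs that violate the funnel) clamps to 0 with a `clamped` flag; a zero
reference rate raises an explicit undefined-gap error rather than
returning 0/0.

## Rate estimation

Marginal and conditional estimates always carry numerator and
denominator.  A conditional whose conditioning event has an empty cell is
explicitly *undefined* (`defined = False`, rate `None`) and downstream
tests skip it with a logged reason — empty cells are reachable in the
reference data's smallest segments (n ≈ 130 with low awareness).  The
law-of-total-probability identity (marginal count = sum of conditional
numerators over the conditioning split) holds exactly on counts and is
property-tested.  No continuity or shrinkage corrections are applied;
the method reports raw proportions.

## Hypothesis battery

* **H1–H3** (stage divide across segments): chi-square test of
  independence on the k×2 table of (stage yes, stage no) counts per
  segment, Total row excluded, k up to 9.  No Yates correction for k > 2;
  for 2×2 the correction is configurable and off by default (the source
  analysis does not specify one).  The minimum expected cell count is
  attached and flagged below 5.  Rate-only inputs raise: the test needs
  counts.
* **H4–H6** (paired stage comparison): the "paired proportion test" is
  McNemar's test on the within-respondent 2×2 — the standard paired-binary
  choice.  Exact binomial on the discordant pairs below 25 discordants,
  continuity-corrected chi-square above; the two routes agree within 0.01
  in p beyond 100 discordants (tested).  Direction reports which stage's
  marginal rate is higher.  H4/H5 are "supported" when adoption trails
  significantly; H6 is satisfied by either significant direction, with
  the sub-verdicts H6-1 (awareness > want, typical of established
  services) and H6-2 (want > awareness, typical of newly introduced ones)
  distinguished in the report.
* **H7–H9** (conditional comparisons): pooled two-proportion z-test of
  the target stage rate between the conditioning stage's 1- and 0-arms,
  run overall and per segment.  Empty arms produce skipped rows with
  reasons, never aborts.

Alpha defaults to .05, the level at which all reference verdicts are
stated.  No multiple-testing correction is applied by default, matching
the source analysis; `adjust=True` annotates Benjamini–Hochberg q-values
without changing verdicts.  Under equal-proportion null simulations
(2000 replicates, n = 500 per arm) each test's rejection rate stays
within [.03, .07] (acceptance suite); the McNemar route sits slightly
below .05 by design of the continuity correction.

## Synthetic surveys

The generator draws, per respondent: aware ~ Bernoulli(p_aware); want ~
Bernoulli(p_want|aware-state); adopt ~ Bernoulli(p_adopt|aware, want
cell).  Defaults encode the funnel: `p_adopt_given_unaware = 0` (no
adoption without awareness) and `p_adopt_given_aware_nowant = 0`;
both can be raised to stress-test hierarchy-violating inputs.  Draws use
one seeded NumPy generator per dataset, consumed in a fixed order
(segments in declaration order, services within a segment, then the
aware/want/adopt uniform vectors), so identical configs and seeds give
byte-identical output.

`spec_from_rates` inverts target marginals (a, w, d) under the **nested
construction**: want ⊆ aware when w ≤ a (p_want|aware = w/a, 0 among the
unaware), otherwise everyone aware wants and the surplus is placed among
the unaware (p_want|unaware = (w − a)/(1 − a)); adoption sits entirely in
the aware∧want cell, whose mass is min(a, w) — hence the feasibility
requirement d ≤ min(a, w).  The implied marginals reproduce the inputs to
machine precision (property-tested).  Marginal rates do not identify the
joint (aware, want) distribution; the nested construction is one
admissible choice and reports label it as such.

What the generator emulates: a stratified single-wave telephone survey
with per-stratum stage probabilities and unit weights.  What it does not:
nonresponse, interviewer effects, within-household clustering,
cross-service correlation beyond shared stratum membership, or temporal
push/pull dynamics.  Passing pipeline tests therefore demonstrate
statistical correctness of the machinery under the stated model, not
robustness to real-survey artifacts.

## Packaged reference tables

The three fixture CSVs transcribe the validation survey's printed tables
verbatim (n = 3074 Taiwanese respondents aged 15+; an established and a
newly introduced eHealth service; 45 segments each: total, gender, age,
education, marital status, area, personal and family income, computer
ownership, internet access).  Labels are normalized to ASCII
("≥65" → ">=65"); "Don't know/no answer" and "Other" are ordinary
categories, never dropped — the analysis treats them as segments.

Each segment row stores both the printed counts and the printed rates,
plus the printed gap ratio and region code as expected-value annotations.
**The printed rates are authoritative**: recomputing count/n reproduces
them only within ~0.7 pp (worst on the smallest stratum, n = 87), a
pattern consistent with an undisclosed weighting in the source analysis.
The loader therefore stores rates as printed, the consistency test bounds
the deviation at 0.7 pp, and all region/gap validation uses printed
rates.  The sample-profile table also contains small internal
inconsistencies (category n's summing to 3073–3075 against a printed
total of 3074); it is transcribed as printed, and the
counts-sum-to-total invariant is asserted only for the package's own
aggregation output.

## Problem sizes used in validation

Fixture-based checks are exact and instantaneous.  Stochastic checks use:
null calibration at 2000 replicates × 500 per arm; generator recovery of
the full-sample rows at n = 100 000 (three-standard-error tolerance);
qualitative battery reproduction on two 1537-respondent strata per
service, sizes chosen to mirror the reference survey's gender strata.

## Known limitations

* Weighted aggregation uses weight-sum pseudo-counts for rates but the
  hypothesis battery consumes raw counts only; design-based variance
  (Rao–Scott style corrections) is out of scope.
* The battery's per-segment conditional tests multiply comparisons;
  q-values are available but verdicts deliberately follow the
  uncorrected convention of the reference analysis.
* Confidence intervals on rates are not reported; standard errors are
  used internally by the validation suite only.
* The matrix plot's axis convention (want on x, awareness on y) is a
  declared choice, configurable via ``want_on_x``.
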