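"""Seeded generator of respondent-level surveys with the funnel hierarchy.

Respondents are drawn segment by segment from a three-level conditional
Bernoulli model: awareness first, then want conditional on the awareness
state, then adoption conditional on the (awareness, want) cell.  The
default adoption channel requires awareness — a respondent who has never
heard of a service cannot have used it — but ``p_adopt_given_unaware`` may
be raised to stress-test inputs that violate the hierarchy.

The model emulates a stratified telephone survey of the kind behind the
packaged reference tables (segments = demographic strata, all weights 1).
It deliberately does not model interviewer effects, item nonresponse, or
correlation between services beyond shared segment membership.

The joint (awareness, want) distribution is not identified by marginal
rates alone; :func:`spec_from_rates` uses the *nested* construction (want
contained in awareness where feasible, adoption entirely inside the
aware-and-want cell), one admissible choice, and reports it as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .classification import (
    AwagRegion,
    ClassificationBands,
    DEFAULT_BANDS,
    classify_region,
)
from .errors import FeasibilityError, ValidationError
from .rate_estimation import marginal_rates
from .survey_data import STAGES, AttributeSchema, SurveyDataset

_PROB_FIELDS = (
    "p_aware",
    "p_want_given_aware",
    "p_want_given_unaware",
    "p_adopt_given_aware_want",
    "p_adopt_given_aware_nowant",
    "p_adopt_given_unaware",
)


@dataclass(frozen=True)
class SegmentSpec:
    """One stratum: its attribute labels, size, and stage probabilities.

    ``label`` is either a mapping attribute-name -> category (multi
    attribute strata) or a bare string, shorthand for ``{"segment": label}``.
    """

    label: Mapping[str, str] | str
    n: int
    p_aware: float
    p_want_given_aware: float
    p_want_given_unaware: float
    p_adopt_given_aware_want: float
    p_adopt_given_aware_nowant: float = 0.0
    p_adopt_given_unaware: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValidationError(f"segment size must be >= 0, got {self.n}")
        for name in _PROB_FIELDS:
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1], got {p}")

    @property
    def attributes(self) -> dict[str, str]:
        if isinstance(self.label, str):
            return {"segment": self.label}
        return dict(self.label)

    def expected_marginals(self) -> tuple[float, float, float]:
        """Exact (awareness, want, adoption) marginals implied by the spec."""
        a = self.p_aware
        w = a * self.p_want_given_aware + (1 - a) * self.p_want_given_unaware
        ad = a * (
            self.p_want_given_aware * self.p_adopt_given_aware_want
            + (1 - self.p_want_given_aware) * self.p_adopt_given_aware_nowant
        ) + (1 - a) * self.p_adopt_given_unaware
        return a, w, ad


@dataclass(frozen=True)
class GeneratorConfig:
    """Respondent pool plus optional per-service probability overrides.

    ``segments`` defines the strata (attributes, sizes, default
    probabilities).  ``services`` maps service name -> {segment key ->
    SegmentSpec} overriding the stage probabilities for that service; a
    service absent from the mapping (or mapped to an empty dict) uses each
    segment's own probabilities.  The segment key is the bare string label
    or, for mapping labels, the "|"-joined category tuple.
    """

    segments: tuple[SegmentSpec, ...]
    services: Mapping[str, Mapping[str, SegmentSpec]] = field(default_factory=dict)
    seed: int = 0
    schema: AttributeSchema | None = None

    def __post_init__(self) -> None:
        keys = [_segment_key(s) for s in self.segments]
        if len(set(keys)) != len(keys):
            raise ValidationError("segment labels must be unique")

    @property
    def service_names(self) -> tuple[str, ...]:
        return tuple(self.services) if self.services else ("service",)

    @classmethod
    def from_mapping(cls, data: Mapping) -> "GeneratorConfig":
        def spec(entry: Mapping) -> SegmentSpec:
            allowed = {f.name for f in dc_fields(SegmentSpec)}
            return SegmentSpec(**{k: v for k, v in entry.items() if k in allowed})

        segments = tuple(spec(e) for e in data["segments"])
        services: dict[str, dict[str, SegmentSpec]] = {}
        for svc, overrides in (data.get("services") or {}).items():
            services[svc] = {}
            for entry in overrides or []:
                s = spec(entry)
                services[svc][_segment_key(s)] = s
        return cls(
            segments=segments,
            services=services,
            seed=int(data.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_mapping(yaml.safe_load(fh))


def _segment_key(spec: SegmentSpec) -> str:
    if isinstance(spec.label, str):
        return spec.label
    return "|".join(str(v) for v in spec.label.values())


def _schema_from_segments(
    segments: Sequence[SegmentSpec], services: Sequence[str]
) -> AttributeSchema:
    names: dict[str, list[str]] = {}
    for seg in segments:
        for attr, cat in seg.attributes.items():
            names.setdefault(attr, [])
            if cat not in names[attr]:
                names[attr].append(cat)
    return AttributeSchema(
        attributes=tuple((n, tuple(cats)) for n, cats in names.items()),
        services=tuple(services),
    )


def generate(config: GeneratorConfig) -> SurveyDataset:
    """Draw a full survey; byte-identical for identical config and seed.

    Draw order is fixed: segments in declaration order, services in
    declaration order within a segment, and aware -> want -> adopt uniform
    vectors within a service.
    """
    rng = np.random.default_rng(config.seed)
    services = config.service_names
    blocks = []
    offset = 0
    for seg in config.segments:
        block: dict = {}
        for attr, cat in seg.attributes.items():
            block[attr] = np.full(seg.n, cat, dtype=object)
        for svc in services:
            spec = config.services.get(svc, {}).get(_segment_key(seg), seg)
            u_aware = rng.random(seg.n)
            u_want = rng.random(seg.n)
            u_adopt = rng.random(seg.n)
            aware = (u_aware < spec.p_aware).astype(np.int8)
            p_want = np.where(
                aware == 1, spec.p_want_given_aware, spec.p_want_given_unaware
            )
            want = (u_want < p_want).astype(np.int8)
            p_adopt = np.where(
                aware == 1,
                np.where(
                    want == 1,
                    spec.p_adopt_given_aware_want,
                    spec.p_adopt_given_aware_nowant,
                ),
                spec.p_adopt_given_unaware,
            )
            adopt = (u_adopt < p_adopt).astype(np.int8)
            block[f"{svc}_aware"] = aware
            block[f"{svc}_want"] = want
            block[f"{svc}_adopt"] = adopt
        frame = pd.DataFrame(block)
        frame.insert(
            0, "respondent_id",
            [f"r{offset + i + 1:06d}" for i in range(seg.n)],
        )
        frame.insert(1, "weight", 1.0)
        offset += seg.n
        blocks.append(frame)
    frame = (
        pd.concat(blocks, ignore_index=True)
        if blocks
        else pd.DataFrame(columns=["respondent_id", "weight"])
    )
    schema = config.schema or _schema_from_segments(config.segments, services)
    return SurveyDataset(frame=frame, schema=schema, services=services)


def spec_from_rates(
    aware_rate: float,
    want_rate: float,
    adopt_rate: float,
    n: int = 1,
    label: Mapping[str, str] | str = "calibrated",
) -> SegmentSpec:
    """Calibrate a nested-model spec whose exact marginals equal the inputs.

    Want nests inside awareness when ``want_rate <= aware_rate``; otherwise
    everyone aware wants and the surplus want is placed among the unaware.
    Adoption sits entirely in the aware-and-want cell, whose mass under
    this construction is ``min(aware_rate, want_rate)`` — hence the
    feasibility requirement ``adopt_rate <= min(aware_rate, want_rate)``.
    """
    for name, rate in (
        ("aware_rate", aware_rate), ("want_rate", want_rate),
        ("adopt_rate", adopt_rate),
    ):
        if not (0.0 <= rate <= 1.0):
            raise ValidationError(f"{name} must be in [0, 1], got {rate}")
    reference = min(aware_rate, want_rate)
    if adopt_rate > reference:
        raise FeasibilityError(
            f"adopt_rate {adopt_rate} exceeds min(aware, want) = {reference}; "
            "infeasible under the nested construction"
        )
    if want_rate <= aware_rate:
        p_w_a = want_rate / aware_rate if aware_rate > 0 else 0.0
        p_w_u = 0.0
    else:
        p_w_a = 1.0
        p_w_u = (want_rate - aware_rate) / (1.0 - aware_rate)
    p_ad_aw = adopt_rate / reference if reference > 0 else 0.0
    return SegmentSpec(
        label=label, n=n,
        p_aware=aware_rate,
        p_want_given_aware=p_w_a,
        p_want_given_unaware=p_w_u,
        p_adopt_given_aware_want=min(p_ad_aw, 1.0),
    )


@dataclass(frozen=True)
class RecoveryReport:
    """Generate-then-reestimate diagnostics for one spec."""

    n: int
    seed: int
    specified_rates: tuple[float, float, float]
    estimated_rates: tuple[float, float, float] | None
    max_abs_deviation: float | None
    specified_region: AwagRegion
    estimated_region: AwagRegion | None
    region_match: bool
    boundary_proximity: bool
    degenerate: bool = False


def recovery_check(
    spec: SegmentSpec,
    n: int,
    seed: int = 0,
    bands: ClassificationBands = DEFAULT_BANDS,
) -> RecoveryReport:
    """Generate n respondents from ``spec`` and re-estimate rates and region.

    ``boundary_proximity`` flags specs whose awareness or want marginal
    lies within 3 sampling standard errors of a band cut — there the
    recovered region may legitimately flip.
    """
    a, w, _ = spec.expected_marginals()
    spec_rates = spec.expected_marginals()
    specified_region = classify_region(a, w, bands)
    proximity = False
    if n > 0:
        for rate in (a, w):
            se = (rate * (1 - rate) / n) ** 0.5
            if any(abs(rate - cut) < 3 * se for cut in bands.cuts):
                proximity = True
    if n == 0:
        return RecoveryReport(
            n=0, seed=seed, specified_rates=spec_rates,
            estimated_rates=None, max_abs_deviation=None,
            specified_region=specified_region, estimated_region=None,
            region_match=False, boundary_proximity=proximity, degenerate=True,
        )
    sized = SegmentSpec(
        label=spec.label, n=n,
        **{f: getattr(spec, f) for f in _PROB_FIELDS},
    )
    data = generate(GeneratorConfig(segments=(sized,), seed=seed))
    est = marginal_rates(data, "service")
    est_rates = (est.aware_rate, est.want_rate, est.adopt_rate)
    estimated_region = classify_region(est.aware_rate, est.want_rate, bands)
    return RecoveryReport(
        n=n, seed=seed, specified_rates=spec_rates,
        estimated_rates=est_rates,
        max_abs_deviation=max(
            abs(e - s) for e, s in zip(est_rates, spec_rates)
        ),
        specified_region=specified_region,
        estimated_region=estimated_region,
        region_match=estimated_region.code == specified_region.code,
        boundary_proximity=proximity,
    )
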