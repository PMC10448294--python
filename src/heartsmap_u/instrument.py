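"""Data model for the HEARTSMAP-U instrument and its assessment records.

HEARTSMAP-U is a psychosocial self-screening instrument for postsecondary
students.  It has 10 sections, each scored on a 4-point Likert-type scale
from 0 (no concern) to 3 (severe concern).  The decision-making algorithm
aggregates section scores into 4 broad domains (Social, Function,
Psychiatry, Student Health); each domain maps to exactly 3 sections and a
section may serve more than one domain.  The domain score (0-9) is the sum
of the mapped section scores and is banded into a severity class — none
(0), mild (1-3), moderate (4-6), severe (7-9) — which drives firm (urgent,
time-sensitive) and soft (advisory) resource recommendations.

This module holds the validated data containers:

* :class:`InstrumentDefinition` — the versioned rule set (sections, domain
  map, severity cutoffs, recommendation rules), fully config-driven.
* :class:`AssessmentRecord` — one participant x timepoint of section
  scores and conditional resource-access flags.
* :class:`ClinicianAssessment` — the clinician reference-standard record
  (psychiatric concern, ordinal severity, psychosocial concern categories,
  resource needs with timeframes).

All structural invariants are enforced at construction via pydantic, so a
record or definition that exists is valid.
"""

from __future__ import annotations

import enum
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "Severity",
    "ResourceCategory",
    "Timeframe",
    "Firmness",
    "Timepoint",
    "RecommendationRule",
    "InstrumentDefinition",
    "AssessmentRecord",
    "ClinicianAssessment",
    "InstrumentValidationError",
    "SECTION_DISPLAY_NAMES",
    "PSYCHOSOCIAL_SECTION_MAP",
    "default_instrument",
    "validate_instrument",
    "validate_assessment",
]


class InstrumentValidationError(ValueError):
    """A structural invariant of the instrument or a record is violated.

    The message always names the offending element (section, domain,
    cutoff band or rule) so config errors are diagnosable.
    """


class Severity(str, enum.Enum):
    """Ordinal severity band for a domain score (and clinician ratings)."""

    NONE = "none"
    MILD = "mild"
    MODERATE = "moderate"
    SEVERE = "severe"

    @property
    def rank(self) -> int:
        return _SEVERITY_ORDER.index(self)

    def __ge__(self, other: "Severity") -> bool:  # type: ignore[override]
        return self.rank >= other.rank

    def __gt__(self, other: "Severity") -> bool:  # type: ignore[override]
        return self.rank > other.rank

    def __le__(self, other: "Severity") -> bool:  # type: ignore[override]
        return self.rank <= other.rank

    def __lt__(self, other: "Severity") -> bool:  # type: ignore[override]
        return self.rank < other.rank


_SEVERITY_ORDER = [Severity.NONE, Severity.MILD, Severity.MODERATE, Severity.SEVERE]


class ResourceCategory(str, enum.Enum):
    """Service categories a recommendation can point to."""

    URGENT_CRISIS = "urgent_crisis"
    PSYCHIATRIC_CONSULTATION = "psychiatric_consultation"
    COUNSELING = "counseling"
    PRIMARY_CARE = "primary_care"
    PEER_SUPPORT = "peer_support"
    COMMUNITY_SERVICE = "community_service"  # academic / financial / housing
    SELF_DIRECTED = "self_directed"


# fixed category order used for deterministic recommendation ordering
CATEGORY_ORDER = [
    ResourceCategory.URGENT_CRISIS,
    ResourceCategory.PSYCHIATRIC_CONSULTATION,
    ResourceCategory.COUNSELING,
    ResourceCategory.PRIMARY_CARE,
    ResourceCategory.PEER_SUPPORT,
    ResourceCategory.COMMUNITY_SERVICE,
    ResourceCategory.SELF_DIRECTED,
]


class Timeframe(str, enum.Enum):
    """How soon a recommended resource should be accessed."""

    IMMEDIATELY = "immediately"
    WITHIN_72H = "within-72h"
    WITHIN_1WK = "within-1wk"
    AFTER_1WK = "after-1wk"
    UNSPECIFIED = "unspecified"

    @property
    def urgency_rank(self) -> int:
        """0 is most urgent; ``unspecified`` sorts last."""
        return _TIMEFRAME_ORDER.index(self)


_TIMEFRAME_ORDER = [
    Timeframe.IMMEDIATELY,
    Timeframe.WITHIN_72H,
    Timeframe.WITHIN_1WK,
    Timeframe.AFTER_1WK,
    Timeframe.UNSPECIFIED,
]

#: Timeframes a clinician reference record may use (no "unspecified").
CLINICIAN_TIMEFRAMES = frozenset(_TIMEFRAME_ORDER[:4])


class Firmness(str, enum.Enum):
    FIRM = "firm"
    SOFT = "soft"


class Timepoint(str, enum.Enum):
    BASELINE = "baseline"
    FOLLOWUP = "followup"


# clinician psychosocial concern categories and the tool section whose
# flag (score >= 1) predicts each of them
PSYCHOSOCIAL_SECTION_MAP: dict[str, str] = {
    "housing": "housing",
    "education": "education",
    "relationships": "relationships",
    "substances": "substances",
    "sexual": "sexual_wellness",
    "abuse": "abuse",
}

SECTION_DISPLAY_NAMES: dict[str, str] = {
    "housing": "Housing & Material Security",
    "education": "Education & Activities",
    "relationships": "Relationships",
    "thoughts_anxiety": "Thoughts & Anxiety",
    "substances": "Substances & Behavioural Dependencies",
    "safety": "Safety",
    "sexual_wellness": "Sexual Wellness",
    "mood": "Mood",
    "abuse": "Abuse",
    "professionals": "Professionals & Resources",
}


class RecommendationRule(BaseModel):
    """One row of the recommendation rule table.

    The trigger is a conjunction over whichever predicate fields are set:

    * ``domain`` + ``severity_in`` — fires when that domain's severity
      class is in the set;
    * ``section`` + ``min_score`` — fires when that single section scores
      at or above the threshold (acuity/crisis overrides, e.g. Safety >= 2);
    * neither — an unconditional floor rule (self-directed maintenance).

    Firm rules are urgent and time-sensitive, so they must carry a concrete
    timeframe; soft rules are advisory considerations.
    """

    model_config = ConfigDict(frozen=True)

    rule_id: str
    resource_category: ResourceCategory
    firmness: Firmness
    timeframe: Timeframe
    domain: Optional[str] = None
    severity_in: Optional[frozenset[Severity]] = None
    section: Optional[str] = None
    min_score: Optional[int] = Field(default=None, ge=0, le=3)

    @model_validator(mode="after")
    def _check(self) -> "RecommendationRule":
        if self.firmness is Firmness.FIRM and self.timeframe is Timeframe.UNSPECIFIED:
            raise InstrumentValidationError(
                f"rule {self.rule_id!r}: firm rules require a concrete timeframe"
            )
        if (self.domain is None) != (self.severity_in is None):
            raise InstrumentValidationError(
                f"rule {self.rule_id!r}: domain and severity_in must be set together"
            )
        if (self.section is None) != (self.min_score is None):
            raise InstrumentValidationError(
                f"rule {self.rule_id!r}: section and min_score must be set together"
            )
        return self

    @property
    def is_floor(self) -> bool:
        return self.domain is None and self.section is None


class InstrumentDefinition(BaseModel):
    """A versioned instrument rule set.

    ``severity_cutoffs`` maps each severity label to an inclusive
    ``(low, high)`` integer range over the 0-9 domain-score scale; the
    ranges must partition 0-9 with no gap or overlap.  ``domain_map``
    assigns exactly 3 declared sections to each domain (sections may serve
    several domains).
    """

    model_config = ConfigDict(frozen=True)

    name: str
    version: str
    sections: tuple[str, ...]
    domain_map: dict[str, tuple[str, str, str]]
    severity_cutoffs: dict[Severity, tuple[int, int]]
    recommendation_rules: tuple[RecommendationRule, ...]

    @model_validator(mode="after")
    def _check(self) -> "InstrumentDefinition":
        if len(self.sections) != 10:
            raise InstrumentValidationError(
                f"instrument must declare exactly 10 sections, got {len(self.sections)}"
            )
        if len(set(self.sections)) != len(self.sections):
            dupes = sorted({s for s in self.sections if self.sections.count(s) > 1})
            raise InstrumentValidationError(f"duplicate section identifiers: {dupes}")
        declared = set(self.sections)
        for domain, secs in self.domain_map.items():
            if len(secs) != 3 or len(set(secs)) != 3:
                raise InstrumentValidationError(
                    f"domain {domain!r} must map to exactly 3 distinct sections, got {secs}"
                )
            for s in secs:
                if s not in declared:
                    raise InstrumentValidationError(
                        f"domain {domain!r} references unknown section {s!r}"
                    )
        self._check_cutoffs()
        for rule in self.recommendation_rules:
            if rule.domain is not None and rule.domain not in self.domain_map:
                raise InstrumentValidationError(
                    f"rule {rule.rule_id!r} references unknown domain {rule.domain!r}"
                )
            if rule.section is not None and rule.section not in declared:
                raise InstrumentValidationError(
                    f"rule {rule.rule_id!r} references unknown section {rule.section!r}"
                )
        # totality: the floor rule guarantees every assessment yields >=1 item
        if not any(rule.is_floor for rule in self.recommendation_rules):
            raise InstrumentValidationError(
                "rule set has no unconditional floor rule; recommendations would "
                "not be total over assessments"
            )
        return self

    def _check_cutoffs(self) -> None:
        covered: dict[int, Severity] = {}
        for label, (lo, hi) in self.severity_cutoffs.items():
            if lo > hi:
                raise InstrumentValidationError(
                    f"severity band {label.value!r} has empty range ({lo}, {hi})"
                )
            for s in range(lo, hi + 1):
                if s in covered:
                    raise InstrumentValidationError(
                        f"severity bands {covered[s].value!r} and {label.value!r} "
                        f"overlap at score {s}"
                    )
                covered[s] = label
        missing = sorted(set(range(10)) - set(covered))
        extra = sorted(set(covered) - set(range(10)))
        if missing:
            raise InstrumentValidationError(
                f"severity bands leave domain scores {missing} unclassified"
            )
        if extra:
            raise InstrumentValidationError(
                f"severity bands cover scores {extra} outside the 0-9 range"
            )

    @property
    def domains(self) -> tuple[str, ...]:
        return tuple(self.domain_map)


class AssessmentRecord(BaseModel):
    """One participant's self-assessment at one timepoint.

    Every declared section carries a score in {0, 1, 2, 3}.  The tool only
    prompts for resource access when a section is scored 1-3, so an access
    flag must be present exactly for sections with score >= 1.  Free-text
    responses are stored verbatim and never parsed.
    """

    model_config = ConfigDict(frozen=True)

    participant_id: str
    timepoint: Timepoint
    section_scores: dict[str, int]
    access_flags: dict[str, bool] = Field(default_factory=dict)
    free_text: dict[str, str] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check_scores(self) -> "AssessmentRecord":
        for section, score in self.section_scores.items():
            if score not in (0, 1, 2, 3):
                raise InstrumentValidationError(
                    f"participant {self.participant_id!r}: section {section!r} "
                    f"score {score} outside 0-3"
                )
        return self


class ClinicianAssessment(BaseModel):
    """Clinician-administered reference-standard assessment.

    ``psychiatric_severity`` is ``none`` exactly when no psychiatric
    concern is endorsed.  ``resource_needs`` pairs each identified service
    category with the clinician's access timeframe (four-level list, never
    "unspecified").
    """

    model_config = ConfigDict(frozen=True)

    participant_id: str
    timepoint: Timepoint
    psychiatric_concern: bool
    psychiatric_severity: Severity
    concern_areas: frozenset[str] = frozenset()
    psychosocial_concerns: dict[str, bool] = Field(default_factory=dict)
    resource_needs: frozenset[tuple[ResourceCategory, Timeframe]] = frozenset()

    @model_validator(mode="after")
    def _check(self) -> "ClinicianAssessment":
        if (self.psychiatric_severity is Severity.NONE) != (not self.psychiatric_concern):
            raise InstrumentValidationError(
                f"participant {self.participant_id!r}: psychiatric_severity must be "
                "'none' exactly when psychiatric_concern is absent"
            )
        for category, timeframe in self.resource_needs:
            if timeframe not in CLINICIAN_TIMEFRAMES:
                raise InstrumentValidationError(
                    f"participant {self.participant_id!r}: resource need "
                    f"{category.value!r} carries non-clinical timeframe {timeframe.value!r}"
                )
        return self


# ---------------------------------------------------------------------------
# default (shipped) instrument definition
# ---------------------------------------------------------------------------

_DEFAULT_SECTIONS = (
    "housing",
    "education",
    "relationships",
    "thoughts_anxiety",
    "substances",
    "safety",
    "sexual_wellness",
    "mood",
    "abuse",
    "professionals",
)

# Social, Function and Psychiatry section membership is fixed by the
# instrument's published description.  Student Health's 3 sections are not
# enumerated there; the shipped default (an explicit assumption, replaceable
# via config) assigns the two otherwise-unmapped sections plus Sexual
# Wellness, honouring "multiple sections map to >1 domain".
_DEFAULT_DOMAIN_MAP: dict[str, tuple[str, str, str]] = {
    "social": ("housing", "substances", "abuse"),
    "function": ("substances", "relationships", "sexual_wellness"),
    "psychiatry": ("mood", "thoughts_anxiety", "safety"),
    "student_health": ("education", "professionals", "sexual_wellness"),
}

_DEFAULT_CUTOFFS: dict[Severity, tuple[int, int]] = {
    Severity.NONE: (0, 0),
    Severity.MILD: (1, 3),
    Severity.MODERATE: (4, 6),
    Severity.SEVERE: (7, 9),
}

# Domain-matched firm service for severe presentations.
_DOMAIN_SEVERE_CATEGORY: dict[str, ResourceCategory] = {
    "psychiatry": ResourceCategory.PSYCHIATRIC_CONSULTATION,
    "social": ResourceCategory.COMMUNITY_SERVICE,
    "function": ResourceCategory.COUNSELING,
    "student_health": ResourceCategory.PRIMARY_CARE,
}


def _default_rules() -> tuple[RecommendationRule, ...]:
    rules: list[RecommendationRule] = []
    sev = frozenset({Severity.SEVERE})
    mod = frozenset({Severity.MODERATE})
    mild = frozenset({Severity.MILD})
    for domain, category in _DOMAIN_SEVERE_CATEGORY.items():
        rules.append(
            RecommendationRule(
                rule_id=f"{domain}-severe",
                domain=domain,
                severity_in=sev,
                resource_category=category,
                firmness=Firmness.FIRM,
                timeframe=Timeframe.WITHIN_72H,
            )
        )
        rules.append(
            RecommendationRule(
                rule_id=f"{domain}-moderate-counseling",
                domain=domain,
                severity_in=mod,
                resource_category=ResourceCategory.COUNSELING,
                firmness=Firmness.FIRM,
                timeframe=Timeframe.WITHIN_1WK,
            )
        )
        rules.append(
            RecommendationRule(
                rule_id=f"{domain}-moderate-primary-care",
                domain=domain,
                severity_in=mod,
                resource_category=ResourceCategory.PRIMARY_CARE,
                firmness=Firmness.FIRM,
                timeframe=Timeframe.WITHIN_1WK,
            )
        )
        # mild issues: advisory primary-care access in case of escalation
        rules.append(
            RecommendationRule(
                rule_id=f"{domain}-mild-primary-care",
                domain=domain,
                severity_in=mild,
                resource_category=ResourceCategory.PRIMARY_CARE,
                firmness=Firmness.SOFT,
                timeframe=Timeframe.UNSPECIFIED,
            )
        )
        rules.append(
            RecommendationRule(
                rule_id=f"{domain}-mild-peer-support",
                domain=domain,
                severity_in=mild,
                resource_category=ResourceCategory.PEER_SUPPORT,
                firmness=Firmness.SOFT,
                timeframe=Timeframe.UNSPECIFIED,
            )
        )
    # crisis overrides: acute safety or abuse concerns escalate regardless of
    # the aggregated domain severity
    rules.append(
        RecommendationRule(
            rule_id="safety-crisis",
            section="safety",
            min_score=2,
            resource_category=ResourceCategory.URGENT_CRISIS,
            firmness=Firmness.FIRM,
            timeframe=Timeframe.IMMEDIATELY,
        )
    )
    rules.append(
        RecommendationRule(
            rule_id="abuse-crisis",
            section="abuse",
            min_score=3,
            resource_category=ResourceCategory.URGENT_CRISIS,
            firmness=Firmness.FIRM,
            timeframe=Timeframe.IMMEDIATELY,
        )
    )
    # floor: self-directed maintenance resources for everyone
    rules.append(
        RecommendationRule(
            rule_id="maintenance",
            resource_category=ResourceCategory.SELF_DIRECTED,
            firmness=Firmness.SOFT,
            timeframe=Timeframe.UNSPECIFIED,
        )
    )
    return tuple(rules)


def default_instrument() -> InstrumentDefinition:
    """The shipped HEARTSMAP-U definition (10 sections, 4 domains,
    cutoffs 0 / 1-3 / 4-6 / 7-9, default rule table)."""
    return InstrumentDefinition(
        name="HEARTSMAP-U",
        version="1.0",
        sections=_DEFAULT_SECTIONS,
        domain_map=_DEFAULT_DOMAIN_MAP,
        severity_cutoffs=_DEFAULT_CUTOFFS,
        recommendation_rules=_default_rules(),
    )


def validate_instrument(defn: InstrumentDefinition) -> InstrumentDefinition:
    """Return ``defn`` unchanged if all structural invariants hold.

    Pydantic enforces the invariants at construction; this re-runs them so
    definitions assembled by other means (e.g. ``model_construct``) are
    checked too.
    """
    return InstrumentDefinition.model_validate(defn.model_dump())


def validate_assessment(
    rec: AssessmentRecord, defn: InstrumentDefinition
) -> AssessmentRecord:
    """Validate a record against an instrument definition.

    Checks: every declared section is scored (and nothing else is), every
    score is in 0-3 (enforced at construction), and the access flag is
    present exactly for sections scored >= 1.
    """
    declared = set(defn.sections)
    scored = set(rec.section_scores)
    missing = sorted(declared - scored)
    if missing:
        raise InstrumentValidationError(
            f"participant {rec.participant_id!r}: missing section scores {missing}"
        )
    unknown = sorted(scored - declared)
    if unknown:
        raise InstrumentValidationError(
            f"participant {rec.participant_id!r}: unknown sections {unknown}"
        )
    for section in defn.sections:
        score = rec.section_scores[section]
        has_flag = section in rec.access_flags
        if score >= 1 and not has_flag:
            raise InstrumentValidationError(
                f"participant {rec.participant_id!r}: section {section!r} scored "
                f"{score} but has no resource-access answer"
            )
        if score == 0 and has_flag:
            raise InstrumentValidationError(
                f"participant {rec.participant_id!r}: section {section!r} scored 0 "
                "but carries a resource-access answer (prompt only fires for 1-3)"
            )
    return rec
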