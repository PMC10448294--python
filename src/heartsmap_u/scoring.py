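"""Decision-making algorithm: domain aggregation, severity banding and
resource-recommendation triggering.

The algorithm is deterministic and side-effect free: a domain score is the
sum of its 3 mapped section scores (0-9), the severity class is the cutoff
band containing the score, a domain flags "any concern" when its score is
>= 1, and the recommendation rule table is evaluated against the domain
severities and raw section scores.  Duplicate (category, firmness) items
are collapsed keeping the most urgent timeframe, and the result is ordered
by urgency, then a fixed category order, then rule id, so reports are
reproducible byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .instrument import (
    CATEGORY_ORDER,
    AssessmentRecord,
    Firmness,
    InstrumentDefinition,
    InstrumentValidationError,
    RecommendationRule,
    ResourceCategory,
    Severity,
    Timeframe,
)

__all__ = [
    "DomainResult",
    "RecommendationItem",
    "RecommendationSet",
    "AssessmentResult",
    "compute_domain_score",
    "classify_severity",
    "flag_any_concern",
    "trigger_recommendations",
    "score_assessment",
]


@dataclass(frozen=True)
class DomainResult:
    """Aggregated outcome for one domain: score (0-9) and severity band."""

    domain: str
    score: int
    severity: Severity


@dataclass(frozen=True)
class RecommendationItem:
    resource_category: ResourceCategory
    firmness: Firmness
    timeframe: Timeframe
    rule_id: str


@dataclass(frozen=True)
class RecommendationSet:
    """Ordered, de-duplicated recommendations for one assessment.

    ``maintenance_only`` is true exactly when no needs-based item (one that
    is not self-directed) is present — the "self-care and maintaining
    mental well-being only" outcome.
    """

    items: tuple[RecommendationItem, ...]

    @property
    def maintenance_only(self) -> bool:
        return all(
            it.resource_category is ResourceCategory.SELF_DIRECTED for it in self.items
        )

    @property
    def categories(self) -> frozenset[ResourceCategory]:
        return frozenset(it.resource_category for it in self.items)

    def has_firm(self) -> bool:
        return any(it.firmness is Firmness.FIRM for it in self.items)


@dataclass(frozen=True)
class AssessmentResult:
    """Full scoring output for one participant x timepoint."""

    participant_id: str
    timepoint: str
    domain_results: tuple[DomainResult, ...]
    recommendations: RecommendationSet
    accessed_sections: tuple[str, ...] = field(default=())

    def domain(self, name: str) -> DomainResult:
        for dr in self.domain_results:
            if dr.domain == name:
                return dr
        raise KeyError(name)


def compute_domain_score(
    rec: AssessmentRecord, domain: str, defn: InstrumentDefinition
) -> int:
    """Sum of the 3 section scores mapped to ``domain`` (0-9)."""
    try:
        sections = defn.domain_map[domain]
    except KeyError:
        raise InstrumentValidationError(f"unknown domain {domain!r}") from None
    return sum(rec.section_scores[s] for s in sections)


def classify_severity(score: int, defn: InstrumentDefinition) -> Severity:
    """Severity band containing a domain score (total on 0-9)."""
    if not 0 <= score <= 9:
        raise InstrumentValidationError(f"domain score {score} outside 0-9")
    for label, (lo, hi) in defn.severity_cutoffs.items():
        if lo <= score <= hi:
            return label
    raise InstrumentValidationError(f"no severity band covers score {score}")


def flag_any_concern(
    rec: AssessmentRecord, domain: str, defn: InstrumentDefinition
) -> bool:
    """True iff the domain score is >= 1 (the tool's any-concern flag)."""
    return compute_domain_score(rec, domain, defn) >= 1


def _rule_fires(
    rule: RecommendationRule,
    rec: AssessmentRecord,
    severities: dict[str, Severity],
) -> bool:
    if rule.domain is not None and severities[rule.domain] not in rule.severity_in:
        return False
    if rule.section is not None and rec.section_scores[rule.section] < rule.min_score:
        return False
    return True


def trigger_recommendations(
    rec: AssessmentRecord,
    results: list[DomainResult] | tuple[DomainResult, ...],
    defn: InstrumentDefinition,
) -> RecommendationSet:
    """Evaluate the rule table against domain severities and section scores.

    Duplicate (category, firmness) pairs are collapsed keeping the most
    urgent timeframe (and the lexicographically first rule id among the
    most urgent, for reproducibility).  Ordering is urgency rank, then the
    fixed category order, then rule id.
    """
    severities = {dr.domain: dr.severity for dr in results}
    fired = [
        r for r in defn.recommendation_rules if _rule_fires(r, rec, severities)
    ]
    best: dict[tuple[ResourceCategory, Firmness], RecommendationItem] = {}
    for rule in fired:
        key = (rule.resource_category, rule.firmness)
        item = RecommendationItem(
            resource_category=rule.resource_category,
            firmness=rule.firmness,
            timeframe=rule.timeframe,
            rule_id=rule.rule_id,
        )
        cur = best.get(key)
        if (
            cur is None
            or (item.timeframe.urgency_rank, item.rule_id)
            < (cur.timeframe.urgency_rank, cur.rule_id)
        ):
            best[key] = item
    ordered = sorted(
        best.values(),
        key=lambda it: (
            it.timeframe.urgency_rank,
            CATEGORY_ORDER.index(it.resource_category),
            it.rule_id,
        ),
    )
    return RecommendationSet(items=tuple(ordered))


def score_assessment(
    rec: AssessmentRecord, defn: InstrumentDefinition
) -> AssessmentResult:
    """Run the full algorithm: one DomainResult per declared domain, the
    triggered RecommendationSet, and the list of sections where the
    participant reported already accessing resources."""
    domain_results = tuple(
        DomainResult(
            domain=d,
            score=(score := compute_domain_score(rec, d, defn)),
            severity=classify_severity(score, defn),
        )
        for d in defn.domains
    )
    recs = trigger_recommendations(rec, domain_results, defn)
    accessed = tuple(
        s for s in defn.sections if rec.access_flags.get(s, False)
    )
    return AssessmentResult(
        participant_id=rec.participant_id,
        timepoint=rec.timepoint.value,
        domain_results=domain_results,
        recommendations=recs,
        accessed_sections=accessed,
    )
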