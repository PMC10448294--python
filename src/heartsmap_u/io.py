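"""File dialects, report rendering and the help-seeking tabulation.

All CSVs are RFC-4180, UTF-8, with declared headers; schema violations
raise :class:`DialectError` naming the offending line.  Every writer/reader
pair round-trips records field-for-field.  Report tables co-print raw
counts beside estimates and render percentages with round-half-up integer
rounding, so the rounding is always auditable against the counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .instrument import (
    AssessmentRecord,
    ClinicianAssessment,
    InstrumentDefinition,
    ResourceCategory,
    Severity,
    Timeframe,
    Timepoint,
    validate_assessment,
)
from .psychometrics import ConfusionTable, MetricEstimate, MIResult
from .scoring import AssessmentResult, DomainResult, RecommendationSet

__all__ = [
    "DialectError",
    "HelpSeekingRecord",
    "UtilitySummary",
    "summarize_help_seeking",
    "percent",
    "format_estimate",
    "read_assessments_csv",
    "write_assessments_csv",
    "read_assessments_json",
    "write_assessments_json",
    "read_clinician_csv",
    "write_clinician_csv",
    "write_results_json",
    "read_results_json",
    "read_instrument_json",
    "write_instrument_json",
    "read_help_seeking_csv",
    "write_help_seeking_csv",
    "predictive_validity_report",
    "convergent_report",
    "render_validity_table",
    "render_convergent_table",
    "render_mi_table",
    "render_utility_funnel",
    "dataframe_to_markdown",
]

BARRIER_LABELS = (
    "time",
    "cost",
    "cultural_sensitivity",
    "transportation",
    "covid19",
    "service_availability",
    "low_perceived_need",
)


class DialectError(ValueError):
    """A file violates its declared schema; the message names the line."""


# ---------------------------------------------------------------------------
# percent / estimate formatting
# ---------------------------------------------------------------------------


def percent(x: float) -> int:
    """Round a proportion to an integer percent, half away from zero."""
    return int(Decimal(x * 100).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def format_estimate(est: Optional[MetricEstimate]) -> str:
    """``"95 (84-99)"`` style: integer percent with its CI, or ``N/A``."""
    if est is None:
        return "N/A"
    return f"{percent(est.point)} ({percent(est.ci_low)}-{percent(est.ci_high)})"


# ---------------------------------------------------------------------------
# help-seeking (clinical utility)
# ---------------------------------------------------------------------------


class HelpSeekingRecord(BaseModel):
    """One participant's follow-up help-seeking survey.

    The survey branches: participants who already accessed care are not
    asked about attempts or intention, and barriers are only collected
    from those who did not access care.
    """

    model_config = ConfigDict(frozen=True)

    participant_id: str
    received_needs_based_rec: bool
    accessed: bool
    attempted: Optional[bool] = None
    intends_future: Optional[bool] = None
    barriers: frozenset[str] = frozenset()
    barrier_writein: Optional[str] = None

    @model_validator(mode="after")
    def _check(self) -> "HelpSeekingRecord":
        if self.accessed:
            if self.attempted is not None or self.intends_future is not None:
                raise ValueError(
                    f"participant {self.participant_id!r}: accessors are not asked "
                    "about attempts or intention"
                )
            if self.barriers or self.barrier_writein:
                raise ValueError(
                    f"participant {self.participant_id!r}: barriers only collected "
                    "from non-accessors"
                )
        unknown = self.barriers - set(BARRIER_LABELS)
        if unknown:
            raise ValueError(
                f"participant {self.participant_id!r}: unknown barriers {sorted(unknown)} "
                "(write-ins go in barrier_writein)"
            )
        return self


@dataclass(frozen=True)
class UtilitySummary:
    """Funnel counts for participants with a needs-based recommendation."""

    n_needs_based: int
    n_accessed: int
    n_attempted_unsuccessful: int
    n_no_attempt: int
    n_intend_future: int
    barrier_counts: dict[str, int]

    def __post_init__(self) -> None:
        if (
            self.n_accessed + self.n_attempted_unsuccessful + self.n_no_attempt
            != self.n_needs_based
        ):
            raise ValueError("funnel branches must partition the needs-based group")

    def proportion(self, count: int) -> float:
        return count / self.n_needs_based if self.n_needs_based else 0.0

    @property
    def accessed_proportion(self) -> float:
        return self.proportion(self.n_accessed)


def summarize_help_seeking(records: Sequence[HelpSeekingRecord]) -> UtilitySummary:
    """Tabulate the access/attempt/intend funnel over participants who
    received a needs-based (non-maintenance) recommendation.

    Barrier tallies cover non-accessors only, matching the survey
    branching; proportions are computed against the needs-based count.
    """
    needs = [r for r in records if r.received_needs_based_rec]
    accessed = sum(1 for r in needs if r.accessed)
    attempted = sum(1 for r in needs if not r.accessed and r.attempted)
    no_attempt = sum(1 for r in needs if not r.accessed and not r.attempted)
    intend = sum(1 for r in needs if not r.accessed and r.intends_future)
    barriers = {label: 0 for label in BARRIER_LABELS}
    writeins = 0
    for r in needs:
        if r.accessed:
            continue
        for b in r.barriers:
            barriers[b] += 1
        if r.barrier_writein:
            writeins += 1
    barriers["write_in"] = writeins
    return UtilitySummary(
        n_needs_based=len(needs),
        n_accessed=accessed,
        n_attempted_unsuccessful=attempted,
        n_no_attempt=no_attempt,
        n_intend_future=intend,
        barrier_counts=barriers,
    )


# ---------------------------------------------------------------------------
# assessments: long CSV and nested JSON
# ---------------------------------------------------------------------------

_ASSESSMENT_COLUMNS = ["participant_id", "timepoint", "section", "score", "accessed"]


def write_assessments_csv(
    records: Iterable[AssessmentRecord], path: str | Path
) -> None:
    rows = []
    for rec in records:
        for section, score in rec.section_scores.items():
            accessed = ""
            if section in rec.access_flags:
                accessed = "yes" if rec.access_flags[section] else "no"
            rows.append(
                {
                    "participant_id": rec.participant_id,
                    "timepoint": rec.timepoint.value,
                    "section": section,
                    "score": score,
                    "accessed": accessed,
                }
            )
    pd.DataFrame(rows, columns=_ASSESSMENT_COLUMNS).to_csv(path, index=False)


def read_assessments_csv(
    path: str | Path, defn: InstrumentDefinition
) -> list[AssessmentRecord]:
    """Read the long-format dialect and validate every record.

    Errors name the 1-based data line (header is line 1): unknown columns,
    bad score/accessed values, and duplicate (participant, timepoint,
    section) keys are all rejected.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != _ASSESSMENT_COLUMNS:
        raise DialectError(
            f"{path}: expected columns {_ASSESSMENT_COLUMNS}, got {list(df.columns)}"
        )
    acc: dict[tuple[str, str], dict] = {}
    seen: set[tuple[str, str, str]] = set()
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        key = (row.participant_id, row.timepoint, row.section)
        if key in seen:
            raise DialectError(
                f"{path}: line {idx}: duplicate (participant, timepoint, section) {key}"
            )
        seen.add(key)
        try:
            score = int(row.score)
        except ValueError:
            raise DialectError(
                f"{path}: line {idx}: score {row.score!r} is not an integer"
            ) from None
        if row.accessed not in ("", "yes", "no"):
            raise DialectError(
                f"{path}: line {idx}: accessed must be yes/no/empty, got {row.accessed!r}"
            )
        slot = acc.setdefault(
            (row.participant_id, row.timepoint), {"scores": {}, "flags": {}}
        )
        slot["scores"][row.section] = score
        if row.accessed:
            slot["flags"][row.section] = row.accessed == "yes"
    records = []
    for (pid, tp), slot in acc.items():
        rec = AssessmentRecord(
            participant_id=pid,
            timepoint=Timepoint(tp),
            section_scores=slot["scores"],
            access_flags=slot["flags"],
        )
        records.append(validate_assessment(rec, defn))
    return records


def write_assessments_json(
    records: Iterable[AssessmentRecord], path: str | Path
) -> None:
    payload = [
        {
            "participant_id": r.participant_id,
            "timepoint": r.timepoint.value,
            "section_scores": r.section_scores,
            "access_flags": r.access_flags,
            "free_text": r.free_text,
        }
        for r in records
    ]
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True), encoding="utf-8")


def read_assessments_json(
    path: str | Path, defn: InstrumentDefinition
) -> list[AssessmentRecord]:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    seen: set[tuple[str, str]] = set()
    records = []
    for entry in payload:
        key = (entry["participant_id"], entry["timepoint"])
        if key in seen:
            raise DialectError(f"{path}: duplicate (participant, timepoint) {key}")
        seen.add(key)
        rec = AssessmentRecord(
            participant_id=entry["participant_id"],
            timepoint=Timepoint(entry["timepoint"]),
            section_scores=entry["section_scores"],
            access_flags=entry.get("access_flags", {}),
            free_text=entry.get("free_text", {}),
        )
        records.append(validate_assessment(rec, defn))
    return records


# ---------------------------------------------------------------------------
# clinician reference CSV
# ---------------------------------------------------------------------------

_CLINICIAN_COLUMNS = [
    "participant_id",
    "timepoint",
    "psychiatric_concern",
    "psychiatric_severity",
    "concern_areas",
    "psychosocial_concerns",
    "resource_needs",
]


def write_clinician_csv(
    records: Iterable[ClinicianAssessment], path: str | Path
) -> None:
    rows = []
    for rec in records:
        psychosocial = ";".join(
            f"{cat}={'yes' if present else 'no'}"
            for cat, present in sorted(rec.psychosocial_concerns.items())
        )
        needs = ";".join(
            f"{cat.value}@{tf.value}" for cat, tf in sorted(rec.resource_needs)
        )
        rows.append(
            {
                "participant_id": rec.participant_id,
                "timepoint": rec.timepoint.value,
                "psychiatric_concern": "yes" if rec.psychiatric_concern else "no",
                "psychiatric_severity": rec.psychiatric_severity.value,
                "concern_areas": ";".join(sorted(rec.concern_areas)),
                "psychosocial_concerns": psychosocial,
                "resource_needs": needs,
            }
        )
    pd.DataFrame(rows, columns=_CLINICIAN_COLUMNS).to_csv(path, index=False)


def read_clinician_csv(path: str | Path) -> list[ClinicianAssessment]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != _CLINICIAN_COLUMNS:
        raise DialectError(
            f"{path}: expected columns {_CLINICIAN_COLUMNS}, got {list(df.columns)}"
        )
    seen: set[tuple[str, str]] = set()
    records = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        key = (row.participant_id, row.timepoint)
        if key in seen:
            raise DialectError(
                f"{path}: line {idx}: duplicate (participant, timepoint) {key}"
            )
        seen.add(key)
        psychosocial = {}
        if row.psychosocial_concerns:
            for tok in row.psychosocial_concerns.split(";"):
                cat, _, val = tok.partition("=")
                if val not in ("yes", "no"):
                    raise DialectError(
                        f"{path}: line {idx}: bad psychosocial token {tok!r}"
                    )
                psychosocial[cat] = val == "yes"
        needs = set()
        if row.resource_needs:
            for tok in row.resource_needs.split(";"):
                cat, _, tf = tok.partition("@")
                try:
                    needs.add((ResourceCategory(cat), Timeframe(tf)))
                except ValueError:
                    raise DialectError(
                        f"{path}: line {idx}: bad resource-need token {tok!r}"
                    ) from None
        records.append(
            ClinicianAssessment(
                participant_id=row.participant_id,
                timepoint=Timepoint(row.timepoint),
                psychiatric_concern=row.psychiatric_concern == "yes",
                psychiatric_severity=Severity(row.psychiatric_severity),
                concern_areas=frozenset(
                    row.concern_areas.split(";") if row.concern_areas else []
                ),
                psychosocial_concerns=psychosocial,
                resource_needs=frozenset(needs),
            )
        )
    return records


# ---------------------------------------------------------------------------
# scoring results JSON
# ---------------------------------------------------------------------------


def write_results_json(
    results: Iterable[AssessmentResult], path: str | Path
) -> None:
    payload = [
        {
            "participant_id": res.participant_id,
            "timepoint": res.timepoint,
            "domains": [
                {"domain": d.domain, "score": d.score, "severity": d.severity.value}
                for d in res.domain_results
            ],
            "recommendations": [
                {
                    "resource_category": it.resource_category.value,
                    "firmness": it.firmness.value,
                    "timeframe": it.timeframe.value,
                    "rule_id": it.rule_id,
                }
                for it in res.recommendations.items
            ],
            "maintenance_only": res.recommendations.maintenance_only,
            "accessed_sections": list(res.accessed_sections),
        }
        for res in results
    ]
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True), encoding="utf-8")


def read_results_json(path: str | Path) -> list[AssessmentResult]:
    from .instrument import Firmness  # local to avoid a wide import surface
    from .scoring import RecommendationItem

    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    out = []
    for entry in payload:
        domains = tuple(
            DomainResult(
                domain=d["domain"], score=d["score"], severity=Severity(d["severity"])
            )
            for d in entry["domains"]
        )
        items = tuple(
            RecommendationItem(
                resource_category=ResourceCategory(it["resource_category"]),
                firmness=Firmness(it["firmness"]),
                timeframe=Timeframe(it["timeframe"]),
                rule_id=it["rule_id"],
            )
            for it in entry["recommendations"]
        )
        out.append(
            AssessmentResult(
                participant_id=entry["participant_id"],
                timepoint=entry["timepoint"],
                domain_results=domains,
                recommendations=RecommendationSet(items=items),
                accessed_sections=tuple(entry.get("accessed_sections", [])),
            )
        )
    return out


# ---------------------------------------------------------------------------
# instrument definition JSON and help-seeking CSV
# ---------------------------------------------------------------------------


def write_instrument_json(defn: InstrumentDefinition, path: str | Path) -> None:
    Path(path).write_text(defn.model_dump_json(indent=2), encoding="utf-8")


def read_instrument_json(path: str | Path) -> InstrumentDefinition:
    """Parse and schema-validate an instrument definition config file."""
    return InstrumentDefinition.model_validate_json(
        Path(path).read_text(encoding="utf-8")
    )


_HELP_SEEKING_COLUMNS = [
    "participant_id",
    "received_needs_based_rec",
    "accessed",
    "attempted",
    "intends_future",
    "barriers",
    "barrier_writein",
]


def write_help_seeking_csv(
    records: Iterable[HelpSeekingRecord], path: str | Path
) -> None:
    def yn(v: Optional[bool]) -> str:
        return "" if v is None else ("yes" if v else "no")

    rows = [
        {
            "participant_id": r.participant_id,
            "received_needs_based_rec": yn(r.received_needs_based_rec),
            "accessed": yn(r.accessed),
            "attempted": yn(r.attempted),
            "intends_future": yn(r.intends_future),
            "barriers": ";".join(sorted(r.barriers)),
            "barrier_writein": r.barrier_writein or "",
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_HELP_SEEKING_COLUMNS).to_csv(path, index=False)


def read_help_seeking_csv(path: str | Path) -> list[HelpSeekingRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != _HELP_SEEKING_COLUMNS:
        raise DialectError(
            f"{path}: expected columns {_HELP_SEEKING_COLUMNS}, got {list(df.columns)}"
        )

    def parse(v: str, line: int, field: str) -> Optional[bool]:
        if v == "":
            return None
        if v in ("yes", "no"):
            return v == "yes"
        raise DialectError(f"{path}: line {line}: {field} must be yes/no/empty, got {v!r}")

    records = []
    seen: set[str] = set()
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        if row.participant_id in seen:
            raise DialectError(
                f"{path}: line {idx}: duplicate participant {row.participant_id!r}"
            )
        seen.add(row.participant_id)
        records.append(
            HelpSeekingRecord(
                participant_id=row.participant_id,
                received_needs_based_rec=parse(row.received_needs_based_rec, idx, "received_needs_based_rec"),
                accessed=parse(row.accessed, idx, "accessed"),
                attempted=parse(row.attempted, idx, "attempted"),
                intends_future=parse(row.intends_future, idx, "intends_future"),
                barriers=frozenset(row.barriers.split(";")) if row.barriers else frozenset(),
                barrier_writein=row.barrier_writein or None,
            )
        )
    return records


# ---------------------------------------------------------------------------
# report rendering
# ---------------------------------------------------------------------------


def render_validity_table(
    rows: Sequence[
        tuple[str, ConfusionTable, dict[str, Optional[MetricEstimate]], Optional[MetricEstimate]]
    ],
) -> pd.DataFrame:
    """Predictive-validity layout: label, sensitivity/specificity/adjusted
    specificity as ``pct (lo-hi)`` strings, raw TP/FN/FP/TN counts."""
    out = []
    for label, ct, metrics, adjusted in rows:
        out.append(
            {
                "label": label,
                "sensitivity": format_estimate(metrics.get("sensitivity")),
                "specificity": format_estimate(metrics.get("specificity")),
                "adjusted_specificity": format_estimate(adjusted),
                "tp": ct.tp,
                "fn": ct.fn,
                "fp": ct.fp,
                "tn": ct.tn,
            }
        )
    return pd.DataFrame(
        out,
        columns=[
            "label",
            "sensitivity",
            "specificity",
            "adjusted_specificity",
            "tp",
            "fn",
            "fp",
            "tn",
        ],
    )


def render_convergent_table(
    rows: Sequence[tuple[str, str, float, tuple[float, float], int]],
) -> pd.DataFrame:
    """Correlation layout: (tool scale, comparator scale, rho, CI, n)."""
    return pd.DataFrame(
        [
            {
                "tool_scale": a,
                "comparator_scale": b,
                "rho": round(rho, 2),
                "ci_low": round(ci[0], 2),
                "ci_high": round(ci[1], 2),
                "n": n,
            }
            for a, b, rho, ci, n in rows
        ],
        columns=["tool_scale", "comparator_scale", "rho", "ci_low", "ci_high", "n"],
    )


def render_mi_table(rows: Sequence[tuple[str, str, MIResult]]) -> pd.DataFrame:
    """Agreement layout: I_agreement, I_disagreement, I_total (bits), the
    G statistic with df, p, and the verdict."""
    return pd.DataFrame(
        [
            {
                "tool_scale": a,
                "comparator_scale": b,
                "i_agreement": round(res.i_agreement, 2),
                "i_disagreement": round(res.i_disagreement, 2),
                "i_total": round(res.i_total, 2),
                "g_stat": round(res.g_stat, 2),
                "df": res.df,
                "p_value": "N/A" if res.p_value is None else f"{res.p_value:.3g}",
                "verdict": res.verdict,
            }
            for a, b, res in rows
        ],
        columns=[
            "tool_scale",
            "comparator_scale",
            "i_agreement",
            "i_disagreement",
            "i_total",
            "g_stat",
            "df",
            "p_value",
            "verdict",
        ],
    )


def render_utility_funnel(summary: UtilitySummary) -> pd.DataFrame:
    """Funnel counts with explicit denominators, then barrier tallies."""
    n = summary.n_needs_based
    rows = [
        ("needs_based_recommendation", n, n, 100),
        ("accessed", summary.n_accessed, n, percent(summary.proportion(summary.n_accessed))),
        (
            "attempted_unsuccessful",
            summary.n_attempted_unsuccessful,
            n,
            percent(summary.proportion(summary.n_attempted_unsuccessful)),
        ),
        ("no_attempt", summary.n_no_attempt, n, percent(summary.proportion(summary.n_no_attempt))),
        ("intend_future", summary.n_intend_future, n, percent(summary.proportion(summary.n_intend_future))),
    ]
    rows += [
        (f"barrier:{label}", count, n, percent(summary.proportion(count)))
        for label, count in sorted(summary.barrier_counts.items())
    ]
    return pd.DataFrame(rows, columns=["stage", "count", "denominator", "pct"])


def predictive_validity_report(
    results: Sequence[AssessmentResult],
    clinician: Sequence[ClinicianAssessment],
    assessments: Optional[Sequence[AssessmentRecord]] = None,
    level: float = 0.95,
) -> dict[str, pd.DataFrame]:
    """All predictive-validity tables for paired tool/clinician records.

    Produces the any-concern table (per timepoint, with adjusted
    specificity), the moderate-or-severe stratified table, the
    resource-need table (baseline), and — when the raw assessments are
    supplied — the per-section psychosocial table.  Participants missing
    from either side of a pairing are excluded listwise per comparison.
    """
    from .psychometrics import (
        adjusted_specificity,
        build_confusion,
        classification_metrics,
        resource_metrics,
        severity_stratified_metrics,
    )

    res_ix = {(r.participant_id, r.timepoint): r for r in results}
    clin_ix = {(c.participant_id, c.timepoint.value): c for c in clinician}
    timepoints = sorted(
        {tp for _, tp in res_ix} & {tp for _, tp in clin_ix},
        key=lambda tp: tp != Timepoint.BASELINE.value,
    )
    any_rows, strat_rows = [], []
    for tp in timepoints:
        keys = sorted(k for k in res_ix if k[1] == tp and k in clin_ix)
        tool_sev = [res_ix[k].domain("psychiatry").severity for k in keys]
        tool_flag = [int(res_ix[k].domain("psychiatry").score >= 1) for k in keys]
        ref_flag = [int(clin_ix[k].psychiatric_concern) for k in keys]
        ref_sev = [clin_ix[k].psychiatric_severity for k in keys]
        ct = build_confusion(tool_flag, ref_flag)
        metrics = classification_metrics(ct, level)
        adj = adjusted_specificity(tool_sev, ref_flag, level) if ct.n_negative else None
        any_rows.append((f"{tp} (n={len(keys)})", ct, metrics, adj))
        strat = severity_stratified_metrics(tool_sev, ref_sev, level)
        strat_rows.append(
            (
                f"{tp} (n={strat.table.n})",
                strat.table,
                {"sensitivity": strat.sensitivity, "specificity": None},
                strat.adjusted_specificity,
            )
        )
    out = {
        "any_concern": render_validity_table(any_rows),
        "stratified": render_validity_table(strat_rows),
    }
    base_keys = sorted(
        k for k in res_ix if k[1] == Timepoint.BASELINE.value and k in clin_ix
    )
    if base_keys:
        tool_recs = [res_ix[k].recommendations for k in base_keys]
        ref_needs = [
            {cat for cat, _ in clin_ix[k].resource_needs} for k in base_keys
        ]
        rows = []
        for category in ResourceCategory:
            ct, metrics = resource_metrics(tool_recs, ref_needs, category, level)
            rows.append((category.value, ct, metrics, None))
        out["resources"] = render_validity_table(rows)
    if assessments is not None:
        from .instrument import PSYCHOSOCIAL_SECTION_MAP

        rec_ix = {(a.participant_id, a.timepoint.value): a for a in assessments}
        for tp in timepoints:
            keys = sorted(k for k in rec_ix if k[1] == tp and k in clin_ix)
            rows = []
            for category, section in PSYCHOSOCIAL_SECTION_MAP.items():
                tool = [int(rec_ix[k].section_scores[section] >= 1) for k in keys]
                ref = [
                    int(clin_ix[k].psychosocial_concerns.get(category, False))
                    for k in keys
                ]
                ct = build_confusion(tool, ref)
                rows.append((category, ct, classification_metrics(ct, level), None))
            out[f"psychosocial_{tp}"] = render_validity_table(rows)
    return out


def convergent_report(
    results: Sequence[AssessmentResult],
    comparator_scores: dict[str, pd.DataFrame],
    correlation_pairs: Sequence[tuple[str, str]],
    agreement_pairs: Sequence[tuple[str, str, int]] = (),
    level: float = 0.95,
) -> dict[str, pd.DataFrame]:
    """Convergent-validity tables: Spearman correlations for
    (tool domain, comparator) pairs and MI agreement rows for
    (tool domain, comparator, n_bands) triples.

    Comparator composites are banded into ``n_bands`` ordinal classes by
    quantile cutpoints; agreement cells use the default proportional
    ordinal mapping.
    """
    import numpy as np

    from .psychometrics import (
        agreement_table_from_vectors,
        mi_agreement,
        spearman_rho,
    )

    base = [r for r in results if r.timepoint == Timepoint.BASELINE.value]
    corr_rows, mi_rows = [], []
    for domain, comparator in correlation_pairs:
        comp = comparator_scores[comparator].set_index("participant_id")["composite"]
        keys = [r.participant_id for r in base if r.participant_id in comp.index]
        tool = [r.domain(domain).score for r in base if r.participant_id in comp.index]
        rho, ci = spearman_rho(tool, comp.loc[keys].to_numpy(), level)
        corr_rows.append((domain, comparator, rho, ci, len(keys)))
    for domain, comparator, n_bands in agreement_pairs:
        comp = comparator_scores[comparator].set_index("participant_id")["composite"]
        keys = [r.participant_id for r in base if r.participant_id in comp.index]
        sev = [
            r.domain(domain).severity.rank
            for r in base
            if r.participant_id in comp.index
        ]
        values = comp.loc[keys].to_numpy(dtype=float)
        cuts = np.quantile(values, np.arange(1, n_bands) / n_bands)
        bands = np.searchsorted(cuts, values, side="right")
        table = agreement_table_from_vectors(
            sev,
            bands.tolist(),
            row_labels=("none", "mild", "moderate", "severe"),
            col_labels=tuple(f"band_{b}" for b in range(n_bands)),
        )
        mi_rows.append((domain, comparator, mi_agreement(table)))
    return {
        "correlations": render_convergent_table(corr_rows),
        "mi_agreement": render_mi_table(mi_rows),
    }


def dataframe_to_markdown(df: pd.DataFrame) -> str:
    """Minimal GitHub-style markdown table (deterministic, no wrapping)."""
    cols = [str(c) for c in df.columns]
    cells = [[str(v) for v in row] for row in df.itertuples(index=False)]
    widths = [
        max(len(cols[j]), *(len(r[j]) for r in cells)) if cells else len(cols[j])
        for j in range(len(cols))
    ]
    def fmt(row: list[str]) -> str:
        return "| " + " | ".join(v.ljust(w) for v, w in zip(row, widths)) + " |"
    lines = [fmt(cols), "| " + " | ".join("-" * w for w in widths) + " |"]
    lines += [fmt(r) for r in cells]
    return "\n".join(lines) + "\n"
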