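"""Synthetic cohort generation for end-to-end pipeline testing.

Real screening-validation data are individual-level health records and are
not distributable, so every pipeline stage here is exercised on synthetic
cohorts drawn from an explicit latent-trait model:

* a 4-dimensional Gaussian copula over the domain traits (Social,
  Function, Psychiatry, Student Health) captures cross-domain correlation
  of psychosocial severity;
* each section's latent is a loading on its primary domain trait plus
  idiosyncratic noise, discretized to the 0-3 ordinal score through
  per-section thresholds (the shipped defaults match a realistic
  mild-skewed student score distribution);
* the clinician reference applies a detection sensitivity / false-alarm
  model to the same latents, plus a severity-confusion matrix and noisy
  psychosocial/resource-need labels;
* comparator scales are generic Likert item grids loading linearly on a
  domain trait;
* follow-up scores evolve from baseline through per-section 4x4 Markov
  transition rows.

Because the clinician flag is conditionally independent noise on the
tool's (deterministic) any-concern state, the tool-vs-clinician
sensitivity and specificity have closed forms given the tool-positive
prevalence, which is itself computable by 1-d Gauss-Hermite quadrature
over the shared Psychiatry trait.  ``calibrate_clinician_model`` inverts
those forms so a config can target a chosen operating point exactly —
the basis of the parameter-recovery experiments.

A single seeded :class:`numpy.random.Generator` is threaded through all
draws; no global random state is touched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import stats

from .instrument import (
    PSYCHOSOCIAL_SECTION_MAP,
    AssessmentRecord,
    ClinicianAssessment,
    InstrumentDefinition,
    ResourceCategory,
    Severity,
    Timeframe,
    Timepoint,
    default_instrument,
    validate_assessment,
)
from .psychometrics import build_confusion, clopper_pearson, spearman_rho
from .scoring import score_assessment

__all__ = [
    "ClinicianModel",
    "ComparatorModel",
    "CohortConfig",
    "SyntheticCohort",
    "default_config",
    "thresholds_from_marginals",
    "tool_positive_prevalence",
    "calibrate_clinician_model",
    "operating_point",
    "generate_cohort",
    "apply_followup_transition",
    "recovery_experiment",
    "RecoveryResult",
]

DOMAIN_ORDER = ("social", "function", "psychiatry", "student_health")

_SEVERITY_LEVELS = (Severity.NONE, Severity.MILD, Severity.MODERATE, Severity.SEVERE)

# clinician resource needs attached to each severity level (before noise)
_NEEDS_BY_SEVERITY: dict[Severity, tuple[tuple[ResourceCategory, Timeframe], ...]] = {
    Severity.NONE: (),
    Severity.MILD: (
        (ResourceCategory.PEER_SUPPORT, Timeframe.AFTER_1WK),
        (ResourceCategory.SELF_DIRECTED, Timeframe.AFTER_1WK),
    ),
    Severity.MODERATE: (
        (ResourceCategory.COUNSELING, Timeframe.WITHIN_1WK),
        (ResourceCategory.PRIMARY_CARE, Timeframe.WITHIN_1WK),
        (ResourceCategory.SELF_DIRECTED, Timeframe.AFTER_1WK),
    ),
    Severity.SEVERE: (
        (ResourceCategory.URGENT_CRISIS, Timeframe.IMMEDIATELY),
        (ResourceCategory.PSYCHIATRIC_CONSULTATION, Timeframe.WITHIN_72H),
        (ResourceCategory.COUNSELING, Timeframe.WITHIN_1WK),
    ),
}

_CATEGORY_DEFAULT_TIMEFRAME: dict[ResourceCategory, Timeframe] = {
    ResourceCategory.URGENT_CRISIS: Timeframe.IMMEDIATELY,
    ResourceCategory.PSYCHIATRIC_CONSULTATION: Timeframe.WITHIN_72H,
    ResourceCategory.COUNSELING: Timeframe.WITHIN_1WK,
    ResourceCategory.PRIMARY_CARE: Timeframe.WITHIN_1WK,
    ResourceCategory.PEER_SUPPORT: Timeframe.AFTER_1WK,
    ResourceCategory.COMMUNITY_SERVICE: Timeframe.AFTER_1WK,
    ResourceCategory.SELF_DIRECTED: Timeframe.AFTER_1WK,
}



class ClinicianModel(BaseModel):
    """Noise model for the clinician reference standard.

    ``pi_sens`` / ``pi_fa`` are the probabilities that the clinician flags
    a psychiatric concern given the participant's true (tool-derived)
    concern state is present / absent.  ``severity_confusion`` is a 4x4
    row-stochastic matrix from true severity class to clinician-rated
    class (rows ordered none, mild, moderate, severe); among flagged
    participants the draw is renormalized over mild-severe.
    """

    model_config = ConfigDict(frozen=True)

    pi_sens: float = Field(ge=0.0, le=1.0)
    pi_fa: float = Field(ge=0.0, le=1.0)
    severity_confusion: tuple[tuple[float, float, float, float], ...]
    psychosocial_miss: float = Field(default=0.10, ge=0.0, le=1.0)
    psychosocial_fa: float = Field(default=0.05, ge=0.0, le=1.0)
    needs_noise: float = Field(default=0.05, ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _check(self) -> "ClinicianModel":
        if len(self.severity_confusion) != 4:
            raise ValueError("severity_confusion must have 4 rows")
        for i, row in enumerate(self.severity_confusion):
            if abs(sum(row) - 1.0) > 1e-9 or any(p < 0 for p in row):
                raise ValueError(f"severity_confusion row {i} is not a distribution")
        return self


class ComparatorModel(BaseModel):
    """A generic comparator Likert scale loading on one domain trait.

    Items are ``loading * trait + noise`` discretized to ``0..likert_max``
    through equiprobable normal quantiles; the composite is the item sum,
    keyed so that higher means more concern (matching the tool's polarity).
    """

    model_config = ConfigDict(frozen=True)

    trait: str
    loading: float = Field(gt=-1.0, lt=1.0)
    n_items: int = Field(ge=1)
    likert_max: int = Field(default=4, ge=1)

    @model_validator(mode="after")
    def _check(self) -> "ComparatorModel":
        if self.trait not in DOMAIN_ORDER:
            raise ValueError(f"unknown trait {self.trait!r}")
        return self


class CohortConfig(BaseModel):
    """Full specification of a synthetic cohort.

    ``latent_corr`` is the 4x4 correlation matrix of the domain traits in
    :data:`DOMAIN_ORDER`.  ``section_loading`` maps each section to
    (primary domain, loading); the section latent is standard normal
    marginally, so ``section_thresholds`` (3 strictly increasing cutpoints,
    +inf allowed in the tail) determine the marginal score distribution
    directly.  ``followup_transition`` holds per-section 4x4 row-stochastic
    score-transition matrices.
    """

    model_config = ConfigDict(frozen=True, arbitrary_types_allowed=True)

    n: int = Field(ge=1)
    seed: int = 0
    latent_corr: tuple[tuple[float, ...], ...]
    section_loading: dict[str, tuple[str, float]]
    section_thresholds: dict[str, tuple[float, float, float]]
    clinician_model: ClinicianModel
    comparator_models: dict[str, ComparatorModel] = Field(default_factory=dict)
    followup_transition: dict[str, tuple[tuple[float, ...], ...]] = Field(
        default_factory=dict
    )
    p_access: float = Field(default=0.35, ge=0.0, le=1.0)
    strata: Optional[dict[str, float]] = None

    @model_validator(mode="after")
    def _check(self) -> "CohortConfig":
        corr = np.asarray(self.latent_corr, dtype=float)
        if corr.shape != (4, 4):
            raise ValueError("latent_corr must be 4x4")
        if not np.allclose(corr, corr.T):
            raise ValueError("latent_corr must be symmetric")
        if not np.allclose(np.diag(corr), 1.0):
            raise ValueError("latent_corr must have unit diagonal")
        eigmin = np.linalg.eigvalsh(corr).min()
        if eigmin < -1e-10:
            raise ValueError(f"latent_corr is not positive semi-definite (min eig {eigmin:.3g})")
        for section, (domain, loading) in self.section_loading.items():
            if domain not in DOMAIN_ORDER:
                raise ValueError(f"section {section!r} loads on unknown domain {domain!r}")
            if not -1.0 < loading < 1.0:
                raise ValueError(f"section {section!r} loading {loading} outside (-1, 1)")
        if set(self.section_thresholds) != set(self.section_loading):
            raise ValueError("section_thresholds and section_loading must cover the same sections")
        for section, thr in self.section_thresholds.items():
            finite_ok = all(
                thr[i] < thr[i + 1] or (math.isinf(thr[i]) and math.isinf(thr[i + 1]))
                for i in range(2)
            )
            strictly = all(thr[i] < thr[i + 1] for i in range(2))
            if not strictly and not (finite_ok and math.isinf(thr[-1])):
                raise ValueError(f"section {section!r} thresholds {thr} not strictly increasing")
        for section, mat in self.followup_transition.items():
            m = np.asarray(mat, dtype=float)
            if m.shape != (4, 4) or (m < 0).any() or not np.allclose(m.sum(axis=1), 1.0):
                raise ValueError(f"follow-up transition for {section!r} is not row-stochastic 4x4")
        if self.strata is not None:
            total = sum(self.strata.values())
            if abs(total - 1.0) > 1e-9 or any(p < 0 for p in self.strata.values()):
                raise ValueError("strata proportions must be non-negative and sum to 1")
        return self

    @property
    def sections(self) -> tuple[str, ...]:
        return tuple(self.section_loading)


@dataclass(frozen=True)
class SyntheticCohort:
    """A generated cohort plus its provenance (config and seed)."""

    assessments: tuple[AssessmentRecord, ...]
    clinician: tuple[ClinicianAssessment, ...]
    comparator_scores: dict[str, pd.DataFrame]
    config: CohortConfig
    strata_assignment: dict[str, str] = field(default_factory=dict)

    def records(self, timepoint: Timepoint) -> list[AssessmentRecord]:
        return [r for r in self.assessments if r.timepoint is timepoint]

    def clinician_records(self, timepoint: Timepoint) -> list[ClinicianAssessment]:
        return [r for r in self.clinician if r.timepoint is timepoint]


# ---------------------------------------------------------------------------
# defaults and calibration
# ---------------------------------------------------------------------------


def thresholds_from_marginals(probs: Sequence[float]) -> tuple[float, float, float]:
    """Normal-quantile cutpoints reproducing a 4-category score marginal.

    ``probs`` are the target probabilities of scores 0..3 (normalized to
    sum 1); the returned cutpoints are the standard-normal quantiles of
    the cumulative probabilities, with +inf where a tail category has
    probability 0.
    """
    p = np.asarray(probs, dtype=float)
    if p.shape != (4,) or (p < 0).any() or p.sum() <= 0:
        raise ValueError(f"need 4 non-negative probabilities, got {probs!r}")
    p = p / p.sum()
    cum = np.cumsum(p)[:3]
    thr = tuple(float(stats.norm.ppf(min(c, 1.0))) for c in cum)
    return thr  # type: ignore[return-value]


# Realistic mild-skewed baseline marginals for a universal student
# screening sample: most sections concentrate on scores 0-1 with few
# severe responses.
_DEFAULT_MARGINALS: dict[str, tuple[float, float, float, float]] = {
    "housing": (0.79, 0.17, 0.03, 0.01),
    "education": (0.40, 0.40, 0.18, 0.02),
    "relationships": (0.43, 0.45, 0.10, 0.02),
    "thoughts_anxiety": (0.30, 0.56, 0.17, 0.02),
    "substances": (0.40, 0.55, 0.05, 0.00),
    "safety": (0.78, 0.18, 0.04, 0.00),
    "sexual_wellness": (0.78, 0.09, 0.10, 0.03),
    "mood": (0.31, 0.51, 0.13, 0.05),
    "abuse": (0.55, 0.29, 0.16, 0.00),
    "professionals": (0.59, 0.25, 0.11, 0.05),
}

_DEFAULT_SECTION_LOADING: dict[str, tuple[str, float]] = {
    "housing": ("social", 0.7),
    "substances": ("social", 0.7),
    "abuse": ("social", 0.7),
    "relationships": ("function", 0.7),
    "sexual_wellness": ("function", 0.7),
    "mood": ("psychiatry", 0.7),
    "thoughts_anxiety": ("psychiatry", 0.7),
    "safety": ("psychiatry", 0.7),
    "education": ("student_health", 0.7),
    "professionals": ("student_health", 0.7),
}

# cross-domain trait correlations in the moderate range seen for
# psychosocial constructs
_DEFAULT_LATENT_CORR = (
    (1.00, 0.35, 0.35, 0.30),
    (0.35, 1.00, 0.45, 0.40),
    (0.35, 0.45, 1.00, 0.35),
    (0.30, 0.40, 0.35, 1.00),
)

_DEFAULT_SEVERITY_CONFUSION = (
    (1.00, 0.00, 0.00, 0.00),
    (0.00, 0.85, 0.15, 0.00),
    (0.00, 0.25, 0.60, 0.15),
    (0.00, 0.05, 0.35, 0.60),
)

# mild mean-reversion over 3 months: most scores stay put or drift one step
_DEFAULT_TRANSITION = (
    (0.85, 0.13, 0.02, 0.00),
    (0.25, 0.60, 0.13, 0.02),
    (0.10, 0.30, 0.50, 0.10),
    (0.05, 0.20, 0.35, 0.40),
)

_DEFAULT_COMPARATORS: dict[str, ComparatorModel] = {
    "hrqol_emotional": ComparatorModel(trait="psychiatry", loading=0.75, n_items=4, likert_max=4),
    "hrqol_school": ComparatorModel(trait="function", loading=0.70, n_items=3, likert_max=4),
    "wellbeing_total": ComparatorModel(trait="psychiatry", loading=0.65, n_items=14, likert_max=5),
    "depression": ComparatorModel(trait="psychiatry", loading=0.70, n_items=9, likert_max=3),
}


def tool_positive_prevalence(config: CohortConfig) -> float:
    """P(Psychiatry any-concern flag fires) under the config's latent model.

    The flag fires unless all psychiatry-loading sections score 0, i.e.
    all their latents fall below their first cutpoints.  Conditional on
    the shared trait t the latents are independent, so the orthant
    probability is a 1-d integral evaluated by Gauss-Hermite quadrature.
    """
    psych_sections = [
        s for s, (d, _) in config.section_loading.items() if d == "psychiatry"
    ]
    if not psych_sections:
        raise ValueError("config has no psychiatry-loading sections")
    lam = np.array([config.section_loading[s][1] for s in psych_sections])
    tau1 = np.array([config.section_thresholds[s][0] for s in psych_sections])
    nodes, weights = np.polynomial.hermite_e.hermegauss(80)
    # t ~ N(0,1): integrate prod_i Phi((tau_i - lam_i t)/sqrt(1-lam_i^2))
    z = (tau1[None, :] - lam[None, :] * nodes[:, None]) / np.sqrt(1.0 - lam**2)[None, :]
    inner = stats.norm.cdf(z).prod(axis=1)
    p_all_zero = float((weights * inner).sum() / math.sqrt(2.0 * math.pi))
    return 1.0 - p_all_zero


def calibrate_clinician_model(
    prevalence: float,
    target_sensitivity: float,
    target_specificity: float,
    **kwargs,
) -> ClinicianModel:
    """Invert the tool-vs-clinician operating point for (pi_sens, pi_fa).

    With the clinician flag conditionally independent given the true state
    S (which the tool reproduces exactly), sensitivity and specificity of
    the tool against the clinician are determined by prevalence p = P(S=1)
    and the two noise rates; this solves the 2x2 system so a generated
    cohort hits the targets in expectation.  Raises if the target is
    infeasible at that prevalence.
    """
    p = prevalence
    se, sp = target_sensitivity, target_specificity
    if not (0 < p < 1 and 0 < se <= 1 and 0 < sp <= 1):
        raise ValueError("prevalence and targets must lie in (0, 1]")
    k = (1.0 - se) / se
    m = (1.0 - sp) / sp
    denom = 1.0 - k * m
    if denom <= 0:
        raise ValueError("targets infeasible: 1 - (1-se)(1-sp)/(se*sp) <= 0")
    d = (1.0 - p - k * p) / denom  # P(clinician-, tool-)
    c = d * m  # P(clinician-, tool+)
    pi_fa = 1.0 - d / (1.0 - p)
    pi_sens = (p - c) / p
    for name, v in (("pi_sens", pi_sens), ("pi_fa", pi_fa)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(
                f"targets (se={se}, sp={sp}) infeasible at prevalence {p:.3f}: "
                f"{name}={v:.3f} outside [0, 1]"
            )
    kwargs.setdefault("severity_confusion", _DEFAULT_SEVERITY_CONFUSION)
    return ClinicianModel(pi_sens=pi_sens, pi_fa=pi_fa, **kwargs)


def operating_point(config: CohortConfig) -> tuple[float, float]:
    """Analytic tool-vs-clinician (sensitivity, specificity) implied by a
    config — the targets the recovery experiment measures against."""
    p = tool_positive_prevalence(config)
    cm = config.clinician_model
    a = cm.pi_sens * p
    b = cm.pi_fa * (1.0 - p)
    c = (1.0 - cm.pi_sens) * p
    d = (1.0 - cm.pi_fa) * (1.0 - p)
    return a / (a + b), d / (c + d)


def default_config(
    n: int = 100,
    seed: int = 0,
    target_sensitivity: float = 0.95,
    target_specificity: float = 0.25,
) -> CohortConfig:
    """The shipped cohort configuration.

    Marginals, correlations and comparator loadings emulate a universal
    student-screening sample (mild-skewed scores, moderate cross-domain
    correlation, clinician reference agreeing strongly on presence but
    coarsely on severity); the clinician noise rates are calibrated so the
    tool-vs-clinician operating point matches the targets.
    """
    thresholds = {
        s: thresholds_from_marginals(m) for s, m in _DEFAULT_MARGINALS.items()
    }
    partial = CohortConfig(
        n=n,
        seed=seed,
        latent_corr=_DEFAULT_LATENT_CORR,
        section_loading=_DEFAULT_SECTION_LOADING,
        section_thresholds=thresholds,
        clinician_model=ClinicianModel(
            pi_sens=1.0, pi_fa=0.0, severity_confusion=_DEFAULT_SEVERITY_CONFUSION
        ),
        comparator_models=_DEFAULT_COMPARATORS,
        followup_transition={s: _DEFAULT_TRANSITION for s in _DEFAULT_SECTION_LOADING},
    )
    prevalence = tool_positive_prevalence(partial)
    clinician = calibrate_clinician_model(
        prevalence, target_sensitivity, target_specificity
    )
    return partial.model_copy(update={"clinician_model": clinician})


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _draw_section_scores(
    config: CohortConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """(n x n_sections integer score matrix, n x 4 trait draws)."""
    corr = np.asarray(config.latent_corr)
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(4))
    traits = rng.standard_normal((config.n, 4)) @ chol.T
    scores = np.empty((config.n, len(config.sections)), dtype=int)
    for j, section in enumerate(config.sections):
        domain, lam = config.section_loading[section]
        t = traits[:, DOMAIN_ORDER.index(domain)]
        latent = lam * t + math.sqrt(1.0 - lam**2) * rng.standard_normal(config.n)
        thr = np.asarray(config.section_thresholds[section])
        scores[:, j] = np.searchsorted(thr, latent, side="right")
    return scores, traits


def _scores_to_records(
    scores: np.ndarray,
    config: CohortConfig,
    timepoint: Timepoint,
    rng: np.random.Generator,
) -> list[AssessmentRecord]:
    records = []
    access_draw = rng.random(scores.shape) < config.p_access
    for i in range(scores.shape[0]):
        section_scores = {
            s: int(scores[i, j]) for j, s in enumerate(config.sections)
        }
        flags = {
            s: bool(access_draw[i, j])
            for j, s in enumerate(config.sections)
            if scores[i, j] >= 1
        }
        records.append(
            AssessmentRecord(
                participant_id=f"P{i:05d}",
                timepoint=timepoint,
                section_scores=section_scores,
                access_flags=flags,
            )
        )
    return records


def _true_severity(psych_score: int) -> Severity:
    if psych_score == 0:
        return Severity.NONE
    if psych_score <= 3:
        return Severity.MILD
    if psych_score <= 6:
        return Severity.MODERATE
    return Severity.SEVERE


def _draw_clinician(
    records: list[AssessmentRecord],
    config: CohortConfig,
    rng: np.random.Generator,
) -> list[ClinicianAssessment]:
    cm = config.clinician_model
    confusion = np.asarray(cm.severity_confusion)
    psych_sections = [s for s, (d, _) in config.section_loading.items() if d == "psychiatry"]
    out = []
    for rec in records:
        psych_score = sum(rec.section_scores[s] for s in psych_sections)
        true_state = psych_score >= 1
        flagged = rng.random() < (cm.pi_sens if true_state else cm.pi_fa)
        if flagged:
            row = confusion[_SEVERITY_LEVELS.index(_true_severity(psych_score))].copy()
            row[0] = 0.0  # a flagged participant is rated at least mild
            row = row / row.sum() if row.sum() > 0 else np.array([0.0, 1.0, 0.0, 0.0])
            severity = _SEVERITY_LEVELS[rng.choice(4, p=row)]
        else:
            severity = Severity.NONE
        psychosocial = {}
        for category, section in PSYCHOSOCIAL_SECTION_MAP.items():
            present = rec.section_scores[section] >= 1
            if present:
                present = rng.random() >= cm.psychosocial_miss
            else:
                present = rng.random() < cm.psychosocial_fa
            psychosocial[category] = bool(present)
        needs = {cat: tf for cat, tf in _NEEDS_BY_SEVERITY[severity]}
        for cat in ResourceCategory:
            if rng.random() < cm.needs_noise:
                if cat in needs:
                    del needs[cat]
                else:
                    needs[cat] = _CATEGORY_DEFAULT_TIMEFRAME[cat]
        out.append(
            ClinicianAssessment(
                participant_id=rec.participant_id,
                timepoint=rec.timepoint,
                psychiatric_concern=flagged,
                psychiatric_severity=severity,
                psychosocial_concerns=psychosocial,
                resource_needs=frozenset(needs.items()),
            )
        )
    return out


def _draw_comparators(
    traits: np.ndarray,
    ids: list[str],
    config: CohortConfig,
    rng: np.random.Generator,
) -> dict[str, pd.DataFrame]:
    out: dict[str, pd.DataFrame] = {}
    for name, model in config.comparator_models.items():
        t = traits[:, DOMAIN_ORDER.index(model.trait)]
        lam = model.loading
        y = lam * t[:, None] + math.sqrt(1.0 - lam**2) * rng.standard_normal(
            (len(ids), model.n_items)
        )
        # equiprobable normal quantile bins over 0..likert_max
        levels = model.likert_max + 1
        cuts = stats.norm.ppf(np.arange(1, levels) / levels)
        items = np.searchsorted(cuts, y, side="right")
        df = pd.DataFrame(
            items, columns=[f"item_{k + 1}" for k in range(model.n_items)]
        )
        df.insert(0, "participant_id", ids)
        df["composite"] = items.sum(axis=1)
        out[name] = df
    return out


def apply_followup_transition(
    baseline_scores: np.ndarray,
    config: CohortConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw follow-up scores from the per-section transition rows
    conditioned on the baseline scores."""
    if not config.followup_transition:
        raise ValueError("config declares no follow-up transition matrices")
    followup = np.empty_like(baseline_scores)
    for j, section in enumerate(config.sections):
        mat = np.asarray(config.followup_transition[section])
        for score in range(4):
            mask = baseline_scores[:, j] == score
            k = int(mask.sum())
            if k:
                followup[mask, j] = rng.choice(4, size=k, p=mat[score])
    return followup


def _assign_strata(
    config: CohortConfig, rng: np.random.Generator
) -> dict[str, str]:
    """Largest-remainder quota assignment, then a random permutation."""
    if not config.strata:
        return {}
    labels = sorted(config.strata)
    raw = {lab: config.strata[lab] * config.n for lab in labels}
    counts = {lab: int(math.floor(v)) for lab, v in raw.items()}
    short = config.n - sum(counts.values())
    for lab in sorted(labels, key=lambda l: raw[l] - counts[l], reverse=True)[:short]:
        counts[lab] += 1
    pool = [lab for lab in labels for _ in range(counts[lab])]
    order = rng.permutation(config.n)
    return {f"P{i:05d}": pool[order[i]] for i in range(config.n)}


def generate_cohort(
    config: CohortConfig, defn: Optional[InstrumentDefinition] = None
) -> SyntheticCohort:
    """Generate a full paired cohort: baseline + follow-up self
    assessments, clinician references at both timepoints, and comparator
    scale scores.  Fully reproducible given (config, config.seed)."""
    defn = defn or default_instrument()
    rng = np.random.default_rng(config.seed)
    baseline_scores, traits = _draw_section_scores(config, rng)
    baseline = _scores_to_records(baseline_scores, config, Timepoint.BASELINE, rng)
    if config.followup_transition:
        followup_scores = apply_followup_transition(baseline_scores, config, rng)
        followup = _scores_to_records(followup_scores, config, Timepoint.FOLLOWUP, rng)
    else:
        followup = []
    clinician = _draw_clinician(baseline, config, rng)
    clinician += _draw_clinician(followup, config, rng)
    ids = [r.participant_id for r in baseline]
    comparators = _draw_comparators(traits, ids, config, rng)
    strata = _assign_strata(config, rng)
    cohort = SyntheticCohort(
        assessments=tuple(baseline + followup),
        clinician=tuple(clinician),
        comparator_scores=comparators,
        config=config,
        strata_assignment=strata,
    )
    for rec in cohort.assessments:
        validate_assessment(rec, defn)
    return cohort


# ---------------------------------------------------------------------------
# parameter recovery
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RecoveryResult:
    """Bias and CI coverage of the pipeline estimators over replicates."""

    n_reps: int
    target_sensitivity: float
    target_specificity: float
    mean_sensitivity: float
    mean_specificity: float
    bias_sensitivity: float
    bias_specificity: float
    coverage_sensitivity: float
    coverage_specificity: float
    mean_rho: Optional[float] = None
    rho_target: Optional[float] = None


def _cohort_confusion(cohort: SyntheticCohort, defn: InstrumentDefinition):
    records = cohort.records(Timepoint.BASELINE)
    clin = {c.participant_id: c for c in cohort.clinician_records(Timepoint.BASELINE)}
    tool = [
        int(score_assessment(r, defn).domain("psychiatry").score >= 1) for r in records
    ]
    ref = [int(clin[r.participant_id].psychiatric_concern) for r in records]
    return build_confusion(tool, ref)


def recovery_experiment(
    config: CohortConfig,
    reps: int,
    level: float = 0.95,
    comparator: Optional[str] = None,
    rho_reference_n: int = 200_000,
) -> RecoveryResult:
    """Monte Carlo check that the full pipeline recovers the config's
    analytic operating point.

    For each replicate a fresh cohort is generated (child seeds spawned
    from ``config.seed``), scored through the decision algorithm, compared
    against the clinician reference, and summarized with exact intervals;
    the result reports mean estimates, bias against the analytic targets,
    and empirical CI coverage.  If ``comparator`` names a configured
    scale, Spearman recovery of the tool-domain/composite correlation is
    reported against a large-replicate reference value (same generator,
    ``rho_reference_n`` participants).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    defn = default_instrument()
    target_se, target_sp = operating_point(config)
    seeds = np.random.SeedSequence(config.seed).spawn(reps + 1)
    sens, spec, cov_se, cov_sp, rhos = [], [], [], [], []
    for r in range(reps):
        child = config.model_copy(
            update={"seed": int(seeds[r].generate_state(1)[0] % (2**31))}
        )
        cohort = generate_cohort(child, defn)
        ct = _cohort_confusion(cohort, defn)
        if ct.n_positive:
            se = ct.tp / ct.n_positive
            lo, hi = clopper_pearson(ct.tp, ct.n_positive, level)
            sens.append(se)
            cov_se.append(lo <= target_se <= hi)
        if ct.n_negative:
            sp = ct.tn / ct.n_negative
            lo, hi = clopper_pearson(ct.tn, ct.n_negative, level)
            spec.append(sp)
            cov_sp.append(lo <= target_sp <= hi)
        if comparator is not None:
            rho, _ = spearman_rho(
                *_domain_vs_composite(cohort, defn, comparator), level
            )
            rhos.append(rho)
    rho_target = mean_rho = None
    if comparator is not None:
        big = config.model_copy(
            update={
                "n": rho_reference_n,
                "seed": int(seeds[reps].generate_state(1)[0] % (2**31)),
                "followup_transition": {},
            }
        )
        rho_target, _ = spearman_rho(*_domain_vs_composite(generate_cohort(big, defn), defn, comparator))
        mean_rho = float(np.mean(rhos))
    return RecoveryResult(
        n_reps=reps,
        target_sensitivity=target_se,
        target_specificity=target_sp,
        mean_sensitivity=float(np.mean(sens)),
        mean_specificity=float(np.mean(spec)),
        bias_sensitivity=float(np.mean(sens) - target_se),
        bias_specificity=float(np.mean(spec) - target_sp),
        coverage_sensitivity=float(np.mean(cov_se)),
        coverage_specificity=float(np.mean(cov_sp)),
        mean_rho=mean_rho,
        rho_target=rho_target,
    )


def _domain_vs_composite(
    cohort: SyntheticCohort, defn: InstrumentDefinition, comparator: str
) -> tuple[list[int], list[int]]:
    if comparator not in cohort.comparator_scores:
        raise KeyError(f"comparator {comparator!r} not in cohort")
    df = cohort.comparator_scores[comparator]
    trait = cohort.config.comparator_models[comparator].trait
    records = cohort.records(Timepoint.BASELINE)
    scores = [score_assessment(r, defn).domain(trait).score for r in records]
    composite = df.set_index("participant_id").loc[
        [r.participant_id for r in records], "composite"
    ]
    return scores, composite.tolist()
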