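"""Published evaluation counts for the instrument's validation cohort.

The instrument's prospective validation cohort (n=100 postsecondary
students, baseline and 3-month follow-up, clinician-administered interview
as the reference standard) reported every predictive-validity table with
its raw TP/FN/FP/TN counts, the mutual-information agreement triples, and
the help-seeking funnel counts.  Those printed counts are *inputs*: feeding
them back through the estimators reproduces the published sensitivities,
specificities and proportions at desk scale, which is how the package's
acceptance checks work.  Raw participant-level data were never deposited,
so correlation- and alpha-level results are not reproducible from counts
and are exercised on synthetic cohorts instead.

Two published cells are not reproducible under round-half-up integer
rounding and are documented rather than asserted: the baseline any-concern
specificity prints 25 although 12/49 = 24.5 rounds to 24, and the baseline
stratified adjusted specificity prints 77 although 21/27 = 77.8 rounds
to 78.
"""

from __future__ import annotations

from .io import HelpSeekingRecord
from .psychometrics import ConfusionTable

__all__ = [
    "ANY_CONCERN",
    "STRATIFIED",
    "RESOURCE_NEEDS_BASELINE",
    "PSYCHOSOCIAL_BASELINE",
    "PSYCHOSOCIAL_FOLLOWUP",
    "MI_PRINTED",
    "HELP_SEEKING_COUNTS",
    "build_help_seeking_records",
]

#: Any-concern (Psychiatry domain score >= 1) vs clinician concern flag.
ANY_CONCERN: dict[str, ConfusionTable] = {
    "baseline": ConfusionTable(tp=51, fn=0, fp=37, tn=12),
    "followup": ConfusionTable(tp=41, fn=2, fp=45, tn=12),
}

#: Moderate-or-severe discrimination among clinician-positive participants
#: (tp/fn over clinician moderate/severe, fp/tn over clinician mild).
STRATIFIED: dict[str, ConfusionTable] = {
    "baseline": ConfusionTable(tp=16, fn=8, fp=6, tn=21),
    "followup": ConfusionTable(tp=7, fn=3, fp=8, tn=25),
}

#: Tool-recommended vs clinician-identified support needs (baseline only).
RESOURCE_NEEDS_BASELINE: dict[str, ConfusionTable] = {
    "urgent_or_severe": ConfusionTable(tp=1, fn=0, fp=7, tn=92),
    "gp_or_counseling": ConfusionTable(tp=19, fn=4, fp=46, tn=31),
    "gp": ConfusionTable(tp=13, fn=3, fp=50, tn=34),
    "counseling": ConfusionTable(tp=4, fn=8, fp=4, tn=88),
    "peer_support": ConfusionTable(tp=14, fn=2, fp=64, tn=20),
    "self_management": ConfusionTable(tp=40, fn=5, fp=53, tn=2),
}

#: Broader psychosocial concerns, per section flag vs clinician category.
PSYCHOSOCIAL_BASELINE: dict[str, ConfusionTable] = {
    "housing": ConfusionTable(tp=8, fn=2, fp=13, tn=77),
    "education": ConfusionTable(tp=14, fn=2, fp=46, tn=38),
    "relationships": ConfusionTable(tp=18, fn=7, fp=39, tn=36),
    "substances": ConfusionTable(tp=4, fn=0, fp=57, tn=39),
    "sexual": ConfusionTable(tp=1, fn=0, fp=23, tn=76),
    "abuse": ConfusionTable(tp=7, fn=0, fp=33, tn=60),
}

PSYCHOSOCIAL_FOLLOWUP: dict[str, ConfusionTable] = {
    "housing": ConfusionTable(tp=2, fn=4, fp=14, tn=80),
    "education": ConfusionTable(tp=9, fn=3, fp=41, tn=47),
    "relationships": ConfusionTable(tp=15, fn=5, fp=30, tn=50),
    "substances": ConfusionTable(tp=4, fn=0, fp=55, tn=43),
    "sexual": ConfusionTable(tp=1, fn=0, fp=15, tn=84),
    "abuse": ConfusionTable(tp=4, fn=0, fp=40, tn=56),
}

#: Published mutual-information agreement rows:
#: (I_agreement, I_disagreement, I_total, chi_square, df), all at N=100.
MI_PRINTED: dict[tuple[str, str], tuple[float, float, float, float, int]] = {
    ("psychiatry", "hrqol_emotional"): (0.25, -0.01, 0.24, 33.51, 3),
    ("psychiatry", "wellbeing_total"): (0.19, 0.07, 0.26, 35.68, 6),
    ("function", "hrqol_school"): (0.18, 0.00, 0.18, 24.99, 3),
    ("function", "wellbeing_total"): (0.10, 0.11, 0.20, 28.12, 6),
}

#: Help-seeking funnel at 3-month follow-up: of 100 screened, 88 received a
#: needs-based recommendation; 12 accessed it, 11 attempted unsuccessfully,
#: 65 made no attempt, and 54 non-attempters (plus 7 unsuccessful
#: attempters) intended to access care later.  Barrier tallies cover
#: non-accessors.
HELP_SEEKING_COUNTS = {
    "n_screened": 100,
    "needs_based": 88,
    "accessed": 12,
    "attempted_unsuccessful": 11,
    "no_attempt": 65,
    "intend_future_no_attempt": 54,
    "intend_future_attempted": 7,
    "barriers": {"time": 45, "low_perceived_need": 38, "service_availability": 16},
}


def build_help_seeking_records() -> list[HelpSeekingRecord]:
    """Materialize the published funnel counts as individual records.

    Deterministic: participants are laid out in funnel order (accessed,
    then unsuccessful attempters, then non-attempters, then the 12 with
    maintenance-only recommendations) and barrier labels are assigned to
    the leading non-accessors in each tally.  Feeding the result through
    :func:`heartsmap_u.io.summarize_help_seeking` reproduces the published
    proportions exactly.
    """
    c = HELP_SEEKING_COUNTS
    records: list[HelpSeekingRecord] = []
    non_accessors = c["attempted_unsuccessful"] + c["no_attempt"]
    barrier_sets: list[set[str]] = [set() for _ in range(non_accessors)]
    for label, count in c["barriers"].items():
        for i in range(count):
            barrier_sets[i % non_accessors].add(label)
    intend = [False] * non_accessors
    for i in range(c["intend_future_attempted"]):
        intend[i] = True  # attempters first in the layout below
    for i in range(c["attempted_unsuccessful"],
                   c["attempted_unsuccessful"] + c["intend_future_no_attempt"]):
        intend[i] = True
    pid = 0
    for _ in range(c["accessed"]):
        records.append(
            HelpSeekingRecord(
                participant_id=f"S{pid:03d}",
                received_needs_based_rec=True,
                accessed=True,
            )
        )
        pid += 1
    for i in range(non_accessors):
        records.append(
            HelpSeekingRecord(
                participant_id=f"S{pid:03d}",
                received_needs_based_rec=True,
                accessed=False,
                attempted=i < c["attempted_unsuccessful"],
                intends_future=intend[i],
                barriers=frozenset(barrier_sets[i]),
            )
        )
        pid += 1
    for _ in range(c["n_screened"] - c["needs_based"]):
        records.append(
            HelpSeekingRecord(
                participant_id=f"S{pid:03d}",
                received_needs_based_rec=False,
                accessed=False,
                attempted=False,
                intends_future=False,
            )
        )
        pid += 1
    return records
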