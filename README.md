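# heartsmap-u

A configurable implementation of **HEARTSMAP-U** — a 10-section,
4-domain psychosocial self-screening instrument for postsecondary
students — together with the psychometric pipeline used to evaluate such
screeners against a clinician reference standard, comparator scales, and
follow-up help-seeking surveys.

The package is for researchers validating or adapting multidomain mental
health screening tools: it separates the *instrument* (a versioned,
config-driven rule set), the *decision algorithm* (deterministic scoring
and resource-recommendation triggering), the *evaluation statistics*, and
a *synthetic cohort generator* so that every stage is testable without
access to participant-level health records.

## The instrument and its decision algorithm

Each of the 10 sections (Mood, Thoughts & Anxiety, Safety, Housing &
Material Security, …) is scored on a 4-point Likert-type scale,
0 (no concern) to 3 (severe concern). Sections scored 1–3 additionally
prompt whether resources are already being accessed. The algorithm
aggregates sections into four domains (Social, Function, Psychiatry,
Student Health), each the sum of 3 mapped sections:

```
domain score D = s₁ + s₂ + s₃ ∈ [0, 9]
severity(D)   = none (0) | mild (1–3) | moderate (4–6) | severe (7–9)
```

A rule table keyed on domain severity and single-section acuity
overrides (e.g. Safety ≥ 2) emits **firm** (urgent, time-bound) and
**soft** (advisory) recommendations across seven service categories,
de-duplicated to the most urgent timeframe and deterministically ordered.

## The evaluation statistics

* **Predictive validity** — sensitivity `tp/(tp+fn)` and specificity
  `tn/(tn+fp)` against the clinician flag, with exact Clopper–Pearson
  95% CIs (beta-quantile inversion of the binomial tails); *adjusted*
  specificity collapses the tool's none+mild classes as a negative
  screen; a stratified variant measures mild vs moderate-or-severe
  discrimination among clinician-positives; per-category resource-need
  metrics compare recommended vs clinician-identified services.
* **Convergent validity** — midrank Spearman ρ with Fisher-z CIs
  (SE = 1/√(n−3)), and Cronbach's α for internal consistency.
* **Classification agreement** — the mutual information of an r×c
  severity cross-classification, in bits, decomposed over designated
  agreement cells:
  `I_total = Σ p(i,j) log₂ p(i,j)/(p(i·)p(·j)) = I_agree + I_disagree`,
  tested with the likelihood-ratio statistic `G = 2·N·ln2·I_total` on
  (r−1)(c−1) df; agreement is declared when `I_agree > I_disagree` and
  p < .10.
* **Clinical utility** — the help-seeking funnel (accessed / attempted
  unsuccessfully / no attempt, intention, barrier tallies) over
  participants who received a needs-based recommendation.

## Worked example

```python
from heartsmap_u import *

defn = default_instrument()
rec = AssessmentRecord(
    participant_id="S042", timepoint=Timepoint.BASELINE,
    section_scores={"housing": 0, "education": 2, "relationships": 1,
                    "thoughts_anxiety": 2, "substances": 1, "safety": 2,
                    "sexual_wellness": 0, "mood": 3, "abuse": 0,
                    "professionals": 1},
    access_flags={"education": False, "relationships": False,
                  "thoughts_anxiety": True, "substances": False,
                  "safety": False, "mood": True, "professionals": False},
)
res = score_assessment(validate_assessment(rec, defn), defn)
for d in res.domain_results:
    print(f"{d.domain:14s} score={d.score}  severity={d.severity.value}")
for it in res.recommendations.items:
    print(f"  {it.resource_category.value:26s} {it.firmness.value:4s} "
          f"{it.timeframe.value:12s} ({it.rule_id})")
```

prints

```
social         score=1  severity=mild
function       score=2  severity=mild
psychiatry     score=7  severity=severe
student_health score=3  severity=mild
  urgent_crisis              firm immediately  (safety-crisis)
  psychiatric_consultation   firm within-72h   (psychiatry-severe)
  primary_care               soft unspecified  (function-mild-primary-care)
  peer_support               soft unspecified  (function-mild-peer-support)
  self_directed              soft unspecified  (maintenance)
```

Mood 3 + Thoughts & Anxiety 2 + Safety 2 put the Psychiatry domain at 7
(severe), triggering a firm psychiatric consultation within 72 h, and the
acute Safety score ≥ 2 escalates to an immediate crisis recommendation;
the milder domains add soft advisory items, with self-directed
maintenance resources as the universal floor.

Evaluation works from confusion counts:

```python
m = classification_metrics(ConfusionTable(tp=51, fn=0, fp=37, tn=12))
m["sensitivity"].point, m["sensitivity"].ci_low   # 1.0, 0.9302
m["specificity"].point                            # 0.2449
```

i.e. sensitivity 100% (95% CI 93–100) and specificity 24.5% for a
51-positive / 49-negative cohort whose every tool-negative was also
clinician-negative.

A full synthetic pipeline from the command line:

```bash
heartsmap-u simulate --n 100 --seed 7 --out sim/
heartsmap-u score    --assessments sim/assessments.csv --out results.json
heartsmap-u validate --tool results.json --clinician sim/clinician.csv \
                     --assessments sim/assessments.csv --out tables/
heartsmap-u converge --tool results.json --comparators sim/ --out conv/
heartsmap-u report   --table tables/any_concern.csv --out any_concern.md
```

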