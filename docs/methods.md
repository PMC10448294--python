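# Methods

This note documents the models, defaults, numerical choices and known
limitations of the package. It is written for maintainers and for
researchers judging what the tests do and do not establish.

## Instrument model

The instrument is fully config-driven (`InstrumentDefinition`): 10
sections, a domain map assigning exactly 3 sections per domain (sections
may serve several domains), severity cutoffs that must partition the 0–9
domain-score range, and a recommendation rule table. All structural
invariants are enforced at construction, so an object that exists is
valid; errors name the offending element.

Two pieces of the shipped default are explicit assumptions rather than
published facts:

* **Student Health membership.** The published description enumerates the
  Social, Function and Psychiatry domains but not Student Health's three
  sections. The default assigns
  `{education, professionals, sexual_wellness}`, which covers the two
  otherwise-unmapped sections and preserves the documented property that
  some sections serve more than one domain. Replace via config if the
  authoritative mapping becomes available.
* **The rule table.** The published material describes the recommendation
  gradient qualitatively (firm = urgent and time-sensitive, soft =
  advisory; intensity scales with severity and acuity). The shipped
  default operationalizes it as: severe domain → firm domain-matched
  service within 72 h; moderate → firm counseling and primary care
  within 1 week; mild → soft primary care and peer support; Safety ≥ 2
  (or Abuse = 3) → firm immediate crisis referral; and an unconditional
  soft self-directed maintenance floor, which guarantees rule-set
  totality. **Acuity** is operationalized as the maximum single-section
  score, expressed through those section-level override rules.
* The per-section "already accessing resources" answer is recorded and
  surfaced in reports but does not influence rule triggering; nothing in
  the published algorithm description ties triggering to it.

Free-text boxes are stored verbatim and never parsed. Section
identifiers are canonical snake-case tokens with a display-name table so
config files diff cleanly.

## Scoring

Domain score = sum of the 3 mapped section scores; severity = the cutoff
band containing the score; the any-concern flag fires at domain
score ≥ 1. Recommendation evaluation is deterministic: duplicate
(category, firmness) items collapse to the most urgent timeframe
(lexicographically first rule id as tie-break), and output order is
urgency rank, then a fixed category order, then rule id. Scoring is
side-effect free and idempotent; the monotonicity property (raising any
section score never lowers any domain score or severity) is
property-tested, and the domain-sum/severity logic is verified
exhaustively over all 4³ section combinations per domain.

## Predictive-validity estimators

* Confidence intervals are **exact Clopper–Pearson** (beta-quantile
  form, via statsmodels), chosen because the published perfect-sensitivity
  lower bound (93 for 51/51) matches the x=n closed form
  `0.025^(1/51) = 0.9302` exactly. Degenerate bounds are 0 at x=0 and 1
  at x=n. Tests cross-check every (x, n) with n ≤ 50 against a direct
  binomial-tail bisection oracle.
* Metrics with a zero denominator are reported as not-applicable (N/A in
  rendered tables) rather than raising, mirroring empty strata in
  published layouts.
* **Adjusted specificity** treats tool classes {none, mild} as a negative
  screen and is computed over reference-negative participants.
* **Stratified metrics** restrict to reference-positive participants:
  sensitivity is P(tool ∈ {moderate, severe} | reference ∈ {moderate,
  severe}); adjusted specificity is P(tool ∈ {none, mild} | reference =
  mild).
* Report percentages round **half-up to integer percent**, with raw
  counts co-printed so rounding is auditable. Under this convention two
  published cells are irreproducible from their own printed counts
  (12/49 = 24.5 prints as 25; 21/27 = 77.8 prints as 77); the tests
  document both exclusions rather than asserting the printed values.
* Listwise exclusion per paired comparison; participants missing from
  either side of a pairing are dropped for that table only.

## Convergent validity

Spearman ρ uses midranks (scipy); the CI is the conventional Fisher-z
normal approximation with SE = 1/√(n−3). This is approximate — it
degenerates to a point at |ρ| = 1 and is anticonservative for very small
n — but is the standard choice for reported correlation CIs. Cronbach's
α is the variance-ratio formula `k/(k−1)·(1 − Σσ²ᵢ/σ²ₜ)` with n−1
variances; tests cross-check against pingouin and against the
Spearman–Brown closed form `kr/(1+(k−1)r)` under a common inter-item
correlation.

## Mutual-information agreement

For an r×c cross-classification with cell proportions p(i,j),

    I_total = Σ_{p(i,j)>0} p(i,j) · log₂ [ p(i,j) / (p(i·) p(·j)) ]

decomposed over a designated set of *agreement cells* (the rest are
disagreement cells); per-cell contributions may be negative, so
I_disagreement can be negative, and the identity
I_agree + I_disagree = I_total holds to 1e−12 by construction (verified
on 1,000 random tables). The test statistic is the likelihood-ratio
**G = 2·N·ln2·I_total** on (r−1)(c−1) df — the log-base-2 analogue of
the standard G-test, cross-checked against scipy's log-likelihood-ratio
contingency test. A Pearson chi-square variant is available
(`statistic="pearson"`) but G is the default: recomputing 2·N·ln2·I from
the published two-decimal I values reproduces the published chi-squares
within input rounding, which a Pearson statistic would not be guaranteed
to do. Agreement is declared when I_agree > I_disagree and p < .10.
Single-row/column tables get df = 0 and no p-value.

For non-square tables the agreement cells default to the proportional
ordinal band map `j = round(i·(c−1)/(r−1))`: for 4 severities × 2 risk
classes, {none, mild} ↔ not-at-risk and {moderate, severe} ↔ at-risk;
for 4 × 3 well-being bands, none ↔ healthiest, mild/moderate ↔ middle,
severe ↔ most impaired. The published analyses do not print their cell
mapping, so this default is an assumption and is overrideable per
comparison.

## Synthetic cohorts

The generator emulates a screening-validation study: correlated ordinal
psychosocial severities, a noisy clinician reference, comparator scales,
and a 3-month follow-up.

* **Latent model.** A 4-dimensional Gaussian copula over domain traits
  (default cross-correlations 0.30–0.45, the moderate range typical of
  psychosocial constructs). Each section's latent is
  `λ·trait + √(1−λ²)·ε` (default λ = 0.7), standard normal marginally,
  discretized through per-section thresholds. Default thresholds are
  normal quantiles of a realistic mild-skewed student score
  distribution (most sections concentrated on scores 0–1, severe
  responses at 0–5%); marginals are normalized to sum to 1 before the
  quantile transform. A +∞ threshold encodes a zero-probability top
  category.
* **Clinician reference.** The participant's "true" concern state is the
  tool's deterministic any-concern flag computed from the same latents;
  the clinician flags it with probability `pi_sens` (or `pi_fa` when
  absent) and rates severity through a row-stochastic confusion matrix,
  renormalized over mild–severe for flagged participants. Psychosocial
  category labels flip the section-derived truth with miss/false-alarm
  rates (defaults 0.10/0.05); resource needs attach to the rated
  severity with a small per-category flip rate (default 0.05).
  Because the clinician noise is conditionally independent given the
  true state, the tool-vs-clinician operating point has a closed form in
  the tool-positive prevalence, and that prevalence is itself computed
  by 80-node Gauss–Hermite quadrature over the shared Psychiatry trait
  (the three psychiatry sections are conditionally independent given the
  trait). `calibrate_clinician_model` inverts the closed form, so a
  config targets a chosen sensitivity/specificity *exactly* in
  expectation — the basis of the recovery experiments. The default
  config targets 0.95/0.25, a high-sensitivity low-specificity regime
  characteristic of universal screeners.
* **Comparators.** Generic Likert grids loading on one domain trait
  (defaults 0.65–0.75, 3–14 items), keyed so higher = more concern.
  Item-level content of named commercial instruments is deliberately not
  simulated.
* **Follow-up.** Per-section 4×4 Markov transition rows (default: mild
  mean-reversion, ~85% of zeros stay zero). Tests verify the identity
  and absorbing limits and that long-run marginals match the stationary
  eigenvector.
* **Strata** are assigned by largest-remainder quota then randomly
  permuted, so realized proportions are within rounding of quota.
* All randomness flows through one seeded `numpy.random.Generator`;
  replicate seeds are spawned via `SeedSequence`. Identical
  (config, seed) reproduce cohorts record-for-record.

What passing tests show — and don't. Recovery within ±0.02 at n = 10,000
and ≥ 95% empirical CI coverage at n = 100 demonstrate that the
estimators and generator are mutually consistent under the latent-trait
model. They do not validate the instrument on real students: real data
have clustered missingness, clinician drift, item-level idiosyncrasies
and selection effects the copula model does not emulate.

## Problem sizes

The shipped defaults keep everything desk-scale: exhaustive scoring
checks (4³ per domain), exact-interval oracles for all n ≤ 50,
1,000-table MI identity checks, one n = 10,000 recovery cohort, 500
coverage replicates at n = 100, and a 400,000-draw vectorized oracle for
Spearman recovery. The full suite runs in well under a minute plus ~25 s
for the simulation-heavy tests; the acceptance script runs in seconds
(its coverage loop uses 200 replicates).

## Known limitations

* The Student Health domain map, the rule table, and the MI agreement
  cells are documented assumptions (config-replaceable), not published
  facts.
* The Fisher-z Spearman CI is approximate; bootstrap CIs are out of
  scope.
* The generator draws follow-up scores purely from per-section Markov
  rows, ignoring cross-section correlation in the *changes* (levels stay
  correlated through baseline).
* The clinician severity confusion default is plausible but uncalibrated
  to any external data.
* No diagnostic likelihood ratios, ROC analysis, or multiplicity
  correction: the evaluation design this package implements reports
  per-comparison estimates with 95% CIs only.
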