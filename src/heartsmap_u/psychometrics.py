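"""Psychometric evaluation statistics for screening-instrument validation.

Implements the full analytic toolkit used to evaluate a screening tool
against a clinician reference standard and comparator scales:

* predictive validity — confusion tables, sensitivity/specificity with
  exact (Clopper-Pearson) binomial CIs, adjusted specificity (none+mild
  collapsed as a negative screen), severity-stratified metrics, and
  per-category resource-need metrics;
* convergent validity — midrank Spearman correlations with Fisher-z CIs,
  and Cronbach's alpha for internal consistency;
* classification agreement — the mutual-information decomposition over a
  cross-classification with designated agreement cells, tested with the
  likelihood-ratio (G) statistic; agreement is declared when
  I_agreement > I_disagreement and p < .10;
* a Pearson chi-square homogeneity test for comparing score distributions
  across timepoints.

Mutual information is reported in bits.  For an r x c table with cell
proportions p(i,j) and marginals p(i.), p(.j),

    I_total = sum_{ij} p(i,j) * log2( p(i,j) / (p(i.) p(.j)) )

summed over non-empty cells.  The designated agreement cells contribute
I_agreement and the rest I_disagreement (individual contributions may be
negative), with I_agreement + I_disagreement = I_total exactly.  The
associated likelihood-ratio statistic is G = 2 * N * ln(2) * I_total on
(r-1)(c-1) degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .instrument import ResourceCategory, Severity
from .scoring import RecommendationSet

__all__ = [
    "ConfusionTable",
    "MetricEstimate",
    "AgreementTable",
    "MIResult",
    "build_confusion",
    "clopper_pearson",
    "classification_metrics",
    "adjusted_specificity",
    "severity_stratified_metrics",
    "resource_metrics",
    "spearman_rho",
    "cronbach_alpha",
    "mi_agreement",
    "ordinal_band_cells",
    "agreement_table_from_vectors",
    "chi_square_homogeneity",
]

_NEGATIVE_SCREEN = frozenset({Severity.NONE, Severity.MILD})
_POSITIVE_SCREEN = frozenset({Severity.MODERATE, Severity.SEVERE})


@dataclass(frozen=True)
class ConfusionTable:
    """TP/FN/FP/TN counts of a tool flag against a reference flag."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"count {name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def n_positive(self) -> int:
        """Reference-positive participants."""
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.fp + self.tn


@dataclass(frozen=True)
class MetricEstimate:
    """A proportion with its exact confidence interval."""

    point: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    method: str = "clopper-pearson"

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_low <= self.point <= self.ci_high <= 1.0):
            raise ValueError(
                f"interval [{self.ci_low}, {self.ci_high}] must contain the point "
                f"{self.point} within [0, 1]"
            )


def build_confusion(
    tool_flags: Sequence[int] | Sequence[bool],
    ref_flags: Sequence[int] | Sequence[bool],
) -> ConfusionTable:
    """Cross-tabulate paired binary tool/reference flags."""
    t = np.asarray(tool_flags)
    r = np.asarray(ref_flags)
    if t.shape != r.shape or t.ndim != 1:
        raise ValueError(
            f"tool and reference vectors must be equal-length 1-d, got shapes "
            f"{t.shape} and {r.shape}"
        )
    for name, v in (("tool", t), ("reference", r)):
        if not np.isin(v, (0, 1)).all():
            raise ValueError(f"{name} vector contains non-binary entries")
    t = t.astype(bool)
    r = r.astype(bool)
    return ConfusionTable(
        tp=int(np.sum(t & r)),
        fn=int(np.sum(~t & r)),
        fp=int(np.sum(t & ~r)),
        tn=int(np.sum(~t & ~r)),
    )


def clopper_pearson(
    successes: int, trials: int, level: float = 0.95
) -> tuple[float, float]:
    """Exact two-sided binomial confidence interval.

    Obtained by inverting the binomial tail probabilities (beta-quantile
    form).  The lower bound is 0 when ``successes`` is 0 and the upper
    bound is 1 when ``successes`` equals ``trials``.
    """
    if trials < 1 or not 0 <= successes <= trials:
        raise ValueError(f"invalid counts: {successes} successes in {trials} trials")
    if not 0.0 < level < 1.0:
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    lo, hi = proportion_confint(successes, trials, alpha=1.0 - level, method="beta")
    # statsmodels leaves the degenerate bounds at nan
    lo = 0.0 if successes == 0 or math.isnan(lo) else float(lo)
    hi = 1.0 if successes == trials or math.isnan(hi) else float(hi)
    return lo, hi


def _estimate(successes: int, trials: int, level: float) -> MetricEstimate:
    lo, hi = clopper_pearson(successes, trials, level)
    return MetricEstimate(point=successes / trials, ci_low=lo, ci_high=hi, level=level)


def classification_metrics(
    ct: ConfusionTable, level: float = 0.95
) -> dict[str, Optional[MetricEstimate]]:
    """Sensitivity tp/(tp+fn) and specificity tn/(tn+fp) with exact CIs.

    A metric whose denominator is zero is reported as ``None``
    (not applicable), mirroring empty strata.
    """
    sens = _estimate(ct.tp, ct.n_positive, level) if ct.n_positive else None
    spec = _estimate(ct.tn, ct.n_negative, level) if ct.n_negative else None
    return {"sensitivity": sens, "specificity": spec}


def adjusted_specificity(
    tool_severity: Sequence[Severity],
    ref_flags: Sequence[int] | Sequence[bool],
    level: float = 0.95,
) -> MetricEstimate:
    """Specificity with the tool's none+mild classes collapsed as negative.

    Computed over reference-negative participants only: the proportion the
    tool rated none or mild.
    """
    sev = list(tool_severity)
    ref = np.asarray(ref_flags).astype(bool)
    if len(sev) != len(ref):
        raise ValueError("paired vectors must have equal length")
    neg = [s for s, r in zip(sev, ref) if not r]
    if not neg:
        raise ValueError("no reference-negative participants; adjusted specificity undefined")
    successes = sum(1 for s in neg if s in _NEGATIVE_SCREEN)
    return _estimate(successes, len(neg), level)


@dataclass(frozen=True)
class StratifiedMetrics:
    """Moderate-or-severe discrimination among reference-positives."""

    table: ConfusionTable
    sensitivity: Optional[MetricEstimate]
    adjusted_specificity: Optional[MetricEstimate]


def severity_stratified_metrics(
    tool_severity: Sequence[Severity],
    ref_severity: Sequence[Severity],
    level: float = 0.95,
) -> StratifiedMetrics:
    """Ability to distinguish mild from moderate-or-severe issues.

    Restricted to reference-positive participants (reference severity at
    least mild).  Sensitivity is P(tool moderate/severe | reference
    moderate/severe); adjusted specificity is P(tool none/mild | reference
    mild).  The confusion layout is tool-vs-reference on the
    moderate-or-severe split: tp/fn among reference moderate/severe, fp/tn
    among reference mild.
    """
    pairs = [
        (t, r)
        for t, r in zip(tool_severity, ref_severity, strict=True)
        if r is not Severity.NONE
    ]
    tp = sum(1 for t, r in pairs if r in _POSITIVE_SCREEN and t in _POSITIVE_SCREEN)
    fn = sum(1 for t, r in pairs if r in _POSITIVE_SCREEN and t in _NEGATIVE_SCREEN)
    fp = sum(1 for t, r in pairs if r is Severity.MILD and t in _POSITIVE_SCREEN)
    tn = sum(1 for t, r in pairs if r is Severity.MILD and t in _NEGATIVE_SCREEN)
    ct = ConfusionTable(tp=tp, fn=fn, fp=fp, tn=tn)
    sens = _estimate(tp, tp + fn, level) if tp + fn else None
    adj = _estimate(tn, fp + tn, level) if fp + tn else None
    return StratifiedMetrics(table=ct, sensitivity=sens, adjusted_specificity=adj)


def resource_metrics(
    tool_recs: Sequence[RecommendationSet],
    ref_needs: Sequence[set[ResourceCategory] | frozenset[ResourceCategory]],
    category: ResourceCategory,
    level: float = 0.95,
) -> tuple[ConfusionTable, dict[str, Optional[MetricEstimate]]]:
    """Per-category resource-need prediction: tool recommended the category
    vs the clinician identified it as a need."""
    if not isinstance(category, ResourceCategory):
        raise ValueError(f"unknown resource category {category!r}")
    if len(tool_recs) != len(ref_needs):
        raise ValueError("paired sequences must have equal length")
    tool = [int(category in rs.categories) for rs in tool_recs]
    ref = [int(category in needs) for needs in ref_needs]
    ct = build_confusion(tool, ref)
    return ct, classification_metrics(ct, level)


# ---------------------------------------------------------------------------
# convergent validity
# ---------------------------------------------------------------------------


def spearman_rho(
    x: Sequence[float], y: Sequence[float], level: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Midrank Spearman correlation with a Fisher-z confidence interval.

    The CI uses the conventional normal approximation on the z scale with
    standard error 1/sqrt(n-3); it is approximate, especially near |rho|=1
    where it degenerates to a point.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired vectors must be equal-length 1-d")
    n = x.size
    if n < 4:
        raise ValueError(f"need at least 4 pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the vectors; rho undefined")
    rho = float(stats.spearmanr(x, y).statistic)
    if abs(rho) >= 1.0:
        return rho, (rho, rho)
    z = math.atanh(rho)
    half = stats.norm.ppf(0.5 + level / 2.0) / math.sqrt(n - 3)
    return rho, (math.tanh(z - half), math.tanh(z + half))


def cronbach_alpha(items: np.ndarray) -> float:
    """Cronbach's alpha: k/(k-1) * (1 - sum(item variances)/var(total)).

    ``items`` is a participants x items grid with no missing cells.
    Variances use the n-1 denominator.
    """
    grid = np.asarray(items, dtype=float)
    if grid.ndim != 2 or grid.shape[0] < 2 or grid.shape[1] < 2:
        raise ValueError(f"need a 2-d grid with >=2 participants and >=2 items, got {grid.shape}")
    if np.isnan(grid).any():
        raise ValueError("item grid contains missing cells")
    k = grid.shape[1]
    total_var = grid.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("total score has zero variance; alpha undefined")
    item_var = grid.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))


# ---------------------------------------------------------------------------
# mutual-information agreement
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AgreementTable:
    """r x c cross-classification with designated agreement cells.

    ``agreement_cells`` lists the (row, col) index pairs that count as the
    two instruments agreeing (an ordinal band mapping when the tables are
    non-square); the remaining cells are disagreement cells.
    """

    counts: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    agreement_cells: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-d grid")
        if (counts < 0).any() or not np.issubdtype(counts.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")
        r, c = counts.shape
        if len(self.row_labels) != r or len(self.col_labels) != c:
            raise ValueError("label lengths must match the grid shape")
        if counts.sum() < 1:
            raise ValueError("table must contain at least one observation")
        for (i, j) in self.agreement_cells:
            if not (0 <= i < r and 0 <= j < c):
                raise ValueError(f"agreement cell {(i, j)} outside the {r}x{c} grid")

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class MIResult:
    """Mutual-information agreement decomposition and its G test."""

    i_agreement: float
    i_disagreement: float
    i_total: float
    g_stat: float
    df: int
    p_value: Optional[float]
    verdict: Literal["agreement", "disagreement"]


def mi_agreement(
    table: AgreementTable, statistic: Literal["g", "pearson"] = "g"
) -> MIResult:
    """Decompose a cross-classification's mutual information (in bits) into
    agreement- and disagreement-cell contributions and test it.

    Empty cells contribute 0.  With the default ``statistic="g"`` the test
    statistic is the likelihood-ratio G = 2 * N * ln(2) * I_total on
    (r-1)(c-1) df; ``"pearson"`` substitutes the Pearson chi-square on the
    same table (same df).  A degenerate single-row or single-column table
    has df 0 and no p-value.  Agreement is declared when
    I_agreement > I_disagreement and p < .10.
    """
    counts = table.counts.astype(float)
    n = counts.sum()
    p = counts / n
    pr = p.sum(axis=1, keepdims=True)
    pc = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0) / (pr * pc)), 0.0)
    agree_mask = np.zeros(counts.shape, dtype=bool)
    for (i, j) in table.agreement_cells:
        agree_mask[i, j] = True
    i_agree = float(contrib[agree_mask].sum())
    i_disagree = float(contrib[~agree_mask].sum())
    i_total = float(contrib.sum())
    r, c = counts.shape
    df = (r - 1) * (c - 1)
    if statistic == "g":
        g = 2.0 * n * math.log(2.0) * i_total
    elif statistic == "pearson":
        expected = pr * pc * n
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(expected > 0, (counts - expected) ** 2 / expected, 0.0)
        g = float(terms.sum())
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    p_value = float(stats.chi2.sf(g, df)) if df > 0 else None
    verdict: Literal["agreement", "disagreement"] = (
        "agreement"
        if (i_agree > i_disagree and p_value is not None and p_value < 0.10)
        else "disagreement"
    )
    return MIResult(
        i_agreement=i_agree,
        i_disagreement=i_disagree,
        i_total=i_total,
        g_stat=float(g),
        df=df,
        p_value=p_value,
        verdict=verdict,
    )


def ordinal_band_cells(n_rows: int, n_cols: int) -> frozenset[tuple[int, int]]:
    """Default agreement-cell mapping for two ordinal classifications.

    Row i agrees with the proportionally matching column
    round(i * (c-1) / (r-1)).  For 4 tool severities x 2 risk classes this
    maps {none, mild} to not-at-risk and {moderate, severe} to at-risk;
    for 4 x 3 it maps none to the healthiest band, mild and moderate to
    the middle band, and severe to the most impaired band.  The mapping is
    a shipped default; per-comparison overrides go in the AgreementTable.
    """
    if n_rows < 2 or n_cols < 1:
        raise ValueError(f"degenerate shape ({n_rows}, {n_cols})")
    if n_cols == 1:
        return frozenset((i, 0) for i in range(n_rows))
    return frozenset(
        (i, int(math.floor(i * (n_cols - 1) / (n_rows - 1) + 0.5)))
        for i in range(n_rows)
    )


def agreement_table_from_vectors(
    row_values: Sequence[int],
    col_values: Sequence[int],
    row_labels: Sequence[str],
    col_labels: Sequence[str],
    agreement_cells: Optional[frozenset[tuple[int, int]]] = None,
) -> AgreementTable:
    """Cross-tabulate paired ordinal codes into an AgreementTable.

    Values are 0-based indices into the label lists; the default agreement
    cells come from :func:`ordinal_band_cells`.
    """
    r, c = len(row_labels), len(col_labels)
    counts = np.zeros((r, c), dtype=int)
    for i, j in zip(row_values, col_values, strict=True):
        counts[i, j] += 1
    if agreement_cells is None:
        agreement_cells = ordinal_band_cells(r, c)
    return AgreementTable(
        counts=counts,
        row_labels=tuple(row_labels),
        col_labels=tuple(col_labels),
        agreement_cells=agreement_cells,
    )


def chi_square_homogeneity(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square test that two or more rows of category counts
    share a common distribution.  Returns (statistic, df, p)."""
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2:
        raise ValueError("need a 2-d grid with at least two rows of counts")
    expected = stats.contingency.expected_freq(counts)
    if (expected == 0).any():
        raise ValueError("table has an expected cell count of 0")
    res = stats.chi2_contingency(counts, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)
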