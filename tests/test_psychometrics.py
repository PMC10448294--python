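"""Estimator correctness against independent oracles.

Every non-trivial statistic is checked two ways: the package's
implementation against a brute-force or closed-form oracle written here
(binomial-tail bisection for exact intervals, rank-then-Pearson for
Spearman, Spearman-Brown for alpha, scipy's log-likelihood-ratio
contingency test for G).
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.optimize import brentq

from heartsmap_u import (
    AgreementTable,
    ConfusionTable,
    ResourceCategory,
    Severity,
    adjusted_specificity,
    agreement_table_from_vectors,
    build_confusion,
    chi_square_homogeneity,
    classification_metrics,
    clopper_pearson,
    cronbach_alpha,
    mi_agreement,
    ordinal_band_cells,
    resource_metrics,
    severity_stratified_metrics,
    spearman_rho,
)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def cp_bisection_oracle(x: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Invert the binomial tail probabilities directly."""
    alpha = 1.0 - level
    lo = 0.0 if x == 0 else brentq(
        lambda p: stats.binom.sf(x - 1, n, p) - alpha / 2, 1e-12, 1 - 1e-12, xtol=1e-12
    )
    hi = 1.0 if x == n else brentq(
        lambda p: stats.binom.cdf(x, n, p) - alpha / 2, 1e-12, 1 - 1e-12, xtol=1e-12
    )
    return lo, hi


def midrank_pearson_oracle(x, y) -> float:
    return float(np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1])


def random_table(rng, max_dim=5, max_count=40) -> AgreementTable:
    r = rng.integers(2, max_dim + 1)
    c = rng.integers(2, max_dim + 1)
    counts = rng.integers(0, max_count, size=(r, c))
    if counts.sum() == 0:
        counts[0, 0] = 1
    cells = frozenset(
        (i, j) for i in range(r) for j in range(c) if rng.random() < 0.4
    )
    return AgreementTable(
        counts=counts,
        row_labels=tuple(f"r{i}" for i in range(r)),
        col_labels=tuple(f"c{j}" for j in range(c)),
        agreement_cells=cells,
    )


# ---------------------------------------------------------------------------
# confusion tables and exact intervals
# ---------------------------------------------------------------------------


class TestConfusion:
    def test_perfect_agreement_all_positive(self):
        ct = build_confusion([1] * 5, [1] * 5)
        assert (ct.tp, ct.fn, ct.fp, ct.tn) == (5, 0, 0, 0)

    def test_complement_vectors_have_no_correct_cells(self):
        ct = build_confusion([1, 1, 0, 0], [0, 0, 1, 1])
        assert ct.tp == ct.tn == 0
        assert (ct.fp, ct.fn) == (2, 2)

    def test_length_mismatch_and_non_binary_rejected(self):
        with pytest.raises(ValueError):
            build_confusion([1, 0], [1])
        with pytest.raises(ValueError, match="non-binary"):
            build_confusion([1, 2], [1, 0])

    def test_vectors_reproduce_published_baseline_counts(self):
        tool = [1] * 51 + [1] * 37 + [0] * 12
        ref = [1] * 51 + [0] * 37 + [0] * 12
        ct = build_confusion(tool, ref)
        assert (ct.tp, ct.fn, ct.fp, ct.tn) == (51, 0, 37, 12)


class TestClopperPearson:
    def test_all_successes_closed_form(self):
        lo, hi = clopper_pearson(51, 51)
        assert hi == 1.0
        assert lo == pytest.approx(0.025 ** (1 / 51), abs=1e-12)

    def test_zero_successes_closed_form(self):
        for n in (5, 57):
            lo, hi = clopper_pearson(0, n)
            assert lo == 0.0
            assert hi == pytest.approx(1 - 0.025 ** (1 / n), abs=1e-12)

    def test_interior_case_matches_tail_inversion(self):
        lo, hi = clopper_pearson(12, 57)
        olo, ohi = cp_bisection_oracle(12, 57)
        assert lo == pytest.approx(olo, abs=1e-9)
        assert hi == pytest.approx(ohi, abs=1e-9)

    @given(n=st.integers(1, 200), data=st.data())
    @settings(max_examples=100, deadline=None)
    def test_interval_contains_point_estimate(self, n, data):
        x = data.draw(st.integers(0, n))
        lo, hi = clopper_pearson(x, n)
        assert lo <= x / n <= hi

    def test_width_non_increasing_in_trials_at_fixed_proportion(self):
        widths = []
        for n in (10, 20, 40, 80, 160):
            lo, hi = clopper_pearson(n // 2, n)
            widths.append(hi - lo)
        assert all(a >= b for a, b in zip(widths, widths[1:]))

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            clopper_pearson(5, 4)
        with pytest.raises(ValueError):
            clopper_pearson(-1, 4)


class TestClassificationMetrics:
    @pytest.mark.parametrize(
        "ct, sens, spec",
        [
            (ConfusionTable(51, 0, 37, 12), 1.0, 12 / 49),
            (ConfusionTable(41, 2, 45, 12), 41 / 43, 12 / 57),
            (ConfusionTable(4, 8, 4, 88), 4 / 12, 88 / 92),
        ],
    )
    def test_ratios_match_direct_arithmetic(self, ct, sens, spec):
        m = classification_metrics(ct)
        assert m["sensitivity"].point == pytest.approx(sens)
        assert m["specificity"].point == pytest.approx(spec)

    def test_zero_denominator_reports_not_applicable(self):
        m = classification_metrics(ConfusionTable(0, 0, 3, 7))
        assert m["sensitivity"] is None
        assert m["specificity"] is not None

    def test_label_swap_symmetry(self, rng):
        """Swapping positive/negative labels swaps sensitivity and
        specificity exactly."""
        tool = rng.integers(0, 2, 50)
        ref = rng.integers(0, 2, 50)
        m = classification_metrics(build_confusion(tool, ref))
        m_swapped = classification_metrics(build_confusion(1 - tool, 1 - ref))
        assert m["sensitivity"].point == pytest.approx(m_swapped["specificity"].point)
        assert m["specificity"].point == pytest.approx(m_swapped["sensitivity"].point)


class TestAdjustedAndStratified:
    def test_all_negatives_rated_none_or_mild_gives_one(self):
        sev = [Severity.MILD] * 30 + [Severity.NONE] * 19
        est = adjusted_specificity(sev, [0] * 49)
        assert est.point == 1.0

    def test_all_negatives_rated_moderate_gives_zero(self):
        est = adjusted_specificity([Severity.MODERATE] * 5, [0] * 5)
        assert est.point == 0.0

    def test_mixed_vector_brute_force(self):
        sev = [Severity.MODERATE] * 3 + [Severity.MILD] * 4 + [Severity.NONE] * 3
        est = adjusted_specificity(sev, [0] * 10)
        assert est.point == pytest.approx(0.7)

    def test_perfect_severity_agreement(self):
        sev = [Severity.MILD] * 5 + [Severity.MODERATE] * 3 + [Severity.SEVERE] * 2
        out = severity_stratified_metrics(sev, sev)
        assert out.sensitivity.point == 1.0
        assert out.adjusted_specificity.point == 1.0

    def test_random_vectors_match_brute_force_counter(self, rng):
        levels = list(Severity)
        for _ in range(25):
            tool = [levels[i] for i in rng.integers(0, 4, 20)]
            ref = [levels[i] for i in rng.integers(0, 4, 20)]
            out = severity_stratified_metrics(tool, ref)
            pos = {Severity.MODERATE, Severity.SEVERE}
            pairs = [(t, r) for t, r in zip(tool, ref) if r is not Severity.NONE]
            tp = sum(t in pos and r in pos for t, r in pairs)
            fn = sum(t not in pos and r in pos for t, r in pairs)
            fp = sum(t in pos and r is Severity.MILD for t, r in pairs)
            tn = sum(t not in pos and r is Severity.MILD for t, r in pairs)
            assert (out.table.tp, out.table.fn, out.table.fp, out.table.tn) == (tp, fn, fp, tn)
            if tp + fn:
                assert out.sensitivity.point == pytest.approx(tp / (tp + fn))
            else:
                assert out.sensitivity is None
            if fp + tn:
                assert out.adjusted_specificity.point == pytest.approx(tn / (fp + tn))
            else:
                assert out.adjusted_specificity is None


class TestResourceMetrics:
    def test_recommend_everything_gives_perfect_sensitivity_zero_specificity(self):
        from heartsmap_u import Firmness, RecommendationItem, RecommendationSet, Timeframe

        everything = RecommendationSet(
            items=tuple(
                RecommendationItem(cat, Firmness.SOFT, Timeframe.UNSPECIFIED, "all")
                for cat in ResourceCategory
            )
        )
        recs = [everything] * 10
        needs = [{ResourceCategory.COUNSELING}] * 4 + [set()] * 6
        for cat in ResourceCategory:
            ct, m = resource_metrics(recs, needs, cat)
            if ct.n_positive:
                assert m["sensitivity"].point == 1.0
            if ct.n_negative:
                assert m["specificity"].point == 0.0


# ---------------------------------------------------------------------------
# convergent validity
# ---------------------------------------------------------------------------


class TestSpearman:
    def test_strictly_monotone_vectors(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        rho, _ = spearman_rho(x, [v**3 for v in x])
        assert rho == pytest.approx(1.0, abs=1e-12)
        rho, _ = spearman_rho(x, [-v for v in x])
        assert rho == pytest.approx(-1.0, abs=1e-12)

    def test_eight_point_tied_vector_matches_midrank_pearson(self):
        x = [1, 1, 2, 3, 3, 3, 4, 5]
        y = [2, 1, 2, 2, 4, 5, 5, 5]
        rho, _ = spearman_rho(x, y)
        assert rho == pytest.approx(midrank_pearson_oracle(x, y), abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        x = rng.integers(0, 6, 40).astype(float)
        y = x + rng.normal(0, 1.5, 40)
        rho1, _ = spearman_rho(x, y)
        rho2, _ = spearman_rho(np.exp(x), y**3 if (y > 0).all() else np.arctan(y))
        assert rho1 == pytest.approx(rho2, abs=1e-12)

    def test_fisher_z_interval_brackets_rho(self, rng):
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        rho, (lo, hi) = spearman_rho(x, y)
        assert lo < rho < hi
        # closed-form check of the half-width on the z scale
        z = math.atanh(rho)
        half = 1.959963984540054 / math.sqrt(27)
        assert lo == pytest.approx(math.tanh(z - half))
        assert hi == pytest.approx(math.tanh(z + half))

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 2, 3], [1, 2, 3])  # too short
        with pytest.raises(ValueError, match="variance"):
            spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])


class TestCronbachAlpha:
    def test_two_identical_items_give_one(self, rng):
        item = rng.normal(size=50)
        assert cronbach_alpha(np.column_stack([item, item])) == pytest.approx(1.0)

    def test_spearman_brown_closed_form(self, rng):
        # common inter-item correlation r -> alpha = k r / (1 + (k-1) r)
        k, n, r = 6, 20000, 0.4
        common = rng.normal(size=n)
        lam = math.sqrt(r)
        grid = lam * common[:, None] + math.sqrt(1 - r) * rng.normal(size=(n, k))
        expected = k * r / (1 + (k - 1) * r)
        assert cronbach_alpha(grid) == pytest.approx(expected, abs=0.02)

    def test_independent_items_give_near_zero(self, rng):
        grid = rng.normal(size=(20000, 5))
        assert abs(cronbach_alpha(grid)) < 0.03

    def test_matches_pingouin(self, rng):
        import pandas as pd
        import pingouin as pg

        grid = rng.integers(0, 5, size=(40, 6)).astype(float)
        ours = cronbach_alpha(grid)
        theirs = pg.cronbach_alpha(pd.DataFrame(grid))[0]
        assert ours == pytest.approx(theirs, abs=1e-10)


# ---------------------------------------------------------------------------
# mutual-information agreement
# ---------------------------------------------------------------------------


class TestMIAgreement:
    def test_independence_table_has_zero_information(self):
        counts = np.outer([10, 20, 30], [5, 15]).astype(int)
        table = AgreementTable(
            counts=counts,
            row_labels=("a", "b", "c"),
            col_labels=("x", "y"),
            agreement_cells=frozenset({(0, 0), (1, 0), (2, 1)}),
        )
        res = mi_agreement(table)
        assert res.i_total == pytest.approx(0.0, abs=1e-12)
        assert res.g_stat == pytest.approx(0.0, abs=1e-9)
        assert res.verdict == "disagreement"

    def test_diagonal_table_is_pure_agreement(self):
        counts = np.diag([8, 12, 20]).astype(int)
        table = AgreementTable(
            counts=counts,
            row_labels=("a", "b", "c"),
            col_labels=("x", "y", "z"),
            agreement_cells=frozenset({(0, 0), (1, 1), (2, 2)}),
        )
        res = mi_agreement(table)
        assert res.i_disagreement == pytest.approx(0.0, abs=1e-12)
        assert res.i_agreement == pytest.approx(res.i_total)
        assert res.i_total > 0
        assert res.verdict == "agreement"

    def test_decomposition_identity_on_random_tables(self, rng):
        for _ in range(300):
            res = mi_agreement(random_table(rng))
            assert res.i_agreement + res.i_disagreement == pytest.approx(
                res.i_total, abs=1e-12
            )

    def test_g_statistic_matches_scipy_log_likelihood_ratio(self, rng):
        for _ in range(40):
            table = random_table(rng)
            counts = table.counts
            # scipy needs all-positive marginals
            if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
                continue
            res = mi_agreement(table)
            g_ref = stats.chi2_contingency(
                counts, correction=False, lambda_="log-likelihood"
            ).statistic
            assert res.g_stat == pytest.approx(g_ref, rel=1e-9, abs=1e-9)

    def test_pearson_variant_matches_scipy(self, rng):
        table = random_table(rng)
        counts = table.counts
        if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
            counts = counts + 1
            table = AgreementTable(
                counts=counts,
                row_labels=table.row_labels,
                col_labels=table.col_labels,
                agreement_cells=table.agreement_cells,
            )
        res = mi_agreement(table, statistic="pearson")
        ref = stats.chi2_contingency(table.counts, correction=False).statistic
        assert res.g_stat == pytest.approx(ref, rel=1e-9)

    def test_degrees_of_freedom_by_shape(self, rng):
        four_by_two = agreement_table_from_vectors(
            list(np.repeat([0, 1, 2, 3], 5)),
            list(np.tile([0, 1], 10)),
            row_labels=("none", "mild", "moderate", "severe"),
            col_labels=("not_at_risk", "at_risk"),
        )
        assert mi_agreement(four_by_two).df == 3
        four_by_three = agreement_table_from_vectors(
            list(np.repeat([0, 1, 2, 3], 6)),
            list(np.tile([0, 1, 2], 8)),
            row_labels=("none", "mild", "moderate", "severe"),
            col_labels=("good", "middling", "poor"),
        )
        assert mi_agreement(four_by_three).df == 6

    def test_permutation_invariance(self, rng):
        table = random_table(rng)
        r, c = table.counts.shape
        pr, pc = rng.permutation(r), rng.permutation(c)
        permuted = AgreementTable(
            counts=table.counts[np.ix_(pr, pc)],
            row_labels=tuple(table.row_labels[i] for i in pr),
            col_labels=tuple(table.col_labels[j] for j in pc),
            agreement_cells=frozenset(
                (int(np.where(pr == i)[0][0]), int(np.where(pc == j)[0][0]))
                for i, j in table.agreement_cells
            ),
        )
        a, b = mi_agreement(table), mi_agreement(permuted)
        assert a.i_agreement == pytest.approx(b.i_agreement, abs=1e-12)
        assert a.i_disagreement == pytest.approx(b.i_disagreement, abs=1e-12)
        assert a.g_stat == pytest.approx(b.g_stat, abs=1e-9)
        assert a.df == b.df and a.verdict == b.verdict

    def test_single_column_table_degenerate(self):
        table = AgreementTable(
            counts=np.array([[5], [5]]),
            row_labels=("a", "b"),
            col_labels=("x",),
            agreement_cells=frozenset({(0, 0)}),
        )
        res = mi_agreement(table)
        assert res.df == 0 and res.p_value is None
        assert res.verdict == "disagreement"

    def test_default_ordinal_band_mapping(self):
        assert ordinal_band_cells(4, 2) == frozenset({(0, 0), (1, 0), (2, 1), (3, 1)})
        assert ordinal_band_cells(4, 3) == frozenset({(0, 0), (1, 1), (2, 1), (3, 2)})


class TestChiSquareHomogeneity:
    def test_identical_rows_give_zero(self):
        statistic, df, p = chi_square_homogeneity(np.array([[10, 20, 30], [10, 20, 30]]))
        assert statistic == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_two_by_two_matches_hand_formula(self):
        table = np.array([[10, 20], [20, 10]])
        statistic, df, _ = chi_square_homogeneity(table)
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        by_hand = ((table - expected) ** 2 / expected).sum()
        assert statistic == pytest.approx(by_hand)
        assert df == 1

    def test_degrees_of_freedom_four_by_ten(self, rng):
        statistic, df, _ = chi_square_homogeneity(rng.integers(1, 30, (4, 10)))
        assert df == 27

    def test_zero_expected_cell_rejected(self):
        with pytest.raises(ValueError, match="expected"):
            chi_square_homogeneity(np.array([[0, 10], [0, 20]]))
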