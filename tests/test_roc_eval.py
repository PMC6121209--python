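"""ROC engine: exact cutoff metrics, empirical ROC, AUC identities."""

import math
from fractions import Fraction

import pytest
from hypothesis import given
from hypothesis import strategies as st

from ichscores import (
    ScoreOutcomeTable,
    auc,
    evaluate_scores,
    group_mean_score,
    metrics_at_cutoff,
    roc_points,
    stratum_mortality,
    youden_optimal_cutoff,
)
from ichscores.roc_eval import (
    DegenerateTableError,
    round_half_up,
    trapezoid_auc,
)


def brute_force_metrics(table: ScoreOutcomeTable, cutoff: int):
    """Independent oracle: expand counts into individual patients and
    classify them one by one."""
    tp = fp = fn = tn = 0
    for score, died in table.materialize():
        positive = score >= cutoff
        if positive and died:
            tp += 1
        elif positive:
            fp += 1
        elif died:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


@st.composite
def small_tables(draw):
    """Random count tables with at least one patient per outcome."""
    k = draw(st.integers(2, 6))
    scores = tuple(sorted(draw(
        st.sets(st.integers(-5, 15), min_size=k, max_size=k)
    )))
    dead = tuple(draw(st.lists(st.integers(0, 8), min_size=k, max_size=k)))
    alive = tuple(draw(st.lists(st.integers(0, 8), min_size=k, max_size=k)))
    if sum(dead) == 0:
        dead = dead[:-1] + (1,)
    if sum(alive) == 0:
        alive = (1,) + alive[1:]
    return ScoreOutcomeTable(scores, dead, alive)


class TestMetricsAtCutoff:
    def test_observed_ich_counts_at_printed_cutoff(self, ich_table):
        m = metrics_at_cutoff(ich_table, 2)
        assert m.sensitivity == Fraction(53, 61)
        assert m.specificity == Fraction(29, 46)
        assert round_half_up(m.sensitivity * 100) == 87
        assert round_half_up(m.specificity * 100) == 63
        assert round_half_up(m.lr_pos, 2) == 2.35
        assert round_half_up(m.lr_neg, 2) == 0.21
        assert round_half_up(m.youden_j, 2) == 0.50

    def test_observed_ich_counts_at_cutoff_three(self, ich_table):
        m = metrics_at_cutoff(ich_table, 3)
        assert m.sensitivity == Fraction(38, 61)
        assert m.specificity == Fraction(44, 46)
        assert round_half_up(m.youden_j, 3) == 0.579

    def test_cutoff_below_minimum_marks_everyone_positive(self, ich_table):
        m = metrics_at_cutoff(ich_table, -1)
        assert m.sensitivity == 1
        assert m.specificity == 0
        assert m.npv is None
        assert m.lr_pos == 1  # sens/(1-spec) = 1/1

    def test_perfect_specificity_gives_infinite_lr_pos(self):
        t = ScoreOutcomeTable((0, 1), (0, 3), (4, 0))
        m = metrics_at_cutoff(t, 1)
        assert m.specificity == 1
        assert math.isinf(m.lr_pos)
        assert m.youden_j == 1

    def test_degenerate_table_rejected(self):
        t = ScoreOutcomeTable((0, 1), (2, 3), (0, 0))
        with pytest.raises(DegenerateTableError):
            metrics_at_cutoff(t, 1)

    @given(small_tables(), st.integers(-6, 17))
    def test_agrees_with_patient_materializing_oracle(self, table, cutoff):
        m = metrics_at_cutoff(table, cutoff)
        tp, fp, fn, tn = brute_force_metrics(table, cutoff)
        assert (m.tp, m.fp, m.fn, m.tn) == (tp, fp, fn, tn)
        assert m.sensitivity == Fraction(tp, tp + fn)
        assert m.specificity == Fraction(tn, tn + fp)
        assert m.youden_j == m.sensitivity + m.specificity - 1

    @given(small_tables())
    def test_sensitivity_falls_and_specificity_rises_with_cutoff(self, table):
        cutoffs = range(table.score_values[0] - 1, table.score_values[-1] + 2)
        ms = [metrics_at_cutoff(table, c) for c in cutoffs]
        for a, b in zip(ms, ms[1:]):
            assert b.sensitivity <= a.sensitivity
            assert b.specificity >= a.specificity


class TestRocPoints:
    def test_endpoints_and_monotonicity(self, ich_table):
        pts = roc_points(ich_table)
        assert len(pts) == 8  # 7 score values + the all-negative endpoint
        assert (pts[0].fpr, pts[0].tpr) == (0, 0)
        assert (pts[-1].fpr, pts[-1].tpr) == (1, 1)
        for a, b in zip(pts, pts[1:]):
            assert b.fpr >= a.fpr and b.tpr >= a.tpr
        # a discriminating score stays on or above the diagonal
        assert all(p.tpr >= p.fpr for p in pts)

    def test_single_score_value_collapses_to_diagonal(self):
        t = ScoreOutcomeTable((3,), (5,), (4,))
        pts = roc_points(t)
        assert [(p.fpr, p.tpr) for p in pts] == [(0, 0), (1, 1)]

    def test_perfectly_separated_curve_passes_through_corner(self):
        t = ScoreOutcomeTable((0, 5), (0, 7), (6, 0))
        assert any(p.fpr == 0 and p.tpr == 1 for p in roc_points(t))


class TestAuc:
    def test_observed_tables_reproduce_reported_aucs(self, ich_table, modified_table):
        assert round_half_up(auc(ich_table), 3) == 0.855
        assert round_half_up(auc(modified_table), 3) == 0.826

    def test_all_tied_scores_give_half(self):
        t = ScoreOutcomeTable((2,), (7,), (5,))
        assert auc(t) == Fraction(1, 2)

    @given(small_tables())
    def test_pair_count_equals_trapezoid_exactly(self, table):
        assert auc(table) == trapezoid_auc(table)

    @given(small_tables())
    def test_swapping_outcomes_reflects_auc(self, table):
        assert auc(table.swapped()) == 1 - auc(table)

    @given(small_tables())
    def test_invariant_under_monotone_relabeling(self, table):
        relabeled = ScoreOutcomeTable(
            tuple(2 * s**3 + s + 1 for s in table.score_values),
            table.dead_counts,
            table.alive_counts,
        )
        assert auc(relabeled) == auc(table)

    @given(small_tables())
    def test_matches_sklearn(self, table):
        """Independent cross-check against scikit-learn's Mann-Whitney AUC."""
        from sklearn.metrics import roc_auc_score

        patients = table.materialize()
        y = [int(d) for _, d in patients]
        x = [s for s, _ in patients]
        assert float(auc(table)) == pytest.approx(roc_auc_score(y, x), abs=1e-12)


class TestYoudenOptimalCutoff:
    def test_perfect_separation_reaches_j_of_one(self):
        t = ScoreOutcomeTable((0, 5), (0, 7), (6, 0))
        cutoff, j = youden_optimal_cutoff(t)
        assert cutoff == 5 and j == 1

    def test_observed_tables(self, ich_table, modified_table):
        cutoff, j = youden_optimal_cutoff(ich_table)
        assert cutoff == 3 and round_half_up(j, 3) == 0.579
        cutoff, j = youden_optimal_cutoff(modified_table)
        assert cutoff == 4 and round_half_up(j, 3) == 0.569

    @given(small_tables())
    def test_maximizes_j_over_every_cutoff(self, table):
        cutoff, j = youden_optimal_cutoff(table)
        for c in range(table.score_values[0] - 1, table.score_values[-1] + 2):
            other = metrics_at_cutoff(table, c).youden_j
            assert j >= other
            # ties break toward the lower candidate cutoff; candidates are
            # the observed scores plus one above the maximum (other integers
            # classify identically to the next candidate up)
            candidates = set(table.score_values) | {table.score_values[-1] + 1}
            if other == j and c in candidates:
                assert cutoff <= c


class TestStratumMortalityAndMeans:
    def test_observed_strata(self, ich_table, modified_table):
        ich = stratum_mortality(ich_table)
        assert round_half_up(ich[0] * 100, 1) == 18.2
        mod = stratum_mortality(modified_table)
        assert mod[6] == 1
        assert mod[0] == 0 and mod[1] == 0

    def test_empty_stratum_is_undefined_not_zero(self):
        t = ScoreOutcomeTable((0, 1, 2), (1, 0, 3), (2, 0, 1))
        assert stratum_mortality(t)[1] is None

    def test_observed_group_means(self, ich_table, modified_table):
        assert round_half_up(group_mean_score(ich_table, "dead"), 2) == 2.90
        assert round_half_up(group_mean_score(modified_table, "dead"), 2) == 3.90
        assert round_half_up(group_mean_score(ich_table, "alive"), 2) == 1.22

    def test_single_stratum_mean_is_that_score(self):
        t = ScoreOutcomeTable((4,), (3,), (2,))
        assert group_mean_score(t, "dead") == 4
        assert group_mean_score(t, "alive") == 4

    def test_empty_group_rejected(self):
        t = ScoreOutcomeTable((0,), (3,), (0,))
        with pytest.raises(DegenerateTableError):
            group_mean_score(t, "alive")


class TestEvaluateScores:
    def test_two_patient_separated_cohort_has_auc_one(self):
        import pandas as pd

        df = pd.DataFrame({"s_score": [5, 1], "dead_30d": [1, 0]})
        report = evaluate_scores(df, "dead_30d")
        assert report["scores"]["s_score"]["auc"]["value"] == 1.0

    def test_row_order_invariance(self, ich_table):
        import pandas as pd

        patients = ich_table.materialize()
        df = pd.DataFrame(
            {"ich_score": [s for s, _ in patients],
             "dead_30d": [d for _, d in patients]}
        )
        r1 = evaluate_scores(df, "dead_30d", cutoffs=[2])
        r2 = evaluate_scores(
            df.iloc[::-1].reset_index(drop=True), "dead_30d", cutoffs=[2]
        )
        assert r1 == r2

    def test_report_matches_table_level_computation(self, ich_table):
        report = evaluate_scores(ich_table, cutoffs=[2])
        block = report["scores"]["score"]
        assert block["auc"]["value"] == 0.855
        assert block["metrics_at_cutoffs"]["2"]["sensitivity_pct"] == 87
        assert block["youden_optimal"] == {"cutoff": 3, "j": 0.579}

    def test_single_outcome_cohort_rejected(self):
        import pandas as pd

        df = pd.DataFrame({"s_score": [1, 2, 3], "dead_30d": [0, 0, 0]})
        with pytest.raises(DegenerateTableError):
            evaluate_scores(df, "dead_30d")
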