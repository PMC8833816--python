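"""Diagnostic metrics: 2x2 bookkeeping, exact CIs, McNemar, subgroups."""

import numpy as np
import pytest
from scipy.stats import binom
from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

from ovatriage import (
    TwoByTwo,
    UltrasoundExam,
    compare_strategies,
    confusion_table,
    make_cohort,
    mcnemar_paired,
    proportion_ci,
    run_all_strategies,
    sens_spec_accuracy,
    subgroup_analysis,
)
from ovatriage.metrics import PredictionIntegrityError

from .test_cohort import make_valid_record


def pct1(numerator: int, denominator: int) -> float:
    """Exact half-up rounding of a count ratio to one decimal of a percent."""
    return ((2000 * numerator + denominator) // (2 * denominator)) / 10


class TestTwoByTwo:
    def test_conservation_identities(self):
        t = TwoByTwo(tp=64, fp=26, fn=15, tn=66)
        assert t.n == 171 and t.diseased == 79 and t.non_diseased == 92

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            TwoByTwo(tp=-1, fp=0, fn=0, tn=0)


class TestSensSpecAccuracy:
    @pytest.mark.parametrize(
        "counts, expected",  # published worked examples, 1 d.p. of a percent
        [
            ((64, 26, 15, 66), (81.0, 71.7, 76.0)),  # expert, inconclusive stratum
            ((50, 25, 29, 67), (63.3, 72.8, 68.4)),  # ROMA, inconclusive stratum
            ((96, 10, 23, 390), (80.7, 97.5, 93.6)),  # IOTA, conclusive stratum
            ((97, 59, 22, 341), (81.5, 85.3, 84.4)),  # ROMA, conclusive stratum
            ((84, 23, 35, 377), (70.6, 94.3, 88.8)),  # RMI, conclusive stratum
        ],
    )
    def test_worked_examples_reproduce_published_points(self, counts, expected):
        est = sens_spec_accuracy(TwoByTwo(*counts))
        for m, value in zip(("sensitivity", "specificity", "accuracy"), expected):
            assert est[m].point == est[m].numerator / est[m].denominator
            assert pct1(est[m].numerator, est[m].denominator) == value

    def test_perfect_classifier_on_two_records(self):
        est = sens_spec_accuracy(TwoByTwo(1, 0, 0, 1))
        for m in ("sensitivity", "specificity", "accuracy"):
            assert est[m].point == 1.0
            assert est[m].ci_high == 1.0

    def test_zero_denominator_flagged_undefined(self):
        est = sens_spec_accuracy(TwoByTwo(tp=3, fp=0, fn=1, tn=0))  # no benign masses
        assert not est["specificity"].defined
        assert est["sensitivity"].defined and est["sensitivity"].point == 0.75


class TestProportionCi:
    def test_boundary_cases_hit_zero_and_one_exactly(self):
        assert proportion_ci(0, 10, "clopper_pearson")[0] == 0.0
        assert proportion_ci(10, 10, "clopper_pearson")[1] == 1.0

    def test_exact_beta_quantile_oracle(self):
        # beta.ppf(0.025, 64, 16) / beta.ppf(0.975, 65, 15), frozen
        low, high = proportion_ci(64, 79, "clopper_pearson")
        assert low == pytest.approx(0.7062415403812735, abs=1e-12)
        assert high == pytest.approx(0.8896524755629918, abs=1e-12)

    @pytest.mark.parametrize("method", ["clopper_pearson", "wilson"])
    def test_interval_contains_point_and_stays_in_unit_interval(self, method):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(1, 500))
            x = int(rng.integers(0, n + 1))
            low, high = proportion_ci(x, n, method)
            assert 0.0 <= low <= x / n <= high <= 1.0


class TestMcNemar:
    def test_symmetric_discordance_gives_p_one(self):
        assert mcnemar_paired([True] * 5 + [False] * 5, [False] * 5 + [True] * 5).p_exact == 1.0

    def test_hand_enumerated_binomial_tail(self):
        # b=9, c=1: 2 * P(X <= 1 | n=10, p=1/2) = 2 * 11/1024
        a = [True] * 9 + [False] * 1 + [True] * 5
        b = [False] * 9 + [True] * 1 + [True] * 5
        cmp = mcnemar_paired(a, b)
        assert (cmp.b, cmp.c) == (9, 1)
        assert cmp.p_exact == pytest.approx(0.021484375, abs=1e-15)

    def test_no_discordance_convention(self):
        cmp = mcnemar_paired([True, False], [True, False])
        assert cmp.p_exact == 1.0 and cmp.p_cc == 1.0 and cmp.statistic == 0.0

    def test_antisymmetric_under_swapping_methods(self):
        rng = np.random.default_rng(3)
        a = rng.random(60) < 0.8
        b = rng.random(60) < 0.7
        ab, ba = mcnemar_paired(a, b), mcnemar_paired(b, a)
        assert (ab.b, ab.c) == (ba.c, ba.b)
        assert ab.p_exact == ba.p_exact and ab.p_cc == ba.p_cc

    @pytest.mark.parametrize("b, c", [(0, 7), (3, 4), (2, 10), (6, 6), (1, 0)])
    def test_exact_p_equals_brute_force_enumeration(self, b, c):
        nd = b + c
        k = min(b, c)
        brute = min(1.0, 2 * sum(binom.pmf(i, nd, 0.5) for i in range(k + 1)))
        a_vec = [True] * b + [False] * c
        b_vec = [False] * b + [True] * c
        assert mcnemar_paired(a_vec, b_vec).p_exact == pytest.approx(brute, abs=1e-12)

    def test_agrees_with_statsmodels_exact_mcnemar(self):
        for b, c in [(9, 1), (3, 8), (0, 5), (12, 10)]:
            table = [[0, b], [c, 0]]
            expected = float(sm_mcnemar(table, exact=True).pvalue)
            a_vec = [True] * b + [False] * c
            b_vec = [False] * b + [True] * c
            assert mcnemar_paired(a_vec, b_vec).p_exact == pytest.approx(expected, abs=1e-12)

    def test_misaligned_vectors_rejected(self):
        with pytest.raises(PredictionIntegrityError):
            mcnemar_paired([True, False], [True])


def tiny_cohort():
    """Eight hand-built records covering both truths and all IOTA calls."""
    exam_mal = UltrasoundExam(colour_score=2, m_irregular_solid=True)
    exam_ben = UltrasoundExam(colour_score=2, b_unilocular=True)
    exam_inc = UltrasoundExam(colour_score=2)
    spec = [
        # (id, histology, exam, he4, ca125, expert)
        ("A", "malignant", exam_mal, 500.0, 800.0, "malignant"),
        ("B", "malignant", exam_inc, 500.0, 800.0, "malignant"),
        ("C", "malignant", exam_ben, 20.0, 10.0, "benign"),
        ("D", "borderline", exam_inc, 20.0, 10.0, "benign"),
        ("E", "benign", exam_ben, 20.0, 10.0, "benign"),
        ("F", "benign", exam_inc, 500.0, 800.0, "malignant"),
        ("G", "benign", exam_ben, 500.0, 800.0, "benign"),
        ("H", "benign", exam_inc, 20.0, 10.0, "benign"),
    ]
    return make_cohort(
        [
            make_valid_record(
                pid, histology=h, exam=e, he4=he4, ca125=ca, expert_call=x, menopausal="post"
            )
            for pid, h, e, he4, ca, x in spec
        ]
    )


class TestConfusionTable:
    def test_counts_match_hand_tally(self):
        cohort = tiny_cohort()
        predictions = run_all_strategies(cohort)
        # IOTA_EXPERT: A high, B high, C low, D low, E low, F high, G low, H low
        table = confusion_table(predictions, cohort, "IOTA_EXPERT")
        assert (table.tp, table.fp, table.fn, table.tn) == (2, 1, 2, 3)

    def test_perfect_predictor_has_no_errors(self):
        cohort = tiny_cohort().subset(lambda r: r.patient_id in {"A", "E"})
        predictions = run_all_strategies(cohort)
        table = confusion_table(predictions, cohort, "IOTA_ONLY")
        assert table.fp == 0 and table.fn == 0

    def test_unknown_patient_id_is_an_integrity_error(self):
        cohort = tiny_cohort()
        predictions = run_all_strategies(cohort)
        smaller = cohort.subset(lambda r: r.patient_id != "A")
        with pytest.raises(PredictionIntegrityError):
            confusion_table(predictions, smaller, "IOTA_EXPERT")

    def test_conservation_against_subset_size(self):
        cohort = tiny_cohort()
        predictions = run_all_strategies(cohort)
        table = confusion_table(predictions, cohort, "ROMA_ALONE", subset=lambda r: r.truth_malignant)
        assert table.n == 4 and table.diseased == 4


class TestCompareStrategies:
    def test_strategy_compared_with_itself_is_null(self):
        cohort = tiny_cohort()
        predictions = run_all_strategies(cohort)
        result = compare_strategies(cohort, predictions, "ROMA_ALONE", "ROMA_ALONE")
        for cmp in result.comparisons.values():
            assert cmp.b == cmp.c == 0 and cmp.p_exact == 1.0

    def test_discordant_cells_match_exhaustive_hand_enumeration(self):
        cohort = tiny_cohort()
        predictions = run_all_strategies(cohort)
        result = compare_strategies(cohort, predictions, "IOTA_EXPERT", "ROMA_ALONE")
        # hand enumeration: ROMA alone high iff markers are (500, 800), i.e.
        # A, B, F, G high.  Expert path: A, B, F high (G's conclusive benign
        # IOTA overrides its markers).  Correctness: expert {A,B,E,G,H},
        # ROMA {A,B,E,H} -> G discordant in the expert path's favour.
        acc = result.comparisons["accuracy"]
        assert (acc.b, acc.c) == (1, 0)
        spec = result.comparisons["specificity"]
        assert (spec.b, spec.c) == (1, 0) and spec.n == 4
        sens = result.comparisons["sensitivity"]
        assert (sens.b, sens.c) == (0, 0) and sens.n == 4

    def test_dominance_yields_one_sided_discordance(self):
        cohort = tiny_cohort()
        predictions = run_all_strategies(cohort)
        # IOTA_EXPERT is correct on a strict superset of RMI_ALONE's correct
        # malignant records here: RMI sees u=0 everywhere (no RMI features)
        result = compare_strategies(cohort, predictions, "IOTA_EXPERT", "RMI_ALONE")
        sens = result.comparisons["sensitivity"]
        assert sens.c == 0 and sens.b == 2

    def test_common_subset_excludes_records_missing_components(self):
        cohort = tiny_cohort()
        records = [
            r if r.patient_id != "A" else make_valid_record(
                "A", histology="malignant", exam=r.exam, he4=None, ca125=800.0,
                expert_call="malignant",
            )
            for r in cohort
        ]
        cohort2 = make_cohort(records)
        predictions = run_all_strategies(cohort2)
        result = compare_strategies(cohort2, predictions, "IOTA_EXPERT", "ROMA_ALONE")
        assert result.n_common == 7  # A lacks HE4, excluded from the pair


class TestSubgroupAnalysis:
    def test_iota_conclusiveness_partitions_the_cohort(self, cohort_1k, predictions_1k):
        groups = subgroup_analysis(cohort_1k, predictions_1k, "iota_conclusiveness",
                                   strategies=["ROMA_ALONE"])
        sizes = {name: int(frame.loc[0, "n"]) for name, frame in groups.items()}
        assert set(sizes) == {"conclusive", "inconclusive"}
        assert sum(sizes.values()) == len(cohort_1k)

    def test_menopause_groups_cover_both_statuses(self, cohort_1k, predictions_1k):
        groups = subgroup_analysis(cohort_1k, predictions_1k, "menopause")
        assert set(groups) == {"pre", "post"}

    def test_stage_groups_have_undefined_specificity(self, cohort_1k, predictions_1k):
        groups = subgroup_analysis(cohort_1k, predictions_1k, "figo_stage")
        assert "I" in groups
        frame = groups["I"]
        assert not frame["specificity_defined"].any()
        assert frame["sensitivity_defined"].all()

    def test_empty_groups_are_omitted(self):
        cohort = tiny_cohort()  # nobody staged
        predictions = run_all_strategies(cohort)
        assert subgroup_analysis(cohort, predictions, "figo_stage") == {}
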