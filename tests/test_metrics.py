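"""Hierarchical matching, ERR, IDIAE, risk recall, and comparative arithmetic."""

import itertools

import numpy as np
import pytest

from aekit.metrics import (
    IDIAEConfig,
    SafetyItemList,
    attenuation,
    bleu4,
    correction_factor,
    edit_similarity,
    element_recall_rate,
    idiae,
    match_element,
    relative_improvement,
    risk_recall,
    rouge_l,
    surface_metrics,
)
from aekit.reports import AEReport, PredictionRecord

from conftest import brute_force_levenshtein


class TestMatchElement:
    def test_containment_is_exact(self):
        out = match_element("ABCDE", "XABCDEY")
        assert out.matched and out.mode == "exact"

    def test_fuzzy_below_threshold(self):
        out = match_element("ABCD", "ABXD")
        assert out.similarity == pytest.approx(0.75)
        assert not out.matched and out.mode == "none"

    def test_boundary_is_strict(self):
        # distance 1 over length 5: similarity exactly 0.8, not > 0.8
        out = match_element("ABCDE", "ABCDX")
        assert out.similarity == pytest.approx(0.8)
        assert not out.matched

    def test_fuzzy_match_above_threshold(self):
        out = match_element("ABCDEFGHIJ", "ABCDEFGHIX")
        assert out.matched and out.mode == "fuzzy"
        assert out.similarity == pytest.approx(0.9)

    def test_identical_similarity_one(self):
        assert match_element("xyz", "xyz").similarity == 1.0

    def test_empty_reference_error(self):
        with pytest.raises(ValueError):
            match_element("", "abc")

    def test_unicode_edit_distance(self):
        # character-level distance on Chinese text: 1 substitution over 4 chars
        out = match_element("温度报警", "温度报讯")
        assert out.similarity == pytest.approx(0.75)

    def test_agrees_with_dp_oracle_on_random_pairs(self, rng):
        alphabet = list("abcde温度")
        for _ in range(500):
            a = "".join(rng.choice(alphabet, size=rng.integers(1, 9)))
            b = "".join(rng.choice(alphabet, size=rng.integers(0, 9)))
            expected = (
                1.0
                if a == b
                else (
                    0.0
                    if not b
                    else 1 - brute_force_levenshtein(a, b) / max(len(a), len(b))
                )
            )
            assert edit_similarity(a, b) == pytest.approx(expected)

    def test_threshold_monotonicity(self, rng):
        # raising the threshold never converts a non-match into a match
        alphabet = list("abc")
        for _ in range(1000):
            a = "".join(rng.choice(alphabet, size=rng.integers(1, 7)))
            b = "".join(rng.choice(alphabet, size=rng.integers(1, 7)))
            low = match_element(a, b, threshold=0.5)
            high = match_element(a, b, threshold=0.9)
            if not low.matched:
                assert not high.matched


def _pair(ref_elements, pred_elements, free_text=""):
    ref = AEReport(
        report_id="R1",
        narrative="",
        elements={k: [v] for k, v in ref_elements.items()},
    )
    pred = PredictionRecord(report_id="R1", elements=pred_elements, free_text=free_text)
    return ref, pred


CORE = {
    "occurrence_date": "2023-04-01",
    "abnormal_condition": "temperature alarm triggered",
    "follow_up_measures": "transferred to backup incubator",
}
SECONDARY = {
    "failure_cause": "heating element aging",
    "triggered_risk": "risk of hypothermia",
}


class TestElementRecallRate:
    def test_all_match(self):
        ref, pred = _pair(CORE, dict(CORE))
        assert element_recall_rate([ref], [pred]) == 1.0

    def test_two_of_three(self):
        pred_elements = dict(CORE)
        pred_elements["follow_up_measures"] = "zzzz completely different"
        ref, pred = _pair(CORE, pred_elements)
        assert element_recall_rate([ref], [pred]) == pytest.approx(2 / 3)

    def test_no_predictions_zero(self):
        ref, pred = _pair(CORE, {})
        assert element_recall_rate([ref], [pred]) == 0.0

    def test_unmatched_report_id_error(self):
        ref, _ = _pair(CORE, {})
        other = PredictionRecord(report_id="R2", elements={})
        with pytest.raises(KeyError):
            element_recall_rate([ref], [other])

    def test_mean_over_reports_is_arithmetic_mean(self):
        # oracle: brute-force recount over per-report values
        refs, preds, per_report = [], [], []
        for i, hits in enumerate([3, 1, 0, 2]):
            elements = dict(CORE)
            pe = {}
            for j, k in enumerate(CORE):
                pe[k] = elements[k] if j < hits else "unrelated text qqq"
            r = AEReport(report_id=f"R{i}", narrative="", elements={k: [v] for k, v in elements.items()})
            p = PredictionRecord(report_id=f"R{i}", elements=pe)
            refs.append(r)
            preds.append(p)
            per_report.append(hits / 3)
        assert element_recall_rate(refs, preds) == pytest.approx(np.mean(per_report))


class TestCorrectionFactor:
    @pytest.mark.parametrize(
        "n_red,m_error,expected",
        [(0, 0, 1.0), (10, 1, 1.3), (20, 1, 1.4), (5, 0, 1.05), (0, 3, 1.6)],
    )
    def test_formula(self, n_red, m_error, expected):
        assert correction_factor(n_red, m_error) == pytest.approx(expected)

    def test_negative_counts_error(self):
        with pytest.raises(ValueError):
            correction_factor(-1, 0)


class TestIDIAE:
    def test_perfect_report_scores_one(self, perfect_pair):
        ref, pred = perfect_pair
        bd = idiae(ref, pred, n_red=0, m_error=0)
        assert bd.score == pytest.approx(1.0)
        assert bd.beta == 1.0

    def test_partial_coverage_with_penalties(self):
        # 3 core + 1 secondary covered, N_red=20, M_error=1:
        # (3 + 0.8) / (4.6 * 1.4) = 0.5901 by hand arithmetic
        elements = {**CORE, **SECONDARY}
        pe = {k: v for k, v in elements.items() if k != "triggered_risk"}
        ref, pred = _pair(elements, pe)
        bd = idiae(ref, pred, n_red=20, m_error=1)
        assert bd.beta == pytest.approx(1.4)
        assert bd.score == pytest.approx(3.8 / (4.6 * 1.4), abs=1e-4)
        assert bd.score == pytest.approx(0.5901, abs=1e-4)

    def test_field_count_normalization(self):
        elements = {**CORE, **SECONDARY}
        ref, pred = _pair(elements, dict(elements))
        cfg = IDIAEConfig(normalization_mode="field_count")
        bd = idiae(ref, pred, cfg, n_red=0, m_error=0)
        assert bd.score == pytest.approx(4.6 / 5)

    def test_monotone_in_n_red(self):
        elements = {**CORE, **SECONDARY}
        ref, pred = _pair(elements, dict(elements))
        scores = [idiae(ref, pred, n_red=n, m_error=0).score for n in range(0, 50, 5)]
        assert all(a > b for a, b in zip(scores, scores[1:]))

    def test_monotone_in_m_error(self):
        elements = {**CORE, **SECONDARY}
        ref, pred = _pair(elements, dict(elements))
        scores = [idiae(ref, pred, n_red=0, m_error=m).score for m in range(5)]
        assert all(a > b for a, b in zip(scores, scores[1:]))

    def test_score_bounded_by_uncorrected(self):
        elements = {**CORE, **SECONDARY}
        ref, pred = _pair(elements, dict(elements))
        assert (
            idiae(ref, pred, n_red=30, m_error=2).score
            <= idiae(ref, pred, n_red=0, m_error=0).score
        )

    def test_empty_reference_error(self):
        ref = AEReport(report_id="R1", narrative="", elements={})
        pred = PredictionRecord(report_id="R1", elements={})
        with pytest.raises(ValueError):
            idiae(ref, pred)

    def test_detection_counts_injected_noise(self):
        elements = {**CORE, **SECONDARY}
        pe = {k: v for k, v in elements.items()}
        free = " ".join(pe.values()) + " zqxjkwvz incubatar"
        ref, pred = _pair(elements, pe, free_text=free)
        bd = idiae(ref, pred, term_lexicon=["incubator"])
        assert bd.n_red >= 8  # the injected garbage characters
        assert bd.m_error == 1  # 'incubatar' is a near-miss of 'incubator'


class TestRiskRecall:
    def test_conservation_identity(self, rng):
        items = list(SafetyItemList().items)
        sets = [list(rng.choice(items, size=rng.integers(0, 7), replace=False)) for _ in range(40)]
        recall, mean_count = risk_recall(sets)
        assert recall == pytest.approx(mean_count / 6)

    def test_printed_example(self):
        # mean 5.52 identified items over the 6-item list -> recall 0.92
        items = list(SafetyItemList().items)
        # construct 25 reports averaging 5.52: 13 with 6 items, 12 with 5
        sets = [items] * 13 + [items[:5]] * 12
        recall, mean_count = risk_recall(sets)
        assert mean_count == pytest.approx(5.52)
        assert recall == pytest.approx(0.92)

    def test_all_and_half(self):
        items = list(SafetyItemList().items)
        assert risk_recall([items, items])[0] == 1.0
        assert risk_recall([items[:3]])[0] == 0.5

    def test_unknown_item_error(self):
        with pytest.raises(ValueError):
            risk_recall([["not_a_safety_item"]])


class TestComparativeArithmetic:
    @pytest.mark.parametrize(
        "value,baseline,expected",
        [
            (0.215, 0.137, 56.9),
            (0.215, 0.162, 32.7),
            (0.484, 0.315, 53.7),
            (0.815, 0.691, 17.9),
            (0.815, 0.715, 14.0),
            (0.5, 0.5, 0.0),
        ],
    )
    def test_relative_improvement(self, value, baseline, expected):
        assert relative_improvement(value, baseline) == expected

    @pytest.mark.parametrize(
        "short,long,expected",
        [(0.847, 0.810, 4.4), (0.834, 0.766, 8.2), (0.829, 0.739, 10.9), (0.7, 0.7, 0.0)],
    )
    def test_attenuation(self, short, long, expected):
        assert attenuation(short, long) == expected

    def test_degenerate_baselines_error(self):
        with pytest.raises(ValueError):
            relative_improvement(0.5, 0.0)
        with pytest.raises(ValueError):
            attenuation(0.0, 0.1)


class TestSurfaceMetrics:
    def test_identical_strings(self):
        out = surface_metrics("a b c d", "a b c d")
        assert out["rouge_l"] == 1.0
        assert out["bleu4"] == pytest.approx(1.0)

    def test_disjoint_tokens(self):
        assert rouge_l("a b c", "x y z") == 0.0
        assert bleu4("a b c d e", "x y z w v") == 0.0

    def test_rouge_l_partial(self):
        # LCS("a b c d", "a c d e") = 3; P = R = 3/4 -> F1 = 3/4
        assert rouge_l("a b c d", "a c d e") == pytest.approx(0.75)

    def test_empty_text_error(self):
        with pytest.raises(ValueError):
            surface_metrics("", "x")
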