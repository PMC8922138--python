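"""Validation metrics: exact fractions, rounding, kappa, yields."""

from __future__ import annotations

import random
from fractions import Fraction

import pytest
from hypothesis import given
from hypothesis import strategies as st

from wellsauto.models import COMPONENT_NAMES, GoldAnnotation
from wellsauto.scoring import WellsResult, compute_wells_score
from wellsauto.validation import (
    ConfusionCounts,
    Rate,
    classification_metrics,
    cohen_kappa,
    component_metrics,
    ctpa_yield,
    percent_string,
    round_half_away,
)

from conftest import make_components


class TestRounding:
    @pytest.mark.parametrize(
        "frac, decimals, expected",
        [
            (Fraction(119 + 67, 202), 1, "92.1"),
            (Fraction(119, 128), 1, "93.0"),
            (Fraction(67, 74), 1, "90.5"),
            (Fraction(119, 126), 1, "94.4"),
            (Fraction(67, 76), 1, "88.2"),
            (Fraction(151, 202), 1, "74.8"),
        ],
    )
    def test_one_decimal_half_away(self, frac, decimals, expected):
        assert percent_string(frac, decimals) == expected

    def test_adaptive_precision(self):
        assert percent_string(Fraction(28, 202)) == "14"
        assert percent_string(Fraction(7, 202)) == "3.5"
        assert percent_string(Fraction(8, 155)) == "5.2"
        assert percent_string(Fraction(0, 180)) == "0"
        assert percent_string(Fraction(87, 87)) == "100"

    def test_half_rounds_away_from_zero(self):
        assert round_half_away(Fraction(1, 2), 0) == 1
        assert round_half_away(Fraction(-1, 2), 0) == -1
        assert round_half_away(Fraction(145, 1000), 2) == Fraction(15, 100)
        assert float(round_half_away(Fraction(25, 1000) * 100, 1)) == 2.5


class TestClassificationMetrics:
    def test_confusion_119_7_9_67(self):
        m = classification_metrics(ConfusionCounts(tp=119, fp=7, fn=9, tn=67))
        assert m.as_percent_dict() == {
            "accuracy": 92.1,
            "sensitivity": 93.0,
            "specificity": 90.5,
            "ppv": 94.4,
            "npv": 88.2,
        }

    def test_zero_denominator_rates_absent(self):
        m = classification_metrics(ConfusionCounts(tp=0, fp=0, fn=0, tn=10))
        assert m.accuracy.fraction == 1
        assert m.sensitivity is None
        assert m.ppv is None
        assert m.specificity is not None

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fp=0, fn=0, tn=0)

    @given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=1, max_size=60))
    def test_counts_match_brute_force_recount(self, pairs):
        gold = [g for g, _ in pairs]
        auto = [a for _, a in pairs]
        cc = ConfusionCounts.from_labels(gold, auto)
        # independent recount straight from the label lists
        assert cc.tp == sum(g and a for g, a in pairs)
        assert cc.fp == sum((not g) and a for g, a in pairs)
        assert cc.fn == sum(g and not a for g, a in pairs)
        assert cc.tn == sum(not g and not a for g, a in pairs)
        m = classification_metrics(cc)
        assert m.accuracy.fraction == Fraction(sum(g == a for g, a in pairs), len(pairs))

    @given(
        st.integers(0, 50), st.integers(0, 50), st.integers(0, 50), st.integers(1, 50)
    )
    def test_accuracy_identity(self, tp, fp, fn, tn):
        cc = ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)
        m = classification_metrics(cc)
        p, n = tp + fn, tn + fp
        lhs = m.accuracy.fraction * (p + n)
        rhs = (m.sensitivity.fraction * p if p else 0) + (
            m.specificity.fraction * n if n else 0
        )
        assert lhs == rhs

    def test_cross_check_against_sklearn(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = random.Random(7)
        gold = [rng.random() < 0.6 for _ in range(200)]
        auto = [g if rng.random() < 0.9 else not g for g in gold]
        cc = ConfusionCounts.from_labels(gold, auto)
        tn, fp, fn, tp = sklearn_metrics.confusion_matrix(gold, auto).ravel()
        assert (cc.tp, cc.fp, cc.fn, cc.tn) == (tp, fp, fn, tn)


class TestCohenKappa:
    def test_perfect_agreement(self):
        assert cohen_kappa([1, 0, 1, 0], [1, 0, 1, 0]) == 1.0

    def test_hand_computed_zero(self):
        # p_o = 0.5 and p_e = 0.5 -> kappa 0
        assert cohen_kappa((1, 1, 0, 0), (1, 0, 1, 0)) == 0.0

    def test_constant_identical_raters(self):
        assert cohen_kappa([1, 1, 1], [1, 1, 1]) == 1.0

    def test_symmetric_and_label_renaming_invariant(self):
        rng = random.Random(3)
        a = [rng.random() < 0.4 for _ in range(300)]
        b = [x if rng.random() < 0.85 else not x for x in a]
        k = cohen_kappa(a, b)
        assert k == pytest.approx(cohen_kappa(b, a))
        renamed = cohen_kappa(["x" if v else "y" for v in a], ["x" if v else "y" for v in b])
        assert k == pytest.approx(renamed)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            cohen_kappa([1], [1, 0])

    def test_asymmetric_disagreement_matches_closed_form(self):
        """kappa on a simulated rater pair approaches the closed-form value
        of the generating process (rater B flips A's positives w.p. q)."""
        p, q, n = 0.35, 0.03, 20000
        rng = random.Random(11)
        a = [rng.random() < p for _ in range(n)]
        b = [x and not (rng.random() < q) for x in a]
        pb = p * (1 - q)
        p_o = 1 - p * q
        p_e = p * pb + (1 - p) * (1 - pb)
        expected = (p_o - p_e) / (1 - p_e)
        assert cohen_kappa(a, b) == pytest.approx(expected, abs=0.02)

    def test_cross_check_against_sklearn(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = random.Random(5)
        a = [rng.randrange(2) for _ in range(500)]
        b = [x if rng.random() < 0.8 else rng.randrange(2) for x in a]
        assert cohen_kappa(a, b) == pytest.approx(
            sklearn_metrics.cohen_kappa_score(a, b)
        )


def _gold(eid: str, pe: bool = False, **comps) -> GoldAnnotation:
    values = {n: comps.get(n, False) for n in COMPONENT_NAMES if n != "gestalt"}
    tier = compute_wells_score(make_components(**values)).tier
    return GoldAnnotation(encounter_id=eid, tier=tier, pe_diagnosed=pe, **values)


class TestComponentMetrics:
    def test_identical_auto_and_gold(self):
        gold = [
            _gold("a", dvt_signs=True, tachycardia=True),
            _gold("b", hemoptysis=True),
            _gold("c"),
        ]
        auto = {
            g.encounter_id: make_components(
                **{n: g.component(n) for n in COMPONENT_NAMES}
            )
            for g in gold
        }
        metrics, pooled = component_metrics(gold, auto)
        assert pooled.fraction == 1
        for name in COMPONENT_NAMES:
            m = metrics[name]
            assert m.captured == m.present
            assert m.erroneous == 0

    def test_counts_from_mixed_cohort(self):
        gold = [_gold("a", dvt_signs=True), _gold("b", dvt_signs=True), _gold("c")]
        auto = {
            "a": make_components(dvt_signs=True),
            "b": make_components(),  # miss
            "c": make_components(dvt_signs=True),  # false positive
        }
        metrics, pooled = component_metrics(gold, auto)
        m = metrics["dvt_signs"]
        assert (m.present, m.captured, m.erroneous) == (2, 1, 1)
        assert m.sensitivity.fraction == Fraction(1, 2)
        assert m.false_positive_rate.fraction == Fraction(1, 1)
        # pooled: 6 components x 3 encounters, 2 errors
        assert pooled.fraction == Fraction(16, 18)

    def test_unpaired_encounters_error(self):
        with pytest.raises(ValueError, match="no automated components"):
            component_metrics([_gold("a")], {})


class TestCtpaYield:
    def test_stratified_and_overall(self):
        gold = [_gold(f"l{i}", pe=i < 2, tachycardia=True) for i in range(10)]
        gold += [_gold(f"u{i}", pe=i < 1) for i in range(5)]
        results = {g.encounter_id: WellsResult(score_half=12 if g.encounter_id.startswith("l") else 6) for g in gold}
        yields = ctpa_yield(results, gold)
        assert yields["PE_likely"].fraction == Fraction(2, 10)
        assert yields["PE_unlikely"].fraction == Fraction(1, 5)
        assert yields["overall"].fraction == Fraction(3, 15)

    def test_zero_pe(self):
        gold = [_gold("a"), _gold("b")]
        results = {g.encounter_id: WellsResult(score_half=6) for g in gold}
        yields = ctpa_yield(results, gold)
        assert yields["PE_unlikely"].fraction == 0
        assert yields["PE_likely"] is None  # empty stratum absent

    def test_brute_force_recount(self):
        rng = random.Random(2)
        gold = [_gold(f"e{i}", pe=rng.random() < 0.15, tachycardia=rng.random() < 0.5)
                for i in range(120)]
        results = {
            g.encounter_id: compute_wells_score(
                make_components(tachycardia=g.tachycardia)
            )
            for g in gold
        }
        yields = ctpa_yield(results, gold)
        for tier in ("PE_likely", "PE_unlikely"):
            members = [g for g in gold if results[g.encounter_id].tier == tier]
            if members:
                assert yields[tier] == Rate(
                    sum(g.pe_diagnosed for g in members), len(members)
                )
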