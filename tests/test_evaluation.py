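"""Strict scorers, PRF arithmetic and document-level bootstrap."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from phenonote.documents import ConceptMatch, Entity, Measurement
from phenonote.evaluation import (
    BootstrapConfig,
    bootstrap_ci,
    e2e_counts,
    evaluate_documents,
    measurement_counts,
    prf,
    strict_counts,
)


def _ent(label, start, end, code=None, gold_codes=(), meas=None):
    e = Entity("T", label, start, end, "x" * (end - start))
    if code:
        e.concept = ConceptMatch(code, "syn", 0.9, "jaro_winkler")
    e.codes = tuple(gold_codes)
    e.measurement = meas
    return e


class TestStrictCounts:
    def test_perfect_prediction(self):
        gold = [_ent("drug_name", 0, 5), _ent("drug_name", 7, 9), _ent("drug_name", 12, 15)]
        assert strict_counts(gold, list(gold), "drug_name") == (3, 0, 0)

    def test_spurious_prediction(self):
        gold = [_ent("drug_name", 0, 5)]
        pred = [_ent("drug_name", 0, 5), _ent("drug_name", 7, 9)]
        tp, fp, fn = strict_counts(gold, pred, "drug_name")
        assert (tp, fp, fn) == (1, 1, 0)
        p, r, _ = prf(tp, fp, fn)
        assert (p, r) == (50.0, 100.0)

    def test_off_by_one_character_is_error_both_ways(self):
        gold = [_ent("drug_name", 0, 5)]
        pred = [_ent("drug_name", 0, 6)]
        assert strict_counts(gold, pred, "drug_name") == (0, 1, 1)

    def test_label_mismatch_not_matched(self):
        gold = [_ent("drug_name", 0, 5)]
        pred = [_ent("lab_name", 0, 5)]
        assert strict_counts(gold, pred, "drug_name") == (0, 0, 1)

    def test_duplicate_spans_match_one_to_one(self):
        gold = [_ent("drug_name", 0, 5)]
        pred = [_ent("drug_name", 0, 5), _ent("drug_name", 0, 5)]
        assert strict_counts(gold, pred, "drug_name") == (1, 1, 0)


class TestE2ECounts:
    def test_code_in_gold_list(self):
        gold = [_ent("drug_name", 0, 5, gold_codes=("ATC:A1", "ATC:A2"))]
        pred = [_ent("drug_name", 0, 5, code="A2")]
        assert e2e_counts(gold, pred, "drug_name") == (1, 0, 0)

    def test_wrong_code_counts_fp_and_fn(self):
        gold = [_ent("drug_name", 0, 5, gold_codes=("ATC:A1",))]
        pred = [_ent("drug_name", 0, 5, code="B9")]
        assert e2e_counts(gold, pred, "drug_name") == (0, 1, 1)

    def test_right_code_wrong_span(self):
        gold = [_ent("drug_name", 0, 5, gold_codes=("ATC:A1",))]
        pred = [_ent("drug_name", 1, 5, code="A1")]
        assert e2e_counts(gold, pred, "drug_name") == (0, 1, 1)

    def test_e2e_never_exceeds_strict(self):
        gold = [
            _ent("drug_name", 0, 5, gold_codes=("ATC:A1",)),
            _ent("drug_name", 7, 9, gold_codes=("ATC:A2",)),
        ]
        pred = [_ent("drug_name", 0, 5, code="A1"), _ent("drug_name", 7, 9, code="XX")]
        assert e2e_counts(gold, pred, "drug_name")[0] <= strict_counts(gold, pred, "drug_name")[0]


class TestMeasurementCounts:
    def _pair(self, gm, pm):
        gold = [_ent("lab_complete", 0, 9, meas=gm)]
        pred = [_ent("lab_complete", 0, 9, meas=pm)]
        return measurement_counts(gold, pred)

    def test_same_value_and_unit(self):
        m = Measurement(9.0, "g/dL", False, "9")
        assert self._pair(m, Measurement(9.0, "g/dL", False, "9")) == (1, 0, 0)

    def test_different_unit_is_error_both_ways(self):
        a = Measurement(9.0, "g/dL", False, "9")
        b = Measurement(9.0, "g/L", False, "9")
        assert self._pair(a, b) == (0, 1, 1)

    def test_different_grade_is_error_both_ways(self):
        a = Measurement(1.0, "", True, "positif")
        b = Measurement(0.0, "", True, "négatif")
        assert self._pair(a, b) == (0, 1, 1)


class TestPrf:
    def test_lab_row_rounding(self):
        # P=72.0, R=70.2 combine to F1 71.1 at one-decimal reporting
        p, r = 72.0, 70.2
        f1 = 2 * p * r / (p + r)
        assert round(f1, 1) == 71.1

    def test_drug_row_rounding(self):
        p, r = 91.9, 86.9
        assert round(2 * p * r / (p + r), 1) == 89.3

    def test_zero_denominator_convention(self):
        assert prf(0, 0, 0) == (0.0, 0.0, 0.0)

    def test_scale_consistency(self):
        assert prf(6, 2, 4) == prf(12, 4, 8)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            prf(-1, 0, 0)


@given(
    st.lists(
        st.tuples(st.integers(0, 4), st.integers(0, 4)), min_size=1, max_size=6
    )
)
def test_count_conservation(doc_shapes):
    """TP+FN equals the gold count and TP+FP the predicted count, whatever
    the overlap pattern."""
    gold, pred = [], []
    pos = 0
    for n_gold, n_pred in doc_shapes:
        for k in range(n_gold):
            gold.append(_ent("drug_name", pos + 10 * k, pos + 10 * k + 5))
        for k in range(n_pred):
            pred.append(_ent("drug_name", pos + 10 * k + (k % 2), pos + 10 * k + 5))
        pos += 1000
    tp, fp, fn = strict_counts(gold, pred, "drug_name")
    assert tp + fn == len(gold)
    assert tp + fp == len(pred)


class TestBootstrap:
    def test_identical_documents_zero_width_at_point(self):
        dc = np.tile([5, 1, 2], (8, 1))
        lo, hi = bootstrap_ci(dc, "f1", BootstrapConfig(seed=1))
        point = prf(5 * 8, 1 * 8, 2 * 8)[2]
        assert lo == hi == pytest.approx(point)

    def test_same_seed_identical_interval(self):
        rng = np.random.default_rng(0)
        dc = rng.integers(0, 6, size=(12, 3))
        a = bootstrap_ci(dc, "f1", BootstrapConfig(seed=9))
        b = bootstrap_ci(dc, "f1", BootstrapConfig(seed=9))
        assert a == b

    def test_interval_brackets_point_estimate(self):
        rng = np.random.default_rng(3)
        dc = rng.integers(0, 8, size=(40, 3))
        point = prf(*dc.sum(axis=0))[2]
        lo, hi = bootstrap_ci(dc, "f1", BootstrapConfig(seed=5))
        assert lo <= point <= hi

    def test_basic_variant_reflects_percentile(self):
        rng = np.random.default_rng(3)
        dc = rng.integers(0, 8, size=(20, 3))
        point = prf(*dc.sum(axis=0))[2]
        plo, phi = bootstrap_ci(dc, "f1", BootstrapConfig(seed=5))
        blo, bhi = bootstrap_ci(dc, "f1", BootstrapConfig(seed=5, variant="basic"))
        assert blo == pytest.approx(2 * point - phi)
        assert bhi == pytest.approx(2 * point - plo)


def test_evaluate_documents_report_shape():
    gold = {"d1": [_ent("drug_name", 0, 5), _ent("lab_name", 8, 11)]}
    pred = {"d1": [_ent("drug_name", 0, 5)]}
    report = evaluate_documents(
        gold, pred, ["drug_name", "lab_name"], level="ner",
        bootstrap=BootstrapConfig(replicates=100, seed=0),
    )
    assert report.scores["drug_name"].f1 == 100.0
    assert report.scores["lab_name"].recall == 0.0
    assert report.scores["overall"].tp == 1
    assert report.scores["overall"].f1_ci is not None
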