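"""Entity filtering, lab positivity, patient aggregation, cohort table."""

import pytest

from phenonote.documents import (
    Entity,
    Measurement,
    Qualifiers,
    StructuredDrugRecord,
    StructuredLabRecord,
)
from phenonote.phenotyping import (
    ConceptGroup,
    PatientPhenotype,
    aggregate_patients,
    cohort_table,
    filter_entities,
    lab_is_positive,
    read_concept_groups,
    write_concept_groups,
)

ANA = ConceptGroup("antinuclear antibody", "lab", frozenset({"LAB001"}), 80.0)
CRP = ConceptGroup("CRP elevation", "lab", frozenset({"LAB003"}))
HCQ = ConceptGroup("hydroxychloroquine", "drug", frozenset({"P01BA02"}))


def _drug_entity(code="P01BA02", **q):
    return Entity(
        "T1", "drug_name", 0, 4, "test",
        qualifiers=Qualifiers(**q), codes=(f"ATC:{code}",),
    )


def _lab_entity(meas, code="LAB001"):
    return Entity(
        "T2", "lab_complete", 0, 9, "AAN 1/160",
        codes=(f"CUI:{code}",), measurement=meas,
    )


class TestFilterEntities:
    def test_certain_not_negated_kept(self):
        assert filter_entities([_drug_entity()]) != []

    def test_negated_dropped(self):
        assert filter_entities([_drug_entity(negation=True)]) == []

    def test_hypothetical_dropped(self):
        assert filter_entities([_drug_entity(certainty="hypothetical")]) == []

    def test_conditional_dropped(self):
        assert filter_entities([_drug_entity(certainty="conditional")]) == []

    def test_past_and_stop_are_kept(self):
        # the retention rule names only certainty and negation
        kept = filter_entities([_drug_entity(temporality="past", action="stop")])
        assert len(kept) == 1

    def test_unqualified_drug_rejected(self):
        e = Entity("T1", "drug_name", 0, 4, "test")
        with pytest.raises(ValueError, match="qualification"):
            filter_entities([e])

    def test_lab_entities_pass_unqualified(self):
        m = Measurement(1.0, "", True, "positifs")
        assert filter_entities([_lab_entity(m)]) != []


class TestLabIsPositive:
    def test_qualitative_positive(self):
        assert lab_is_positive(Measurement(1.0, "", True, "positif"), CRP)

    def test_qualitative_negative_and_normal(self):
        assert not lab_is_positive(Measurement(0.0, "", True, "négatif"), CRP)
        assert not lab_is_positive(Measurement(0.5, "", True, "normale"), CRP)

    def test_numeric_exceeds_reference(self):
        assert lab_is_positive(Measurement(9.0, "mg/L", False, "9"), CRP, ref_high=7.5)
        assert not lab_is_positive(Measurement(7.5, "mg/L", False, "7,5"), CRP, ref_high=7.5)

    def test_titer_threshold_rule(self):
        assert lab_is_positive(Measurement(160.0, "titer", False, "1/160"), ANA)
        assert lab_is_positive(Measurement(80.0, "titer", False, "1/80"), ANA)
        assert not lab_is_positive(Measurement(40.0, "titer", False, "1/40"), ANA)

    def test_numeric_without_reference_conservative(self):
        assert not lab_is_positive(Measurement(999.0, "mg/L", False, "999"), CRP)


class TestAggregate:
    def _run(self, labs=(), drugs=(), ents=None):
        return aggregate_patients(
            list(labs), list(drugs), ents or {}, [ANA, HCQ], patient_ids=["p1"]
        )

    def test_structured_only(self):
        labs = [StructuredLabRecord("p1", "LAB001", 160, "titer", None, None, True, "d")]
        (p,) = self._run(labs=labs)
        assert p.flags["antinuclear antibody"] == "structured_only"

    def test_unstructured_only(self):
        m = Measurement(160.0, "titer", False, "1/160")
        (p,) = self._run(ents={"p1": [_lab_entity(m)]})
        assert p.flags["antinuclear antibody"] == "unstructured_only"

    def test_both_and_absent(self):
        labs = [StructuredLabRecord("p1", "LAB001", 160, "titer", None, None, True, "d")]
        m = Measurement(160.0, "titer", False, "1/160")
        (p,) = self._run(labs=labs, ents={"p1": [_lab_entity(m)]})
        assert p.flags["antinuclear antibody"] == "both"
        assert p.flags["hydroxychloroquine"] == "absent"

    def test_negative_structured_lab_is_no_hit(self):
        labs = [StructuredLabRecord("p1", "LAB001", 40, "titer", None, None, False, "d")]
        (p,) = self._run(labs=labs)
        assert p.flags["antinuclear antibody"] == "absent"

    def test_drug_record_is_existence(self):
        (p,) = self._run(drugs=[StructuredDrugRecord("p1", "P01BA02", "d")])
        assert p.flags["hydroxychloroquine"] == "structured_only"

    def test_text_numeric_uses_structured_reference_range(self):
        # a normal structured result still supplies the reference range the
        # text value is compared against
        labs = [StructuredLabRecord("p1", "LAB003", 3.0, "mg/L", 0.0, 5.0, None, "d")]
        m = Measurement(40.0, "mg/L", False, "40")
        ents = {"p1": [_lab_entity(m, code="LAB003")]}
        (p,) = aggregate_patients(labs, [], ents, [CRP], patient_ids=["p1"])
        assert p.flags["CRP elevation"] == "unstructured_only"


class TestCohortTable:
    def _phenos(self, n_both, n_struct_only, n_unstruct_only, n_absent):
        flags = (
            ["both"] * n_both
            + ["structured_only"] * n_struct_only
            + ["unstructured_only"] * n_unstruct_only
            + ["absent"] * n_absent
        )
        return [
            PatientPhenotype(f"p{i}", {"antinuclear antibody": f})
            for i, f in enumerate(flags)
        ]

    def test_published_scale_arithmetic(self):
        """A cohort of 4102 patients with 752 structured positives and 2949
        combined positives yields a text-only benefit of 2197 (53.56%)."""
        phenos = self._phenos(700, 52, 2197, 4102 - 2949)
        (row,) = cohort_table(phenos, [ANA], 4102).to_dict("records")
        assert (row["n_structured"], row["n_combined"], row["n_benefit"]) == (
            752, 2949, 2197,
        )
        assert row["pct_structured"] == 18.33
        assert row["pct_combined"] == 71.89
        assert row["pct_benefit"] == 53.56

    def test_small_count_example(self):
        phenos = self._phenos(1, 0, 1, 1)
        (row,) = cohort_table(phenos, [ANA], 3).to_dict("records")
        assert (row["n_structured"], row["n_combined"], row["n_benefit"]) == (1, 2, 1)

    def test_benefit_identity_and_monotonicity(self):
        phenos = self._phenos(5, 3, 7, 10)
        (row,) = cohort_table(phenos, [ANA], 25).to_dict("records")
        assert row["n_benefit"] == row["n_combined"] - row["n_structured"]
        assert row["n_structured"] <= row["n_combined"]

    def test_cohort_smaller_than_counts_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            cohort_table(self._phenos(3, 0, 0, 0), [ANA], 2)


def test_concept_groups_yaml_round_trip():
    groups = [ANA, CRP, HCQ]
    assert read_concept_groups(write_concept_groups(groups)) == groups
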