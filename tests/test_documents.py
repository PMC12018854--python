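"""Standoff and tabular IO: parsing, serialization, round trips."""

import pytest
from hypothesis import given, strategies as st

from phenonote.documents import (
    DEFAULT_QUALIFIERS,
    Document,
    Entity,
    Measurement,
    Qualifiers,
    StandoffParseError,
    read_dictionary,
    read_standoff,
    read_structured,
    write_standoff,
)

DOC = Document("d1", "p1", "paracetamol 500 mg")


class TestReadStandoff:
    def test_single_entity(self):
        ents = read_standoff(DOC, "T1\tdrug_name 0 11\tparacetamol\n")
        assert len(ents) == 1
        e = ents[0]
        assert (e.label, e.start, e.end, e.surface) == ("drug_name", 0, 11, "paracetamol")

    def test_empty_input(self):
        assert read_standoff(DOC, "") == []

    def test_offset_out_of_bounds(self):
        with pytest.raises(StandoffParseError, match="out of bounds"):
            read_standoff(DOC, "T1\tdrug_name 0 99\tx")

    def test_unknown_label(self):
        with pytest.raises(StandoffParseError, match="unknown label"):
            read_standoff(DOC, "T1\tdisease 0 11\tparacetamol")

    def test_attributes_and_codes_attach(self):
        ann = (
            "T1\tdrug_name 0 11\tparacetamol\n"
            "A1\tnegation T1 true\n"
            "A2\taction T1 stop\n"
            "N1\tRef T1 ATC:N02BE01\n"
            "N2\tRef T1 ATC:N02BE51\n"
        )
        (e,) = read_standoff(DOC, ann)
        assert e.qualifiers == Qualifiers(action="stop", negation=True)
        assert e.codes == ("ATC:N02BE01", "ATC:N02BE51")
        assert e.code_values() == ("N02BE01", "N02BE51")

    def test_entities_sorted_by_span(self):
        ann = "T2\tdrug_strength 12 18\t500 mg\nT1\tdrug_name 0 11\tparacetamol\n"
        ents = read_standoff(DOC, ann)
        assert [e.start for e in ents] == [0, 12]


class TestWriteStandoff:
    def test_empty(self):
        assert write_standoff([]) == ""

    def test_one_line_per_plain_entity(self):
        e = Entity("T1", "drug_name", 0, 11, "paracetamol")
        assert write_standoff([e]).strip().count("\n") == 0

    def test_negation_adds_one_attribute_line(self):
        e = Entity(
            "T1", "drug_name", 0, 11, "paracetamol",
            qualifiers=Qualifiers(negation=True),
        )
        lines = write_standoff([e]).strip().split("\n")
        assert len(lines) == 2
        assert lines[1].startswith("A1\tnegation T1 true")


# -- round-trip property ----------------------------------------------------

_LABELS = ["drug_name", "drug_strength", "lab_name"]


@st.composite
def _doc_with_entities(draw):
    words = draw(st.lists(st.sampled_from(["aan", "para", "mg", "500", "xyz"]),
                          min_size=1, max_size=8))
    text = " ".join(words)
    # word k occupies a known span; pick disjoint word runs per label
    spans = []
    pos = 0
    for w in words:
        spans.append((pos, pos + len(w)))
        pos += len(w) + 1
    entities = []
    used: dict[str, set[int]] = {lbl: set() for lbl in _LABELS}
    n_ents = draw(st.integers(0, min(4, len(words))))
    for k in range(n_ents):
        lbl = draw(st.sampled_from(_LABELS))
        i = draw(st.integers(0, len(words) - 1))
        j = draw(st.integers(i, min(i + 2, len(words) - 1)))
        if any(w in used[lbl] for w in range(i, j + 1)):
            continue
        used[lbl].update(range(i, j + 1))
        q = draw(
            st.one_of(
                st.none(),
                st.builds(
                    Qualifiers,
                    action=st.sampled_from(["unknown", "stop", "start"]),
                    negation=st.booleans(),
                ),
            )
        )
        codes = tuple(
            draw(st.lists(st.sampled_from(["ATC:A", "ATC:B", "CUI:C1"]),
                          max_size=2, unique=True))
        )
        meas = draw(
            st.one_of(
                st.none(),
                st.builds(
                    Measurement,
                    value=st.sampled_from([0.0, 1.0, 9.5, 160.0]),
                    unit=st.just("g/L"),
                    is_qualitative=st.just(False),
                    raw=st.just("9,5"),
                ),
            )
        )
        start, end = spans[i][0], spans[j][1]
        entities.append(
            Entity(f"T{k}", lbl, start, end, text[start:end],
                   qualifiers=q, codes=codes, measurement=meas)
        )
    return Document("d", "p", text), entities


def _canon(ents):
    return sorted(
        (
            e.label, e.start, e.end, e.surface,
            e.effective_qualifiers(), tuple(sorted(e.codes)), e.measurement,
        )
        for e in ents
    )


@given(_doc_with_entities())
def test_standoff_round_trip_lossless(doc_ents):
    """write -> read preserves spans, labels, effective qualifiers, codes and
    measurements (entity ids are renumbered)."""
    doc, entities = doc_ents
    recovered = read_standoff(doc, write_standoff(entities))
    assert _canon(recovered) == _canon(entities)


@given(_doc_with_entities())
def test_offsets_reslice_to_surface(doc_ents):
    doc, entities = doc_ents
    for e in entities:
        assert doc.text[e.start:e.end] == e.surface


# -- dictionaries -----------------------------------------------------------


class TestReadDictionary:
    def test_single_entry(self):
        d = read_dictionary("N02BE01\tparacetamol\tfr\tATC")
        assert len(d) == 1
        assert d.entries[0].code == "N02BE01"

    def test_duplicate_synonyms_preserved(self):
        d = read_dictionary("A\tparacetamol\tfr\tATC\nB\tparacetamol\tfr\tATC")
        assert len(d) == 2

    def test_wrong_column_count(self):
        with pytest.raises(ValueError, match="line 1"):
            read_dictionary("onlyonecolumn")

    def test_optional_header_skipped(self):
        d = read_dictionary("code\tsynonym\tlanguage\tvocabulary\nA\tx\tfr\tATC")
        assert len(d) == 1


# -- structured tables ------------------------------------------------------

LABS_CSV = (
    "patient_id,concept_code,value,unit,ref_low,ref_high,positive_flag,datetime\n"
    "p1,LAB003,12.5,mg/L,0,5,,2020-01-01\n"
    "p1,LAB001,160,titer,,,True,2020-01-02\n"
    "p2,LAB003,3.0,mg/L,0,5,,2020-01-01\n"
)
DRUGS_CSV = "patient_id,atc_code,datetime\np1,P01BA02,2020-01-01\n"


class TestReadStructured:
    def test_row_counts(self):
        labs, drugs = read_structured(LABS_CSV, DRUGS_CSV)
        assert (len(labs), len(drugs)) == (3, 1)
        assert labs[0].value == 12.5 and labs[0].ref_high == 5.0
        assert labs[1].positive_flag is True and labs[1].ref_high is None

    def test_empty_body(self):
        labs, drugs = read_structured(LABS_CSV.splitlines()[0] + "\n",
                                      DRUGS_CSV.splitlines()[0] + "\n")
        assert labs == [] and drugs == []

    def test_missing_column(self):
        with pytest.raises(ValueError, match="atc_code"):
            read_structured(LABS_CSV, "patient_id,datetime\np1,2020\n")

    def test_non_numeric_value(self):
        bad = LABS_CSV.replace("12.5", "douze")
        with pytest.raises(ValueError):
            read_structured(bad, DRUGS_CSV)
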