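"""Data model for clinical notes, standoff annotations, terminology
dictionaries and structured (tabular) records, plus readers/writers for every
on-disk format the pipeline touches.

Conventions
-----------
* All character offsets are 0-based, half-open, counted in Unicode code
  points over the exact loaded text, so ``text[start:end] == surface`` always
  holds.
* Annotations use a brat-style standoff dialect::

      T1\tdrug_name 0 11\tparacetamol
      A1\tnegation T1 true
      N1\tRef T1 ATC:N02BE01
      #1\tAnnotatorNotes T1\t{"value": 1.0, ...}

  "T" lines are entity spans, "A" lines qualifier axes, "N" lines concept
  codes (several per entity allowed), "#" note lines carry a JSON-serialized
  measurement.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

ENTITY_LABELS = (
    "lab_name",
    "lab_complete",
    "drug_name",
    "drug_dose",
    "drug_form",
    "drug_strength",
)

ACTIONS = ("start", "stop", "increase", "decrease", "unique_dose", "unknown")
TEMPORALITIES = ("present", "past", "future")
CERTAINTIES = ("certain", "hypothetical", "conditional")

#: qualifier axes in canonical serialization order
QUALIFIER_AXES = ("action", "temporality", "certainty", "negation")


class StandoffParseError(ValueError):
    """Raised when a standoff annotation file cannot be parsed."""


@dataclass(frozen=True)
class Qualifiers:
    """The four qualification axes of a drug mention.

    Defaults are the "keep" state of the downstream phenotyping filter:
    an unqualified mention counts as a certain, non-negated, present fact.
    """

    action: str = "unknown"
    temporality: str = "present"
    certainty: str = "certain"
    negation: bool = False

    def __post_init__(self) -> None:
        if self.action not in ACTIONS:
            raise ValueError(f"unknown action {self.action!r}")
        if self.temporality not in TEMPORALITIES:
            raise ValueError(f"unknown temporality {self.temporality!r}")
        if self.certainty not in CERTAINTIES:
            raise ValueError(f"unknown certainty {self.certainty!r}")


DEFAULT_QUALIFIERS = Qualifiers()


@dataclass(frozen=True)
class ConceptMatch:
    """Best dictionary code for a term, with its similarity score."""

    code: str
    matched_synonym: str
    score: float
    method: str  # levenshtein | jaro_winkler | embedding | exact

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0 + 1e-12):
            raise ValueError(f"score {self.score} outside [0, 1]")


@dataclass(frozen=True)
class Measurement:
    """A standardized laboratory result: value plus canonical unit.

    Qualitative results are graded 1.0 (positive), 0.0 (negative) or 0.5
    (normal) and carry no unit.  Titers 1/N are stored numerically as value N
    with unit ``"titer"``.
    """

    value: float
    unit: str
    is_qualitative: bool
    raw: str
    unit_unknown: bool = False

    def __post_init__(self) -> None:
        if self.is_qualitative:
            if self.value not in (0.0, 0.5, 1.0):
                raise ValueError("qualitative value must be 0.0, 0.5 or 1.0")
            if self.unit:
                raise ValueError("qualitative measurement carries no unit")


@dataclass
class Entity:
    """A labeled character span in one document.

    ``codes`` holds gold-standard concept annotations ("VOCAB:code" strings;
    several acceptable codes per entity are allowed); ``concept`` holds a
    predicted normalization.
    """

    entity_id: str
    label: str
    start: int
    end: int
    surface: str
    qualifiers: Optional[Qualifiers] = None
    concept: Optional[ConceptMatch] = None
    codes: tuple[str, ...] = ()
    measurement: Optional[Measurement] = None

    def __post_init__(self) -> None:
        if self.label not in ENTITY_LABELS:
            raise ValueError(f"unknown entity label {self.label!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad span [{self.start}, {self.end})")

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def effective_qualifiers(self) -> Qualifiers:
        """Qualifiers with the defaults applied when none were assigned."""
        return self.qualifiers if self.qualifiers is not None else DEFAULT_QUALIFIERS

    def code_values(self) -> tuple[str, ...]:
        """Gold codes with any VOCAB: prefix stripped."""
        return tuple(c.split(":", 1)[1] if ":" in c else c for c in self.codes)


@dataclass
class Document:
    doc_id: str
    patient_id: str
    text: str
    note_datetime: Optional[str] = None


@dataclass(frozen=True)
class DictionaryEntry:
    code: str
    synonym: str
    language: str  # fr | en
    vocabulary: str


@dataclass
class KnowledgeDictionary:
    """code <-> synonym table; a synonym may map to several codes."""

    entries: list[DictionaryEntry]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("dictionary must contain at least one entry")

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class StructuredLabRecord:
    patient_id: str
    concept_code: str
    value: float
    unit: str
    ref_low: Optional[float]
    ref_high: Optional[float]
    positive_flag: Optional[bool]
    datetime: str

    def __post_init__(self) -> None:
        if self.ref_low is None and self.ref_high is None and self.positive_flag is None:
            raise ValueError(
                "lab record needs a reference range or an interpretation flag"
            )


@dataclass(frozen=True)
class StructuredDrugRecord:
    patient_id: str
    atc_code: str
    datetime: str

    def __post_init__(self) -> None:
        if not self.atc_code:
            raise ValueError("atc_code must be non-empty")


# ---------------------------------------------------------------------------
# standoff annotations
# ---------------------------------------------------------------------------

def read_standoff(doc: Document, ann_text: str) -> list[Entity]:
    """Parse a brat-style standoff file against ``doc``.

    Returns entities sorted by (start, end); qualifier / code / measurement
    lines are attached to their entity.  Raises :class:`StandoffParseError`
    naming the offending line for malformed input, unknown labels and spans
    outside the document.
    """
    entities: dict[str, Entity] = {}
    axes: dict[str, dict[str, object]] = {}
    pending: list[tuple[int, str]] = []

    for lineno, line in enumerate(ann_text.splitlines(), start=1):
        if not line.strip():
            continue
        if line[0] == "T":
            parts = line.split("\t")
            if len(parts) != 3:
                raise StandoffParseError(f"line {lineno}: malformed T line")
            tid, spandef, surface = parts
            bits = spandef.split(" ")
            if len(bits) != 3:
                raise StandoffParseError(f"line {lineno}: malformed span definition")
            label, s_start, s_end = bits
            if label not in ENTITY_LABELS:
                raise StandoffParseError(f"line {lineno}: unknown label {label!r}")
            try:
                start, end = int(s_start), int(s_end)
            except ValueError as exc:
                raise StandoffParseError(f"line {lineno}: non-integer offset") from exc
            if not (0 <= start < end <= len(doc.text)):
                raise StandoffParseError(f"line {lineno}: offset out of bounds")
            if doc.text[start:end] != surface:
                raise StandoffParseError(
                    f"line {lineno}: surface mismatch with document text"
                )
            entities[tid] = Entity(tid, label, start, end, surface)
        else:
            pending.append((lineno, line))

    for lineno, line in pending:
        kind = line[0]
        parts = line.split("\t")
        if kind == "A":
            if len(parts) != 2:
                raise StandoffParseError(f"line {lineno}: malformed A line")
            bits = parts[1].split(" ")
            if len(bits) != 3:
                raise StandoffParseError(f"line {lineno}: malformed A line")
            axis, tid, value = bits
            if tid not in entities:
                raise StandoffParseError(f"line {lineno}: unknown entity {tid}")
            if axis not in QUALIFIER_AXES:
                raise StandoffParseError(f"line {lineno}: unknown axis {axis!r}")
            axes.setdefault(tid, {})[axis] = (
                value == "true" if axis == "negation" else value
            )
        elif kind == "N":
            if len(parts) != 2:
                raise StandoffParseError(f"line {lineno}: malformed N line")
            bits = parts[1].split(" ")
            if len(bits) != 3 or bits[0] != "Ref":
                raise StandoffParseError(f"line {lineno}: malformed N line")
            _, tid, code = bits
            if tid not in entities:
                raise StandoffParseError(f"line {lineno}: unknown entity {tid}")
            ent = entities[tid]
            ent.codes = ent.codes + (code,)
        elif kind == "#":
            if len(parts) != 3 or not parts[1].startswith("AnnotatorNotes "):
                raise StandoffParseError(f"line {lineno}: malformed note line")
            tid = parts[1].split(" ", 1)[1]
            if tid not in entities:
                raise StandoffParseError(f"line {lineno}: unknown entity {tid}")
            try:
                payload = json.loads(parts[2])
                entities[tid].measurement = Measurement(
                    value=float(payload["value"]),
                    unit=str(payload["unit"]),
                    is_qualitative=bool(payload["is_qualitative"]),
                    raw=str(payload.get("raw", "")),
                    unit_unknown=bool(payload.get("unit_unknown", False)),
                )
            except (KeyError, ValueError, json.JSONDecodeError) as exc:
                raise StandoffParseError(
                    f"line {lineno}: bad measurement payload"
                ) from exc
        else:
            raise StandoffParseError(f"line {lineno}: unknown line type {kind!r}")

    for tid, overrides in axes.items():
        entities[tid].qualifiers = replace(DEFAULT_QUALIFIERS, **overrides)

    return sorted(entities.values(), key=lambda e: (e.start, e.end, e.label))


def write_standoff(entities: Iterable[Entity]) -> str:
    """Serialize entities to the standoff dialect.

    Only qualifier axes differing from the defaults produce "A" lines, so a
    plainly-asserted mention serializes to its "T" line alone.
    """
    lines: list[str] = []
    a_counter = n_counter = note_counter = 0
    for i, ent in enumerate(
        sorted(entities, key=lambda e: (e.start, e.end, e.label)), start=1
    ):
        tid = f"T{i}"
        lines.append(f"{tid}\t{ent.label} {ent.start} {ent.end}\t{ent.surface}")
        if ent.qualifiers is not None:
            q = ent.qualifiers
            for axis in QUALIFIER_AXES:
                value = getattr(q, axis)
                if value != getattr(DEFAULT_QUALIFIERS, axis):
                    a_counter += 1
                    sval = "true" if value is True else str(value)
                    lines.append(f"A{a_counter}\t{axis} {tid} {sval}")
        for code in ent.codes:
            n_counter += 1
            lines.append(f"N{n_counter}\tRef {tid} {code}")
        if ent.measurement is not None:
            note_counter += 1
            m = ent.measurement
            payload = json.dumps(
                {
                    "value": m.value,
                    "unit": m.unit,
                    "is_qualitative": m.is_qualitative,
                    "raw": m.raw,
                    "unit_unknown": m.unit_unknown,
                },
                ensure_ascii=False,
            )
            lines.append(f"#{note_counter}\tAnnotatorNotes {tid}\t{payload}")
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# dictionaries
# ---------------------------------------------------------------------------

_DICT_HEADER = ("code", "synonym", "language", "vocabulary")


def read_dictionary(tsv_text: str) -> KnowledgeDictionary:
    """Read a 4-column TSV terminology (code, synonym, language, vocabulary).

    The header row is optional; duplicate rows are preserved (a synonym may
    legitimately map to several codes).
    """
    entries: list[DictionaryEntry] = []
    for lineno, line in enumerate(tsv_text.splitlines(), start=1):
        if not line.strip():
            continue
        cols = line.rstrip("\n").split("\t")
        if lineno == 1 and tuple(c.strip().lower() for c in cols) == _DICT_HEADER:
            continue
        if len(cols) != 4:
            raise ValueError(
                f"dictionary line {lineno}: expected 4 tab-separated columns, "
                f"got {len(cols)}"
            )
        entries.append(DictionaryEntry(*[c.strip() for c in cols]))
    return KnowledgeDictionary(entries)


def write_dictionary(dictionary: KnowledgeDictionary) -> str:
    lines = ["\t".join(_DICT_HEADER)]
    for e in dictionary.entries:
        lines.append(f"{e.code}\t{e.synonym}\t{e.language}\t{e.vocabulary}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# structured records
# ---------------------------------------------------------------------------

_LAB_COLUMNS = [
    "patient_id",
    "concept_code",
    "value",
    "unit",
    "ref_low",
    "ref_high",
    "positive_flag",
    "datetime",
]
_DRUG_COLUMNS = ["patient_id", "atc_code", "datetime"]


def _opt_float(x) -> Optional[float]:
    if x is None or (isinstance(x, float) and math.isnan(x)) or x == "":
        return None
    return float(x)


def _opt_bool(x) -> Optional[bool]:
    if x is None or (isinstance(x, float) and math.isnan(x)) or x == "":
        return None
    if isinstance(x, bool):
        return x
    s = str(x).strip().lower()
    if s in ("true", "1", "1.0", "yes"):
        return True
    if s in ("false", "0", "0.0", "no"):
        return False
    raise ValueError(f"cannot interpret {x!r} as a boolean flag")


def read_structured(
    labs_csv: str, drugs_csv: str
) -> tuple[list[StructuredLabRecord], list[StructuredDrugRecord]]:
    """Parse the structured lab-result and drug-administration tables."""
    labs_df = pd.read_csv(io.StringIO(labs_csv), dtype={"patient_id": str})
    for col in _LAB_COLUMNS:
        if col not in labs_df.columns:
            raise ValueError(f"labs CSV missing required column {col!r}")
    labs = [
        StructuredLabRecord(
            patient_id=str(row.patient_id),
            concept_code=str(row.concept_code),
            value=float(row.value),
            unit=str(row.unit),
            ref_low=_opt_float(row.ref_low),
            ref_high=_opt_float(row.ref_high),
            positive_flag=_opt_bool(row.positive_flag),
            datetime=str(row.datetime),
        )
        for row in labs_df.itertuples(index=False)
    ]

    drugs_df = pd.read_csv(io.StringIO(drugs_csv), dtype={"patient_id": str})
    for col in _DRUG_COLUMNS:
        if col not in drugs_df.columns:
            raise ValueError(f"drugs CSV missing required column {col!r}")
    drugs = [
        StructuredDrugRecord(
            patient_id=str(row.patient_id),
            atc_code=str(row.atc_code),
            datetime=str(row.datetime),
        )
        for row in drugs_df.itertuples(index=False)
    ]
    return labs, drugs


# ---------------------------------------------------------------------------
# corpus directory layout
# ---------------------------------------------------------------------------

@dataclass
class Corpus:
    """An on-disk corpus: notes, optional gold annotations, dictionaries,
    structured tables."""

    documents: list[Document]
    gold: dict[str, list[Entity]] = field(default_factory=dict)
    drug_dictionary: Optional[KnowledgeDictionary] = None
    lab_dictionary: Optional[KnowledgeDictionary] = None
    structured_labs: list[StructuredLabRecord] = field(default_factory=list)
    structured_drugs: list[StructuredDrugRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [d.doc_id for d in self.documents]
        if len(set(ids)) != len(ids):
            raise ValueError("doc_id values must be unique within a corpus")

    def doc(self, doc_id: str) -> Document:
        for d in self.documents:
            if d.doc_id == doc_id:
                return d
        raise KeyError(doc_id)


def load_corpus(root: str | Path) -> Corpus:
    root = Path(root)
    manifest = pd.read_csv(root / "manifest.csv", dtype=str)
    documents: list[Document] = []
    gold: dict[str, list[Entity]] = {}
    for row in manifest.itertuples(index=False):
        text = (root / row.path).read_text(encoding="utf-8")
        doc = Document(
            doc_id=row.doc_id,
            patient_id=row.patient_id,
            text=text,
            note_datetime=getattr(row, "datetime", None),
        )
        documents.append(doc)
        ann_path = root / "ann" / f"{doc.doc_id}.ann"
        if ann_path.exists():
            gold[doc.doc_id] = read_standoff(
                doc, ann_path.read_text(encoding="utf-8")
            )

    def _dict(path: Path) -> Optional[KnowledgeDictionary]:
        return (
            read_dictionary(path.read_text(encoding="utf-8"))
            if path.exists()
            else None
        )

    labs_path = root / "structured" / "labs.csv"
    drugs_path = root / "structured" / "drugs.csv"
    labs: list[StructuredLabRecord] = []
    drugs: list[StructuredDrugRecord] = []
    if labs_path.exists() and drugs_path.exists():
        labs, drugs = read_structured(
            labs_path.read_text(encoding="utf-8"),
            drugs_path.read_text(encoding="utf-8"),
        )
    return Corpus(
        documents=documents,
        gold=gold,
        drug_dictionary=_dict(root / "dictionaries" / "drugs.tsv"),
        lab_dictionary=_dict(root / "dictionaries" / "labs.tsv"),
        structured_labs=labs,
        structured_drugs=drugs,
    )


def write_corpus(corpus: Corpus, root: str | Path) -> None:
    root = Path(root)
    (root / "notes").mkdir(parents=True, exist_ok=True)
    rows = []
    for doc in corpus.documents:
        path = Path("notes") / f"{doc.doc_id}.txt"
        (root / path).write_text(doc.text, encoding="utf-8")
        rows.append(
            {
                "doc_id": doc.doc_id,
                "patient_id": doc.patient_id,
                "path": str(path),
                "datetime": doc.note_datetime or "",
            }
        )
    pd.DataFrame(rows, columns=["doc_id", "patient_id", "path", "datetime"]).to_csv(
        root / "manifest.csv", index=False
    )
    if corpus.gold:
        (root / "ann").mkdir(exist_ok=True)
        for doc_id, entities in corpus.gold.items():
            (root / "ann" / f"{doc_id}.ann").write_text(
                write_standoff(entities), encoding="utf-8"
            )
    if corpus.drug_dictionary or corpus.lab_dictionary:
        (root / "dictionaries").mkdir(exist_ok=True)
        if corpus.drug_dictionary:
            (root / "dictionaries" / "drugs.tsv").write_text(
                write_dictionary(corpus.drug_dictionary), encoding="utf-8"
            )
        if corpus.lab_dictionary:
            (root / "dictionaries" / "labs.tsv").write_text(
                write_dictionary(corpus.lab_dictionary), encoding="utf-8"
            )
    (root / "structured").mkdir(exist_ok=True)
    pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "concept_code": r.concept_code,
                "value": r.value,
                "unit": r.unit,
                "ref_low": r.ref_low if r.ref_low is not None else "",
                "ref_high": r.ref_high if r.ref_high is not None else "",
                "positive_flag": r.positive_flag if r.positive_flag is not None else "",
                "datetime": r.datetime,
            }
            for r in corpus.structured_labs
        ],
        columns=_LAB_COLUMNS,
    ).to_csv(root / "structured" / "labs.csv", index=False)
    pd.DataFrame(
        [
            {"patient_id": r.patient_id, "atc_code": r.atc_code, "datetime": r.datetime}
            for r in corpus.structured_drugs
        ],
        columns=_DRUG_COLUMNS,
    ).to_csv(root / "structured" / "drugs.csv", index=False)
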