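"""Seeded generator of synthetic French-like clinical corpora.

The generator emits short, template-based discharge-note sentences with
gold annotations recorded exactly as planted: drug mentions with strength /
dose / form and qualifier cues, complete laboratory tests (numeric values
with French decimal commas, qualitative results, titers), toy terminology
dictionaries, parallel structured tables that only partially overlap the
text, and a per-patient truth table of phenotype flags with provenance.

Vocabulary is controlled and license-clean: drug names are common molecule
names with ATC-shaped codes, laboratory concepts carry synthetic LAB***
codes.  The statistical knobs (typo rate, cue rate, structured coverage,
structured-only rate) define the study conditions every downstream test
runs under; the truth table is the single source of gold for
phenotype-level checks, span-level gold for NER checks.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from typing import Optional

import pandas as pd

from .documents import (
    Corpus,
    DictionaryEntry,
    Document,
    Entity,
    KnowledgeDictionary,
    Measurement,
    Qualifiers,
    StructuredDrugRecord,
    StructuredLabRecord,
)
from .normalization import levenshtein
from .phenotyping import ConceptGroup

_LETTERS = "abcdefghijklmnopqrstuvwxyz"


def corrupt_term(term: str, n_edits: int, seed: int | random.Random) -> str:
    """Apply ``n_edits`` random single-character edits (substitution,
    insertion or deletion); guarantees levenshtein(term, result) <= n_edits."""
    rng = seed if isinstance(seed, random.Random) else random.Random(seed)
    s = list(term)
    for _ in range(n_edits):
        op = rng.choice(["sub", "ins", "del"] if len(s) > 1 else ["sub", "ins"])
        i = rng.randrange(len(s))
        if op == "sub":
            s[i] = rng.choice([c for c in _LETTERS if c != s[i]])
        elif op == "ins":
            s.insert(i, rng.choice(_LETTERS))
        else:
            del s[i]
    result = "".join(s)
    assert levenshtein(term, result) <= n_edits
    return result


# ---------------------------------------------------------------------------
# concept inventory
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DrugConcept:
    name: str
    code: str  # ATC-shaped
    synonyms: tuple[str, ...] = ()


@dataclass(frozen=True)
class LabConcept:
    name: str
    code: str
    kind: str  # titer | qualitative | numeric
    unit: str = ""  # written unit for numeric labs
    ref_low: float = 0.0
    ref_high: float = 0.0
    synonyms: tuple[str, ...] = ()


DEFAULT_DRUGS = (
    DrugConcept("hydroxychloroquine", "P01BA02", ("plaquenil",)),
    DrugConcept("methotrexate", "L04AX03"),
    DrugConcept("rituximab", "L01XC02"),
    DrugConcept("prednisone", "H02AB07"),
    DrugConcept("paracetamol", "N02BE01"),
    DrugConcept("hydroxycarbamide", "L01XX05"),
    DrugConcept("azathioprine", "L04AX01"),
)

DEFAULT_LABS = (
    LabConcept("AAN", "LAB001", "titer", synonyms=("anticorps antinucléaires",)),
    LabConcept("anti-ADN", "LAB002", "qualitative", synonyms=("anticorps anti-ADN",)),
    LabConcept("CRP", "LAB003", "numeric", "mg/L", 0.0, 5.0, ("protéine C réactive",)),
    LabConcept("hémoglobine", "LAB004", "numeric", "g/dL", 12.0, 16.0, ("Hb",)),
)

#: the phenotype groups the default cohort is scored on
DEFAULT_GROUPS = (
    ConceptGroup("antinuclear antibody", "lab", frozenset({"LAB001"}), 80.0),
    ConceptGroup("anti-DNA antibody", "lab", frozenset({"LAB002"})),
    ConceptGroup("C-reactive protein elevation", "lab", frozenset({"LAB003"})),
    ConceptGroup("hydroxychloroquine", "drug", frozenset({"P01BA02"})),
    ConceptGroup("methotrexate", "drug", frozenset({"L04AX03"})),
)


@dataclass(frozen=True)
class SynthConfig:
    n_patients: int = 200
    notes_per_patient: int = 2
    typo_rate: float = 0.0
    cue_rate: float = 0.3  # chance a group fact without text evidence leaves a
    # negated/conditional trace, and that an affirmative mention carries a cue
    text_rate: float = 0.5  # chance a group fact is mentioned in the text
    structured_coverage: float = 0.6  # chance a text fact also appears structured
    structured_only_rate: float = 0.15  # chance of a structured-only fact
    qualitative_ratio: float = 0.5  # qualitative vs numeric filler labs
    seed: int = 0
    drugs: tuple[DrugConcept, ...] = DEFAULT_DRUGS
    labs: tuple[LabConcept, ...] = DEFAULT_LABS
    groups: tuple[ConceptGroup, ...] = DEFAULT_GROUPS

    def __post_init__(self) -> None:
        for p in (
            self.typo_rate,
            self.cue_rate,
            self.text_rate,
            self.structured_coverage,
            self.structured_only_rate,
            self.qualitative_ratio,
        ):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if not self.drugs or not self.labs:
            raise ValueError("concept inventory must be non-empty")


@dataclass
class SynthCohort:
    corpus: Corpus
    groups: list[ConceptGroup]
    truth: pd.DataFrame  # columns: patient_id, group, flag
    config: SynthConfig


# ---------------------------------------------------------------------------
# sentence builders: each returns (text, entities at local offsets)
# ---------------------------------------------------------------------------


def _entity(label, start, end, text, **kw) -> Entity:
    return Entity("G0", label, start, end, text[start:end], **kw)


class _SentenceFactory:
    def __init__(self, cfg: SynthConfig, rng: random.Random):
        self.cfg = cfg
        self.rng = rng

    def _maybe_typo(self, name: str) -> str:
        if self.rng.random() < self.cfg.typo_rate:
            return corrupt_term(name, 1, self.rng)
        return name

    def drug_affirm(self, drug: DrugConcept) -> tuple[str, list[Entity]]:
        name = self._maybe_typo(drug.name)
        strength = self.rng.choice([50, 100, 200, 500])
        template = self.rng.randrange(4)
        q = Qualifiers()
        if template == 0:
            prefix = "Patient sous "
        elif template == 1:
            prefix = "Introduction de "
            q = Qualifiers(action="start")
        elif template == 2:
            prefix = "Majoration de "
            q = Qualifiers(action="increase")
        else:
            prefix = "Traitement par "
        text = f"{prefix}{name} {strength} mg"
        ents = [
            _entity(
                "drug_name",
                len(prefix),
                len(prefix) + len(name),
                text,
                qualifiers=q,
                codes=(f"ATC:{drug.code}",),
            ),
            _entity(
                "drug_strength",
                len(prefix) + len(name) + 1,
                len(text),
                text,
            ),
        ]
        if self.rng.random() < 0.5:
            form = self.rng.choice(["comprimé", "gélule"])
            fs = len(text) + 1
            text = f"{text} {form}"
            ents.append(_entity("drug_form", fs, len(text), text))
        if self.rng.random() < 0.4:
            ds = len(text) + 2
            text = f"{text}, 2 fois par jour"
            ents.append(_entity("drug_dose", ds, len(text), text))
        return f"{text}.", ents

    def drug_negative(self, drug: DrugConcept) -> tuple[str, list[Entity]]:
        name = self._maybe_typo(drug.name)
        if self.rng.random() < 0.5:
            prefix = "Pas de traitement par "
            q = Qualifiers(negation=True)
            text = f"{prefix}{name}."
            start = len(prefix)
        else:
            text = f"{name} si besoin."
            q = Qualifiers(certainty="conditional")
            start = 0
        ents = [
            _entity(
                "drug_name",
                start,
                start + len(name),
                text,
                qualifiers=q,
                codes=(f"ATC:{drug.code}",),
            )
        ]
        return text, ents

    def lab_sentence(
        self, lab: LabConcept, positive: bool
    ) -> tuple[str, list[Entity], Measurement]:
        name = self._maybe_typo(lab.name) if lab.kind == "numeric" else lab.name
        if lab.kind == "titer":
            titer = (
                self.rng.choice([160, 320, 640]) if positive else self.rng.choice([40, 20])
            )
            value_str = f"1/{titer}"
            meas = Measurement(float(titer), "titer", False, value_str)
        elif lab.kind == "qualitative":
            value_str = "positifs" if positive else "négatifs"
            meas = Measurement(1.0 if positive else 0.0, "", True, value_str)
        else:
            raw = (
                round(self.rng.uniform(lab.ref_high * 2, lab.ref_high * 8), 1)
                if positive
                else round(self.rng.uniform(lab.ref_low, lab.ref_high), 1)
            )
            value_str = f"{raw} {lab.unit}".replace(".", ",")
            # canonical value as measurement extraction will standardize it
            from .measurements import convert_unit

            cv, cu, _ = convert_unit(float(raw), lab.unit)
            meas = Measurement(round(cv, 6), cu, False, value_str)
        text = f"{name} : {value_str}."
        name_ent = _entity("lab_name", 0, len(name), text, codes=(f"CUI:{lab.code}",))
        complete = _entity(
            "lab_complete", 0, len(text) - 1, text, measurement=meas
        )
        return text, [name_ent, complete], meas


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def gen_cohort(cfg: SynthConfig = SynthConfig()) -> SynthCohort:
    """Generate a full synthetic cohort; byte-identical for equal configs."""
    rng = random.Random(cfg.seed)
    factory = _SentenceFactory(cfg, rng)
    drugs_by_code = {d.code: d for d in cfg.drugs}
    labs_by_code = {l.code: l for l in cfg.labs}

    documents: list[Document] = []
    gold: dict[str, list[Entity]] = {}
    structured_labs: list[StructuredLabRecord] = []
    structured_drugs: list[StructuredDrugRecord] = []
    truth_rows = []

    filler_drugs = [d for d in cfg.drugs if not any(
        d.code in g.codes for g in cfg.groups
    )]
    filler_labs = [l for l in cfg.labs if not any(
        l.code in g.codes for g in cfg.groups
    )]

    for p in range(cfg.n_patients):
        pid = f"P{p:04d}"
        sentences: list[tuple[str, list[Entity]]] = []

        for group in cfg.groups:
            text_hit = rng.random() < cfg.text_rate
            struct_hit = rng.random() < (
                cfg.structured_coverage if text_hit else cfg.structured_only_rate
            )

            if group.kind == "drug":
                drug = drugs_by_code[next(iter(group.codes))]
                if text_hit:
                    sentences.append(factory.drug_affirm(drug))
                elif rng.random() < cfg.cue_rate:
                    sentences.append(factory.drug_negative(drug))
                if struct_hit:
                    structured_drugs.append(
                        StructuredDrugRecord(pid, drug.code, "2020-01-01")
                    )
            else:
                lab = labs_by_code[next(iter(group.codes))]
                if text_hit:
                    s, ents, meas = factory.lab_sentence(lab, positive=True)
                    sentences.append((s, ents))
                elif rng.random() < cfg.cue_rate:
                    s, ents, meas = factory.lab_sentence(lab, positive=False)
                    sentences.append((s, ents))
                if lab.kind == "numeric":
                    # the structured system always knows the reference range;
                    # the stored value decides structured positivity
                    value = (
                        round(rng.uniform(lab.ref_high * 2, lab.ref_high * 8), 1)
                        if struct_hit
                        else round(rng.uniform(lab.ref_low, lab.ref_high), 1)
                    )
                    structured_labs.append(
                        StructuredLabRecord(
                            pid, lab.code, value, lab.unit,
                            lab.ref_low, lab.ref_high, None, "2020-01-01",
                        )
                    )
                elif struct_hit:
                    structured_labs.append(
                        StructuredLabRecord(
                            pid, lab.code,
                            160.0 if lab.kind == "titer" else 1.0,
                            "titer" if lab.kind == "titer" else "",
                            None, None, True, "2020-01-01",
                        )
                    )

            if struct_hit and text_hit:
                flag = "both"
            elif struct_hit:
                flag = "structured_only"
            elif text_hit:
                flag = "unstructured_only"
            else:
                flag = "absent"
            truth_rows.append(
                {"patient_id": pid, "group": group.name, "flag": flag}
            )

        # distractor content outside the studied groups
        if filler_drugs and rng.random() < 0.6:
            drug = rng.choice(filler_drugs)
            sentences.append(
                factory.drug_affirm(drug)
                if rng.random() < 0.5
                else factory.drug_negative(drug)
            )
        if filler_labs and rng.random() < 0.6:
            lab = rng.choice(filler_labs)
            s, ents, _ = factory.lab_sentence(lab, positive=rng.random() < 0.3)
            sentences.append((s, ents))
        sentences.append(("Examen clinique du jour réalisé.", []))

        rng.shuffle(sentences)

        # distribute sentences over the patient's notes
        n_notes = max(1, cfg.notes_per_patient)
        buckets: list[list[tuple[str, list[Entity]]]] = [[] for _ in range(n_notes)]
        for i, s in enumerate(sentences):
            buckets[i % n_notes].append(s)
        for j, bucket in enumerate(buckets):
            doc_id = f"{pid}-N{j}"
            parts: list[str] = []
            ents: list[Entity] = []
            offset = 0
            for text, sent_ents in bucket:
                parts.append(text)
                for k, e in enumerate(sent_ents):
                    ents.append(
                        replace(
                            e,
                            entity_id=f"G{len(ents) + 1}",
                            start=e.start + offset,
                            end=e.end + offset,
                        )
                    )
                offset += len(text) + 1  # sentences joined by newline
            documents.append(
                Document(doc_id, pid, "\n".join(parts), "2020-01-01")
            )
            gold[doc_id] = sorted(ents, key=lambda e: (e.start, e.end, e.label))

    drug_dict = KnowledgeDictionary(
        [
            DictionaryEntry(d.code, syn, "fr", "ATC")
            for d in cfg.drugs
            for syn in (d.name, *d.synonyms)
        ]
    )
    lab_dict = KnowledgeDictionary(
        [
            DictionaryEntry(l.code, syn, "fr", "LAB")
            for l in cfg.labs
            for syn in (l.name, *l.synonyms)
        ]
    )

    corpus = Corpus(
        documents=documents,
        gold=gold,
        drug_dictionary=drug_dict,
        lab_dictionary=lab_dict,
        structured_labs=structured_labs,
        structured_drugs=structured_drugs,
    )
    truth = pd.DataFrame(truth_rows, columns=["patient_id", "group", "flag"])
    return SynthCohort(corpus, list(cfg.groups), truth, cfg)
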