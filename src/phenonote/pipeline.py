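"""Orchestration of the laboratory-test and drug pipelines.

The laboratory pipeline recognizes test names and complete tests, extracts
and standardizes measurements, and normalizes test names to dictionary
codes; the drug pipeline recognizes drug names (with strength / dose /
form), qualifies each drug mention along four axes, and normalizes names to
ATC codes.  The fused output feeds per-patient phenotyping.

Every stage is a pure function over the document, so stages can be enabled
independently; all randomness flows from the single configured seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import crf as crf_mod
from .documents import (
    Corpus,
    Document,
    Entity,
    Measurement,
    load_corpus,
)
from .evaluation import BootstrapConfig, EvalReport, evaluate_documents
from .fold import fold
from .measurements import (
    UnitTable,
    default_qualitative_lexicon,
    default_unit_table,
    parse_complete_lab,
)
from .ner import bilou_decode, bilou_encode, dict_match, tokenize
from .normalization import (
    DEFAULT_EMBEDDING_THRESHOLD,
    DEFAULT_STRING_PARAMS,
    StringSimilarityParams,
    normalize_term,
)
from .phenotyping import (
    ConceptGroup,
    aggregate_patients,
    cohort_table,
    filter_entities,
    read_concept_groups,
)
from .qualification import CueLexicon, default_cue_lexicon, qualify

NER_LABELS = (
    "lab_name",
    "lab_complete",
    "drug_name",
    "drug_dose",
    "drug_form",
    "drug_strength",
)


@dataclass
class PipelineConfig:
    ner_mode: str = "dictionary"  # dictionary | crf
    model_path: Optional[str] = None
    drug_norm_method: str = "jaro_winkler"
    drug_norm_threshold: float = DEFAULT_STRING_PARAMS.threshold
    lab_norm_method: str = "embedding"
    lab_norm_threshold: float = DEFAULT_EMBEDDING_THRESHOLD
    string_params: StringSimilarityParams = field(default_factory=StringSimilarityParams)
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    run_normalization: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ner_mode not in ("dictionary", "crf"):
            raise ValueError(f"unknown NER mode {self.ner_mode!r}")
        if self.ner_mode == "crf" and not self.model_path:
            raise ValueError("crf mode requires a model path")


# ---------------------------------------------------------------------------
# stage 1: NER
# ---------------------------------------------------------------------------

# separators never span a line break: lab values follow their name inline
_SEP_RE = re.compile(r"[ \t]*[:=][ \t]*|[ \t]+")
_TITER_RE = re.compile(r"1\s*/\s*\d+")
_NUMBER_RE = re.compile(r"\d+(?:[.,]\d+)?")
_UNIT_AFTER_RE = re.compile(r"\s?[A-Za-zµ%][A-Za-z0-9/%µ]*")
_WORD_RE = re.compile(r"[^\W\d_]+", re.UNICODE)


def extend_lab_completes(
    text: str, lab_names: list[Entity], qualitative_lexicon: Optional[dict] = None
) -> list[Entity]:
    """Derive lab_complete spans for the dictionary baseline by extending
    each recognized test name over a following separator + value (+ unit)
    pattern (titer, numeric or qualitative)."""
    lex = (
        qualitative_lexicon
        if qualitative_lexicon is not None
        else default_qualitative_lexicon()
    )
    completes: list[Entity] = []
    for name in lab_names:
        sep = _SEP_RE.match(text, name.end)
        if not sep:
            continue
        pos = sep.end()
        end: Optional[int] = None
        m = _TITER_RE.match(text, pos)
        if m:
            end = m.end()
        else:
            m = _NUMBER_RE.match(text, pos)
            if m:
                end = m.end()
                um = _UNIT_AFTER_RE.match(text, end)
                if um:
                    end = um.end()
            else:
                w = _WORD_RE.match(text, pos)
                if w and fold(w.group()) in lex:
                    end = w.end()
                elif w:  # two-word qualitative forms ("non détecté")
                    w2 = _WORD_RE.match(text, w.end() + 1)
                    if w2 and fold(text[w.start() : w2.end()]) in lex:
                        end = w2.end()
        if end is not None and end > name.end:
            completes.append(
                Entity(
                    f"C{len(completes) + 1}",
                    "lab_complete",
                    name.start,
                    end,
                    text[name.start : end],
                )
            )
    return completes


def run_ner(doc: Document, corpus: Corpus, cfg: PipelineConfig, models=None) -> list[Entity]:
    """Stage 1: recognize the six entity categories in one document."""
    if cfg.ner_mode == "dictionary":
        entities: list[Entity] = []
        if corpus.drug_dictionary:
            entities += dict_match(doc.text, corpus.drug_dictionary, "drug_name")
        if corpus.lab_dictionary:
            lab_names = dict_match(doc.text, corpus.lab_dictionary, "lab_name")
            entities += lab_names
            entities += extend_lab_completes(doc.text, lab_names)
    else:
        tokens = tokenize(doc.text)
        entities = []
        for label in NER_LABELS:
            model = models.get(label) if models else None
            if model is None:
                continue
            tags = crf_mod.viterbi(model, tokens)
            entities += bilou_decode(tokens, tags, doc.text)
    entities.sort(key=lambda e: (e.start, e.end, e.label))
    for i, e in enumerate(entities, start=1):
        e.entity_id = f"E{i}"
    return entities


# ---------------------------------------------------------------------------
# stages 2-4
# ---------------------------------------------------------------------------


def run_qualification(
    doc: Document, entities: list[Entity], lexicon: Optional[CueLexicon] = None
) -> list[Entity]:
    """Stage 2: qualify drug_name entities; other labels pass through."""
    lex = lexicon if lexicon is not None else default_cue_lexicon()
    tokens = tokenize(doc.text)
    for ent in entities:
        if ent.label == "drug_name":
            ent.qualifiers = qualify(ent, tokens, doc.text, lex)
    return entities


def run_measurements(
    entities: list[Entity], unit_table: Optional[UnitTable] = None
) -> list[Entity]:
    """Stage 3: attach standardized measurements to lab_complete entities."""
    names = [e for e in entities if e.label == "lab_name"]
    for ent in entities:
        if ent.label != "lab_complete":
            continue
        nested = [n for n in names if ent.start <= n.start and n.end <= ent.end]
        ent.measurement = parse_complete_lab(ent, nested, unit_table)
    return entities


def run_normalization(
    entities: list[Entity], corpus: Corpus, cfg: PipelineConfig
) -> list[Entity]:
    """Stage 4: assign dictionary codes to drug and lab names; each
    lab_complete inherits the code of its nested test name."""
    for ent in entities:
        if ent.label == "drug_name" and corpus.drug_dictionary:
            ent.concept = normalize_term(
                ent.surface,
                corpus.drug_dictionary,
                method=cfg.drug_norm_method,
                params=cfg.string_params,
                threshold=cfg.drug_norm_threshold,
            )
        elif ent.label == "lab_name" and corpus.lab_dictionary:
            ent.concept = normalize_term(
                ent.surface,
                corpus.lab_dictionary,
                method=cfg.lab_norm_method,
                params=cfg.string_params,
                threshold=cfg.lab_norm_threshold,
            )
    names = [e for e in entities if e.label == "lab_name" and e.concept]
    for ent in entities:
        if ent.label == "lab_complete" and ent.concept is None:
            nested = [n for n in names if ent.start <= n.start and n.end <= ent.end]
            if nested:
                ent.concept = nested[0].concept
    return entities


def process_document(
    doc: Document, corpus: Corpus, cfg: PipelineConfig, models=None
) -> list[Entity]:
    entities = run_ner(doc, corpus, cfg, models)
    entities = run_qualification(doc, entities)
    entities = run_measurements(entities)
    if cfg.run_normalization:
        entities = run_normalization(entities, corpus, cfg)
    return entities


# ---------------------------------------------------------------------------
# serialization of pipeline output
# ---------------------------------------------------------------------------


def entity_record(doc: Document, ent: Entity) -> dict:
    rec = {
        "doc_id": doc.doc_id,
        "patient_id": doc.patient_id,
        "entity_id": ent.entity_id,
        "label": ent.label,
        "start": ent.start,
        "end": ent.end,
        "surface": ent.surface,
    }
    if ent.qualifiers is not None:
        q = ent.qualifiers
        rec["qualifiers"] = {
            "action": q.action,
            "temporality": q.temporality,
            "certainty": q.certainty,
            "negation": q.negation,
        }
    if ent.measurement is not None:
        m = ent.measurement
        rec["measurement"] = {
            "value": m.value,
            "unit": m.unit,
            "is_qualitative": m.is_qualitative,
            "raw": m.raw,
            "unit_unknown": m.unit_unknown,
        }
    if ent.concept is not None:
        rec["concept"] = {
            "code": ent.concept.code,
            "matched_synonym": ent.concept.matched_synonym,
            "score": ent.concept.score,
            "method": ent.concept.method,
        }
    if ent.codes:
        rec["codes"] = list(ent.codes)
    return rec


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------


@dataclass
class PipelineResult:
    entities_by_doc: dict[str, list[Entity]]
    phenotypes: pd.DataFrame  # patient_id, group, flag
    cohort: pd.DataFrame
    log: dict


def run_pipeline(
    corpus: Corpus | str | Path,
    groups: list[ConceptGroup],
    cfg: PipelineConfig = PipelineConfig(),
    out_dir: Optional[str | Path] = None,
    models=None,
) -> PipelineResult:
    """Run NER → qualification → measurement → normalization → phenotyping
    over a corpus and (optionally) write the JSONL/CSV outputs."""
    if not isinstance(corpus, Corpus):
        corpus = load_corpus(corpus)
    if cfg.ner_mode == "crf" and models is None:
        models = load_model_bundle(cfg.model_path)

    entities_by_doc: dict[str, list[Entity]] = {}
    stage_log = []
    for doc in corpus.documents:
        ents = process_document(doc, corpus, cfg, models)
        entities_by_doc[doc.doc_id] = ents
        stage_log.append(
            {
                "doc_id": doc.doc_id,
                "n_entities": len(ents),
                "n_measured": sum(e.measurement is not None for e in ents),
                "n_normalized": sum(e.concept is not None for e in ents),
            }
        )

    by_patient: dict[str, list[Entity]] = {}
    for doc in corpus.documents:
        kept = filter_entities(entities_by_doc[doc.doc_id])
        by_patient.setdefault(doc.patient_id, []).extend(kept)

    patient_ids = {d.patient_id for d in corpus.documents}
    phenos = aggregate_patients(
        corpus.structured_labs,
        corpus.structured_drugs,
        by_patient,
        groups,
        patient_ids=patient_ids,
    )
    pheno_df = pd.DataFrame(
        [
            {"patient_id": p.patient_id, "group": g, "flag": f}
            for p in phenos
            for g, f in p.flags.items()
        ],
        columns=["patient_id", "group", "flag"],
    )
    cohort = cohort_table(phenos, groups, cohort_size=len(patient_ids))

    log = {
        "config": _config_digest(cfg),
        "seed": cfg.seed,
        "n_documents": len(corpus.documents),
        "n_patients": len(patient_ids),
        "stages": stage_log,
    }
    result = PipelineResult(entities_by_doc, pheno_df, cohort, log)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "entities.jsonl", "w", encoding="utf-8") as fh:
            for doc in corpus.documents:
                for ent in entities_by_doc[doc.doc_id]:
                    fh.write(
                        json.dumps(entity_record(doc, ent), ensure_ascii=False) + "\n"
                    )
        pheno_df.to_csv(out / "phenotypes.csv", index=False)
        cohort.to_csv(out / "cohort_table.csv", index=False)
        (out / "run_log.json").write_text(
            json.dumps(log, indent=2), encoding="utf-8"
        )
    return result


def _config_digest(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    blob = json.dumps(d, sort_keys=True, default=str)
    return {"hash": hashlib.sha256(blob.encode()).hexdigest()[:12], **d}


# ---------------------------------------------------------------------------
# CRF training over a corpus
# ---------------------------------------------------------------------------


def split_documents(
    doc_ids: list[str], fractions: tuple[float, float] = (0.806, 0.194), seed: int = 0
) -> tuple[list[str], list[str]]:
    """Seeded document-level train/test split; the train share is rounded to
    the nearest document (103 documents at the default fractions give an
    83/20 split)."""
    if len(doc_ids) < 2:
        raise ValueError("need at least 2 documents to split")
    import random

    rng = random.Random(seed)
    ids = sorted(doc_ids)
    rng.shuffle(ids)
    n_train = int(round(len(ids) * fractions[0] / sum(fractions)))
    n_train = min(max(n_train, 1), len(ids) - 1)
    return ids[:n_train], ids[n_train:]


def load_model_bundle(path: str | Path) -> dict[str, crf_mod.CrfModel]:
    bundle = json.loads(Path(path).read_text(encoding="utf-8"))
    models = {}
    for label, payload in bundle.items():
        import numpy as np

        models[label] = crf_mod.CrfModel(
            tags=payload["tags"],
            feature_index=payload["feature_index"],
            emissions=np.asarray(payload["emissions"], dtype=float),
            transitions=np.asarray(payload["transitions"], dtype=float),
            encoder_id=payload["encoder_id"],
            l2_sigma=payload["l2_sigma"],
            metadata=payload.get("metadata", {}),
        )
    return models


def save_model_bundle(models: dict[str, crf_mod.CrfModel], path: str | Path) -> None:
    bundle = {
        label: {
            "tags": m.tags,
            "feature_index": m.feature_index,
            "emissions": m.emissions.tolist(),
            "transitions": m.transitions.tolist(),
            "encoder_id": m.encoder_id,
            "l2_sigma": m.l2_sigma,
            "metadata": m.metadata,
        }
        for label, m in models.items()
    }
    Path(path).write_text(json.dumps(bundle), encoding="utf-8")


def train_ner(
    corpus: Corpus | str | Path,
    fractions: tuple[float, float] = (0.806, 0.194),
    seed: int = 0,
    epochs: int = 50,
    l2_sigma: float = 1.0,
    learning_rate: float = 0.2,
    labels: tuple[str, ...] = NER_LABELS,
    model_path: Optional[str | Path] = None,
) -> tuple[dict[str, crf_mod.CrfModel], EvalReport]:
    """Train one CRF layer per entity label on a seeded document split and
    score the held-out documents strictly."""
    if not isinstance(corpus, Corpus):
        corpus = load_corpus(corpus)
    if not corpus.gold:
        raise ValueError("training requires gold annotations")

    train_ids, test_ids = split_documents(
        [d.doc_id for d in corpus.documents], fractions, seed
    )

    models: dict[str, crf_mod.CrfModel] = {}
    for label in labels:
        training = []
        for doc_id in train_ids:
            doc = corpus.doc(doc_id)
            tokens = tokenize(doc.text)
            gold = [e for e in corpus.gold.get(doc_id, []) if e.label == label]
            tags = bilou_encode(tokens, gold, label)
            training.append((tokens, tags))
        models[label] = crf_mod.crf_train(
            training,
            l2_sigma=l2_sigma,
            epochs=epochs,
            seed=seed,
            learning_rate=learning_rate,
        )

    pred_by_doc = {}
    gold_by_doc = {}
    for doc_id in test_ids:
        doc = corpus.doc(doc_id)
        tokens = tokenize(doc.text)
        preds: list[Entity] = []
        for label in labels:
            tags = crf_mod.viterbi(models[label], tokens)
            preds += bilou_decode(tokens, tags, doc.text)
        pred_by_doc[doc_id] = preds
        gold_by_doc[doc_id] = corpus.gold.get(doc_id, [])
    report = evaluate_documents(gold_by_doc, pred_by_doc, list(labels), level="ner")

    if model_path is not None:
        save_model_bundle(models, model_path)
    return models, report
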