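"""Strict scoring of NER, end-to-end (NER + normalization) and measurement
extraction, with document-level empirical bootstrap confidence intervals.

Matching is strict throughout: a predicted entity scores a true positive
only with exactly the gold boundaries and label; end-to-end additionally
requires the predicted code to belong to the gold code list; measurement
scoring requires the canonical value and unit to agree.  Precision, recall
and F1 are reported on the percent scale.

Confidence intervals resample whole documents with replacement and
recompute the pooled-count (micro-average) metric on every replicate;
both the percentile and the basic ("reflected") bootstrap variant are
available, percentile being the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .documents import Entity


@dataclass(frozen=True)
class BootstrapConfig:
    replicates: int = 1000
    alpha: float = 0.05
    seed: int = 0
    variant: str = "percentile"  # percentile | basic

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("need at least one bootstrap replicate")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.variant not in ("percentile", "basic"):
            raise ValueError(f"unknown bootstrap variant {self.variant!r}")


@dataclass
class LabelScore:
    label: str
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    precision_ci: Optional[tuple[float, float]] = None
    recall_ci: Optional[tuple[float, float]] = None
    f1_ci: Optional[tuple[float, float]] = None


@dataclass
class EvalReport:
    scores: dict[str, LabelScore]
    bootstrap: Optional[BootstrapConfig] = None


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------


def _greedy_match(
    gold: list[Entity], pred: list[Entity], same
) -> tuple[int, int, int]:
    """One-to-one greedy matching in document order."""
    used = [False] * len(gold)
    tp = 0
    for p in pred:
        for i, g in enumerate(gold):
            if not used[i] and same(g, p):
                used[i] = True
                tp += 1
                break
    return tp, len(pred) - tp, len(gold) - tp


def strict_counts(
    gold: Sequence[Entity], pred: Sequence[Entity], label: str
) -> tuple[int, int, int]:
    """(TP, FP, FN) with exact boundary + label matching."""
    g = [e for e in gold if e.label == label]
    p = [e for e in pred if e.label == label]
    return _greedy_match(g, p, lambda a, b: a.span == b.span)


def e2e_counts(
    gold: Sequence[Entity], pred: Sequence[Entity], label: str
) -> tuple[int, int, int]:
    """(TP, FP, FN) where a TP additionally requires the predicted code to be
    in the gold entity's list of acceptable codes."""

    def same(g: Entity, p: Entity) -> bool:
        if g.span != p.span:
            return False
        pred_code = p.concept.code if p.concept is not None else None
        if pred_code is None:
            values = p.code_values()
            pred_code = values[0] if values else None
        return pred_code is not None and pred_code in g.code_values()

    g = [e for e in gold if e.label == label]
    p = [e for e in pred if e.label == label]
    return _greedy_match(g, p, same)


def measurement_counts(
    gold: Sequence[Entity], pred: Sequence[Entity]
) -> tuple[int, int, int]:
    """(TP, FP, FN) over measurements attached to lab_complete spans.

    A TP requires the exact gold span plus equal canonical value (tolerance
    1e-9) and unit; a span match with a wrong measurement is both a FP and a
    FN, mirroring the strict same-value-and-unit rule.
    """

    def same(g: Entity, p: Entity) -> bool:
        if g.span != p.span or g.measurement is None or p.measurement is None:
            return False
        gm, pm = g.measurement, p.measurement
        return (
            gm.is_qualitative == pm.is_qualitative
            and gm.unit == pm.unit
            and abs(gm.value - pm.value) <= 1e-9
        )

    g = [e for e in gold if e.label == "lab_complete" and e.measurement is not None]
    p = [e for e in pred if e.label == "lab_complete" and e.measurement is not None]
    return _greedy_match(g, p, same)


def prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Precision, recall, F1 on the percent scale; zero denominators give 0."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    p = 100.0 * tp / (tp + fp) if tp + fp else 0.0
    r = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return (p, r, f1)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

_METRIC_INDEX = {"precision": 0, "recall": 1, "f1": 2}


def _metric_from_counts(counts: np.ndarray, metric: str) -> np.ndarray:
    """Vectorized pooled-count metric; ``counts`` has TP/FP/FN on axis -1."""
    tp = counts[..., 0].astype(float)
    fp = counts[..., 1].astype(float)
    fn = counts[..., 2].astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tp + fp > 0, 100.0 * tp / (tp + fp), 0.0)
        r = np.where(tp + fn > 0, 100.0 * tp / (tp + fn), 0.0)
        if metric == "precision":
            return p
        if metric == "recall":
            return r
        return np.where(p + r > 0, 2 * p * r / (p + r), 0.0)


def bootstrap_ci(
    doc_counts: np.ndarray | Sequence[Sequence[int]],
    metric: str = "f1",
    cfg: BootstrapConfig = BootstrapConfig(),
) -> tuple[float, float]:
    """Document-level bootstrap CI for a pooled-count metric.

    ``doc_counts`` is a (documents, 3) array of per-document TP/FP/FN.
    Documents are resampled with replacement ``cfg.replicates`` times and the
    metric is recomputed from the pooled counts of each resample.
    """
    if metric not in _METRIC_INDEX:
        raise ValueError(f"unknown metric {metric!r}")
    counts = np.asarray(doc_counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != 3 or counts.shape[0] < 1:
        raise ValueError("doc_counts must be a non-empty (documents, 3) array")
    D = counts.shape[0]
    rng = np.random.default_rng(cfg.seed)
    idx = rng.integers(0, D, size=(cfg.replicates, D))
    pooled = counts[idx].sum(axis=1)  # (B, 3)
    scores = _metric_from_counts(pooled, metric)
    lo_q, hi_q = 100 * cfg.alpha / 2, 100 * (1 - cfg.alpha / 2)
    lo, hi = np.percentile(scores, [lo_q, hi_q])
    if cfg.variant == "basic":
        point = float(_metric_from_counts(counts.sum(axis=0), metric))
        lo, hi = 2 * point - hi, 2 * point - lo
    return (float(lo), float(hi))


# ---------------------------------------------------------------------------
# corpus-level reports
# ---------------------------------------------------------------------------


def evaluate_documents(
    gold_by_doc: dict[str, list[Entity]],
    pred_by_doc: dict[str, list[Entity]],
    labels: Sequence[str],
    level: str = "ner",
    bootstrap: Optional[BootstrapConfig] = None,
) -> EvalReport:
    """Score a corpus label by label (plus an ``overall`` row pooling all
    labels) at one of three levels: ``ner`` (strict spans), ``e2e`` (spans +
    codes) or ``measurement``."""
    counters = {"ner": strict_counts, "e2e": e2e_counts}
    doc_ids = sorted(set(gold_by_doc) | set(pred_by_doc))

    per_label_doc_counts: dict[str, np.ndarray] = {}
    if level == "measurement":
        rows = [
            measurement_counts(gold_by_doc.get(d, []), pred_by_doc.get(d, []))
            for d in doc_ids
        ]
        per_label_doc_counts["lab_complete"] = np.array(rows, dtype=int).reshape(-1, 3)
        labels = ["lab_complete"]
    else:
        count_fn = counters[level]
        for label in labels:
            rows = [
                count_fn(gold_by_doc.get(d, []), pred_by_doc.get(d, []), label)
                for d in doc_ids
            ]
            per_label_doc_counts[label] = np.array(rows, dtype=int).reshape(-1, 3)

    scores: dict[str, LabelScore] = {}
    overall = np.zeros((len(doc_ids), 3), dtype=int)
    for label in labels:
        dc = per_label_doc_counts[label]
        overall = overall + dc
        scores[label] = _score_from_doc_counts(label, dc, bootstrap)
    if len(labels) > 1:
        scores["overall"] = _score_from_doc_counts("overall", overall, bootstrap)
    return EvalReport(scores=scores, bootstrap=bootstrap)


def _score_from_doc_counts(
    label: str, dc: np.ndarray, bootstrap: Optional[BootstrapConfig]
) -> LabelScore:
    tp, fp, fn = (int(x) for x in dc.sum(axis=0))
    p, r, f1 = prf(tp, fp, fn)
    score = LabelScore(label, tp, fp, fn, p, r, f1)
    if bootstrap is not None and len(dc) > 0:
        score.precision_ci = bootstrap_ci(dc, "precision", bootstrap)
        score.recall_ci = bootstrap_ci(dc, "recall", bootstrap)
        score.f1_ci = bootstrap_ci(dc, "f1", bootstrap)
    return score


def report_frame(report: EvalReport, decimals: int = 1):
    """Tabular view of a report (one row per label, CI columns when
    bootstrapped), rounded for display."""
    import pandas as pd

    rows = []
    for label, s in report.scores.items():
        row = {
            "label": label,
            "n_gold": s.tp + s.fn,
            "tp": s.tp,
            "fp": s.fp,
            "fn": s.fn,
            "precision": round(s.precision, decimals),
            "recall": round(s.recall, decimals),
            "f1": round(s.f1, decimals),
        }
        for name, ci in (
            ("precision_ci", s.precision_ci),
            ("recall_ci", s.recall_ci),
            ("f1_ci", s.f1_ci),
        ):
            if ci is not None:
                row[name] = f"{round(ci[0], decimals)}-{round(ci[1], decimals)}"
        rows.append(row)
    return pd.DataFrame(rows)
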