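"""Qualification of drug mentions along four axes (action, temporality,
certainty, negation) with a cue-lexicon rule engine.

A cue lexicon entry is (surface form, axis, value, direction, max token
distance).  For each axis the nearest in-scope cue — same sentence, within
the distance bound, on the licensed side of the entity — overrides the axis
default.  Defaults are the "keep" state of the downstream phenotyping
filter: action=unknown, temporality=present, certainty=certain,
negation=false.

Sentence boundaries follow the line-oriented structure of clinical notes: a
newline always ends a sentence, as does a period followed by whitespace and
an upper-case letter.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

from .documents import DEFAULT_QUALIFIERS, Entity, Qualifiers
from .documents import ACTIONS, CERTAINTIES, TEMPORALITIES
from .fold import fold, fold_with_map
from .ner import Token

_AXIS_VALUES = {
    "action": set(ACTIONS),
    "temporality": set(TEMPORALITIES),
    "certainty": set(CERTAINTIES),
    "negation": {"true", "false"},
}


@dataclass(frozen=True)
class CueEntry:
    cue: str
    axis: str
    value: str  # "true"/"false" for negation
    direction: str  # before | after | both
    max_token_distance: int

    def __post_init__(self) -> None:
        if self.axis not in _AXIS_VALUES:
            raise ValueError(f"unknown axis {self.axis!r}")
        if self.value not in _AXIS_VALUES[self.axis]:
            raise ValueError(f"value {self.value!r} invalid for axis {self.axis}")
        if self.direction not in ("before", "after", "both"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.max_token_distance < 1:
            raise ValueError("max_token_distance must be >= 1")


@dataclass
class CueLexicon:
    entries: list[CueEntry]


def read_cue_lexicon(tsv_text: str) -> CueLexicon:
    """TSV columns: cue, axis, value, direction, max_token_distance."""
    entries = []
    for lineno, line in enumerate(tsv_text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if cols[0].strip().lower() == "cue":
            continue
        if len(cols) != 5:
            raise ValueError(f"cue lexicon line {lineno}: expected 5 columns")
        cue, axis, value, direction, dist = (c.strip() for c in cols)
        entries.append(CueEntry(cue, axis, value, direction, int(dist)))
    return CueLexicon(entries)


def default_cue_lexicon() -> CueLexicon:
    """The starter French cue lexicon shipped with the package."""
    text = (
        resources.files("phenonote").joinpath("data/cue_lexicon.tsv").read_text("utf-8")
    )
    return read_cue_lexicon(text)


_SENT_BOUNDARY = re.compile(r"\.(?=\s+[A-ZÀÂÉÈÊÎÔÙÛÇ])|\n")


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Half-open sentence spans covering the whole text."""
    spans = []
    start = 0
    for m in _SENT_BOUNDARY.finditer(text):
        end = m.end()
        spans.append((start, end))
        start = end
    if start < len(text):
        spans.append((start, len(text)))
    return spans or [(0, len(text))]


def qualify(
    entity: Entity,
    tokens: Sequence[Token],
    text: str,
    lexicon: CueLexicon,
) -> Qualifiers:
    """Assign the four qualifier axes to a drug_name entity.

    Deterministic and independent of entity order: for each axis the nearest
    in-scope cue wins, ties broken by lexicon order then by text position.
    """
    if entity.label != "drug_name":
        raise ValueError("only drug_name entities are qualified")

    sent = next(
        (s for s in split_sentences(text) if s[0] <= entity.start and entity.end <= s[1]),
        (0, len(text)),
    )
    sent_tokens = [
        (i, t) for i, t in enumerate(tokens) if sent[0] <= t.start and t.end <= sent[1]
    ]
    if not sent_tokens:
        return DEFAULT_QUALIFIERS

    overlapping = [
        i for i, t in sent_tokens if t.start < entity.end and t.end > entity.start
    ]
    if not overlapping:
        return DEFAULT_QUALIFIERS
    ent_first, ent_last = min(overlapping), max(overlapping)

    folded, omap = fold_with_map(text)
    token_starts = {t.start: i for i, t in enumerate(tokens)}
    token_ends = {t.end: i for i, t in enumerate(tokens)}

    # best per axis: (distance, lexicon order, position) minimized
    best: dict[str, tuple[tuple[int, int, int], str]] = {}
    for order, cue in enumerate(lexicon.entries):
        fcue = fold(cue.cue)
        pos = folded.find(fcue)
        while pos != -1:
            ostart = omap[pos]
            oend = omap[pos + len(fcue) - 1] + 1
            pos = folded.find(fcue, pos + 1)
            if not (sent[0] <= ostart and oend <= sent[1]):
                continue
            if ostart not in token_starts or oend not in token_ends:
                continue
            c_first, c_last = token_starts[ostart], token_ends[oend]
            if c_last < ent_first:  # cue lies before the entity
                if cue.direction == "after":
                    continue
                distance = ent_first - c_last
            elif c_first > ent_last:  # cue lies after the entity
                if cue.direction == "before":
                    continue
                distance = c_first - ent_last
            else:
                continue  # cue overlaps the entity itself
            if distance > cue.max_token_distance:
                continue
            key = (distance, order, ostart)
            if cue.axis not in best or key < best[cue.axis][0]:
                best[cue.axis] = (key, cue.value)

    kwargs: dict[str, object] = {}
    for axis, (_, value) in best.items():
        kwargs[axis] = value == "true" if axis == "negation" else value
    return Qualifiers(**{
        "action": kwargs.get("action", DEFAULT_QUALIFIERS.action),
        "temporality": kwargs.get("temporality", DEFAULT_QUALIFIERS.temporality),
        "certainty": kwargs.get("certainty", DEFAULT_QUALIFIERS.certainty),
        "negation": kwargs.get("negation", DEFAULT_QUALIFIERS.negation),
    })
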