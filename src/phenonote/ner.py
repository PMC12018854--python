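"""Named-entity recognition primitives: tokenization, the BILOU span codec
and the exact-match dictionary baseline.

Six entity categories are recognized (lab_name, lab_complete, drug_name,
drug_dose, drug_form, drug_strength).  Each category is tagged as its own
independent BILOU layer, which lets a lab_name span nest inside a
lab_complete span while same-label spans never overlap.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .documents import Entity, KnowledgeDictionary
from .fold import fold, fold_with_map

# maximal letter runs | maximal digit runs | any single non-space character
_TOKEN_RE = re.compile(r"[^\W\d_]+|\d+|\S", re.UNICODE)


@dataclass(frozen=True)
class Token:
    text: str
    start: int
    end: int


def tokenize(text: str) -> list[Token]:
    """Split ``text`` into letter runs, digit runs and single punctuation
    marks; whitespace is discarded and offsets are exact.

    >>> [t.text for t in tokenize("Hb=9g/dL")]
    ['Hb', '=', '9', 'g', '/', 'dL']
    """
    return [Token(m.group(), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


# ---------------------------------------------------------------------------
# BILOU codec
# ---------------------------------------------------------------------------

def bilou_encode(tokens: list[Token], entities: list[Entity], label: str) -> list[str]:
    """Encode entities of one label over the token sequence.

    Single-token entities become ``U-label``; multi-token entities become
    ``B-label, I-label..., L-label``; everything else is ``O``.  Entity
    boundaries must fall on token boundaries and same-label entities must not
    overlap.
    """
    starts = {t.start: i for i, t in enumerate(tokens)}
    ends = {t.end: i for i, t in enumerate(tokens)}
    tags = ["O"] * len(tokens)
    for ent in entities:
        if ent.label != label:
            continue
        if ent.start not in starts or ent.end not in ends:
            raise ValueError(
                f"entity [{ent.start},{ent.end}) not aligned to token boundaries"
            )
        i, j = starts[ent.start], ends[ent.end]
        if any(tags[k] != "O" for k in range(i, j + 1)):
            raise ValueError(f"overlapping {label} entities at [{ent.start},{ent.end})")
        if i == j:
            tags[i] = f"U-{label}"
        else:
            tags[i] = f"B-{label}"
            for k in range(i + 1, j):
                tags[k] = f"I-{label}"
            tags[j] = f"L-{label}"
    return tags


def _tag_label(tag: str) -> str:
    return tag.split("-", 1)[1]


def bilou_decode(
    tokens: list[Token], tags: list[str], text: str | None = None
) -> list[Entity]:
    """Decode a (possibly invalid) BILOU tag sequence into entities.

    Valid structures parse first: a lone ``U`` tag and a ``B (I...) L`` run
    each yield one entity.  Any remaining invalid run is repaired by the
    relaxed rule: a maximal run of non-O tags sharing one label becomes a
    single entity.  The function is total and inverts :func:`bilou_encode`
    on valid input.
    """
    if len(tokens) != len(tags):
        raise ValueError("tokens and tags must have the same length")
    entities: list[Entity] = []
    n = len(tags)
    counter = 0

    def emit(i: int, j: int, label: str) -> None:
        nonlocal counter
        counter += 1
        start, end = tokens[i].start, tokens[j].end
        if text is not None:
            surface = text[start:end]
        else:
            surface = "".join(
                tokens[k].text
                + (" " if k < j and tokens[k].end < tokens[k + 1].start else "")
                for k in range(i, j + 1)
            )
        entities.append(Entity(f"D{counter}", label, start, end, surface))

    i = 0
    while i < n:
        tag = tags[i]
        if tag == "O":
            i += 1
            continue
        label = _tag_label(tag)
        prefix = tag[0]
        if prefix == "U":
            emit(i, i, label)
            i += 1
            continue
        if prefix == "B":
            j = i + 1
            while j < n and tags[j] == f"I-{label}":
                j += 1
            if j < n and tags[j] == f"L-{label}":
                emit(i, j, label)
                i = j + 1
                continue
        # invalid structure: relaxed repair over the maximal same-label run
        j = i
        while j < n and tags[j] != "O" and _tag_label(tags[j]) == label:
            j += 1
        emit(i, j - 1, label)
        i = j
    return entities


# ---------------------------------------------------------------------------
# dictionary exact matcher
# ---------------------------------------------------------------------------

def dict_match(
    text: str, dictionary: KnowledgeDictionary, label: str
) -> list[Entity]:
    """Exact matching of dictionary synonyms in ``text``.

    Matching is done on the case/diacritic-folded text and requires the match
    to start and end on token boundaries.  Overlapping candidates are
    resolved longest-match-first, then leftmost.  Synonym surfaces in the
    dictionary are stored verbatim; folding happens here at query time.
    """
    tokens = tokenize(text)
    token_starts = {t.start for t in tokens}
    token_ends = {t.end for t in tokens}
    folded, omap = fold_with_map(text)

    candidates: list[tuple[int, int, int, str]] = []  # (-len, start, end, folded syn)
    seen: set[str] = set()
    for entry in dictionary.entries:
        fsyn = fold(entry.synonym)
        if not fsyn or fsyn in seen:
            continue
        seen.add(fsyn)
        pos = folded.find(fsyn)
        while pos != -1:
            ostart = omap[pos]
            oend = omap[pos + len(fsyn) - 1] + 1
            if ostart in token_starts and oend in token_ends:
                candidates.append((-(oend - ostart), ostart, oend, fsyn))
            pos = folded.find(fsyn, pos + 1)

    candidates.sort()
    accepted: list[tuple[int, int]] = []
    entities: list[Entity] = []
    for neg_len, ostart, oend, _ in candidates:
        if any(ostart < e and s < oend for s, e in accepted):
            continue
        accepted.append((ostart, oend))
        entities.append(
            Entity(f"M{len(entities) + 1}", label, ostart, oend, text[ostart:oend])
        )
    entities.sort(key=lambda e: (e.start, e.end))
    return entities
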