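"""Case/diacritic folding used everywhere strings are compared.

Folding = Unicode NFD decomposition, removal of combining marks, then
lower-casing.  French clinical text mixes accented and unaccented spellings
("négatif"/"negatif", "arrêt"/"arret"); all matching in this package happens
on folded strings while offsets always refer to the original text.
"""

from __future__ import annotations

import unicodedata
from functools import lru_cache


@lru_cache(maxsize=4096)
def fold_char(c: str) -> str:
    decomposed = unicodedata.normalize("NFD", c)
    stripped = "".join(ch for ch in decomposed if not unicodedata.combining(ch))
    return stripped.lower()


def fold(s: str) -> str:
    """Fold a whole string (no offset tracking)."""
    return "".join(fold_char(c) for c in s)


def fold_with_map(s: str) -> tuple[str, list[int]]:
    """Fold ``s`` and return (folded, omap) where ``omap[i]`` is the index in
    ``s`` of the original character that produced folded character ``i``.

    A single original character may fold to zero, one or several characters
    (e.g. a combining mark folds to nothing); the map lets a match found in
    folded space be projected back onto original-text offsets.
    """
    out: list[str] = []
    omap: list[int] = []
    for i, c in enumerate(s):
        f = fold_char(c)
        out.append(f)
        omap.extend([i] * len(f))
    return "".join(out), omap
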