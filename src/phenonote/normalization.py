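"""Terminology normalization: map a detected surface form to the best
matching code of a knowledge dictionary.

Every synonym of the dictionary is scored against the (folded) term and the
code of the argmax synonym is returned, provided its score reaches the
no-match threshold τ.  Three scorers are available:

* ``levenshtein`` — edit distance normalized to a [0, 1] similarity,
* ``jaro_winkler`` — Jaro similarity with the common-prefix boost,
* ``embedding`` — cosine similarity of term embeddings.  The default
  embedder is an L2-normalized character 3-gram count vector; any
  fixed-dimension term encoder can be substituted through the same
  interface.

With τ = 0 the argmax synonym is always returned; raising τ can only turn a
match into no-match, never change the returned code.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Optional

from .documents import ConceptMatch, KnowledgeDictionary
from .fold import fold


@dataclass(frozen=True)
class StringSimilarityParams:
    """Parameters of the string scorers.

    ``prefix_scale`` and ``max_prefix`` are the Winkler boost parameters
    (classic defaults 0.1 and 4); ``threshold`` is the no-match cutoff τ.
    """

    prefix_scale: float = 0.1
    max_prefix: int = 4
    threshold: float = 0.85

    def __post_init__(self) -> None:
        if not (0.0 < self.prefix_scale <= 0.25):
            raise ValueError("prefix_scale must be in (0, 0.25]")
        if self.max_prefix > 4:
            raise ValueError("max_prefix must be <= 4")
        if not (0.0 <= self.threshold <= 1.0):
            raise ValueError("threshold must be in [0, 1]")


DEFAULT_STRING_PARAMS = StringSimilarityParams()
DEFAULT_EMBEDDING_THRESHOLD = 0.60


def levenshtein(a: str, b: str) -> int:
    """Minimum number of single-character insertions, deletions and
    substitutions turning ``a`` into ``b`` (iterative two-row DP)."""
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[len(b)]


def lev_similarity(a: str, b: str) -> float:
    """1 − d/max(|a|,|b|); 1.0 for two empty strings."""
    if not a and not b:
        return 1.0
    return 1.0 - levenshtein(a, b) / max(len(a), len(b))


def _jaro(a: str, b: str) -> float:
    if a == b:
        return 1.0
    if not a or not b:
        return 0.0
    window = max(len(a), len(b)) // 2 - 1
    match_a = [False] * len(a)
    match_b = [False] * len(b)
    m = 0
    for i, ca in enumerate(a):
        lo, hi = max(0, i - window), min(len(b), i + window + 1)
        for j in range(lo, hi):
            if not match_b[j] and b[j] == ca:
                match_a[i] = match_b[j] = True
                m += 1
                break
    if m == 0:
        return 0.0
    # transpositions: mismatched positions among matched characters, halved
    bs = [b[j] for j in range(len(b)) if match_b[j]]
    t = sum(ca != cb for ca, cb in zip((a[i] for i in range(len(a)) if match_a[i]), bs))
    t /= 2
    return (m / len(a) + m / len(b) + (m - t) / m) / 3.0


def jaro_winkler(
    a: str, b: str, params: StringSimilarityParams = DEFAULT_STRING_PARAMS
) -> float:
    """Jaro similarity boosted by the common-prefix term ℓ·p·(1 − jaro)."""
    j = _jaro(a, b)
    prefix = 0
    for ca, cb in zip(a, b):
        if ca != cb or prefix >= params.max_prefix:
            break
        prefix += 1
    return j + prefix * params.prefix_scale * (1.0 - j)


# ---------------------------------------------------------------------------
# embedding scorer
# ---------------------------------------------------------------------------

Embedder = Callable[[str], dict[str, float]]


def embed_term(term: str) -> dict[str, float]:
    """Default deterministic embedder: L2-normalized character 3-gram counts
    over the folded term (whole term as a single gram when shorter than 3)."""
    if not term:
        raise ValueError("cannot embed an empty term")
    f = fold(term)
    grams = [f[i : i + 3] for i in range(len(f) - 2)] or [f]
    counts = Counter(grams)
    norm = math.sqrt(sum(c * c for c in counts.values()))
    return {g: c / norm for g, c in counts.items()}


def cosine(u: dict[str, float], v: dict[str, float]) -> float:
    if len(v) < len(u):
        u, v = v, u
    return sum(w * v.get(g, 0.0) for g, w in u.items())


# ---------------------------------------------------------------------------
# argmax over the dictionary
# ---------------------------------------------------------------------------

_METHODS = ("levenshtein", "jaro_winkler", "embedding", "exact")


def normalize_term(
    term: str,
    dictionary: KnowledgeDictionary,
    method: str = "jaro_winkler",
    params: StringSimilarityParams = DEFAULT_STRING_PARAMS,
    threshold: Optional[float] = None,
    embedder: Embedder = embed_term,
) -> Optional[ConceptMatch]:
    """Score ``term`` against every dictionary synonym; return the code of the
    best match if its score reaches τ, else None.

    Ties break by higher score, then lexicographically smallest code, then
    shortest synonym — the scan order over the dictionary never affects the
    result.  The ``exact`` method scores 1.0 on folded equality and 0.0
    otherwise (the dictionary-baseline behavior).
    """
    if method not in _METHODS:
        raise ValueError(f"unknown normalization method {method!r}")
    if threshold is None:
        threshold = (
            DEFAULT_EMBEDDING_THRESHOLD if method == "embedding" else params.threshold
        )
    fterm = fold(term)
    term_vec = None
    if method == "embedding":
        term_vec = embedder(term)

    best: Optional[tuple[float, str, int, str, str]] = None
    for entry in dictionary.entries:
        fsyn = fold(entry.synonym)
        if method == "levenshtein":
            score = lev_similarity(fterm, fsyn)
        elif method == "jaro_winkler":
            score = jaro_winkler(fterm, fsyn, params)
        elif method == "exact":
            score = 1.0 if fterm == fsyn else 0.0
        else:
            score = cosine(term_vec, embedder(entry.synonym)) if fsyn else 0.0
        key = (-score, entry.code, len(fsyn), fsyn, entry.synonym)
        if best is None or key < best:
            best = key
    if best is None:
        return None
    score = -best[0]
    if score < threshold:
        return None
    return ConceptMatch(
        code=best[1], matched_synonym=best[4], score=min(score, 1.0), method=method
    )
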