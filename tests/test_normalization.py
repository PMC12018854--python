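"""String/embedding similarity scorers and dictionary normalization."""

import itertools
from functools import lru_cache

import pytest
from hypothesis import given, strategies as st

from phenonote.normalization import (
    StringSimilarityParams,
    cosine,
    embed_term,
    jaro_winkler,
    lev_similarity,
    levenshtein,
    normalize_term,
)


# -- independent oracles ----------------------------------------------------

def lev_oracle(a: str, b: str) -> int:
    """Memoized recursive definition, independent of the DP implementation."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> int:
        if i == 0:
            return j
        if j == 0:
            return i
        return min(
            rec(i - 1, j) + 1,
            rec(i, j - 1) + 1,
            rec(i - 1, j - 1) + (a[i - 1] != b[j - 1]),
        )

    return rec(len(a), len(b))


def jaro_winkler_reference(s1: str, s2: str, p: float = 0.1) -> float:
    """Direct transcription of the textbook definition."""
    if s1 == s2:
        return 1.0
    if not s1 or not s2:
        return 0.0
    window = max(len(s1), len(s2)) // 2 - 1
    flags1, flags2 = [False] * len(s1), [False] * len(s2)
    matches = 0
    for i, c in enumerate(s1):
        for j in range(max(0, i - window), min(len(s2), i + window + 1)):
            if not flags2[j] and s2[j] == c:
                flags1[i] = flags2[j] = True
                matches += 1
                break
    if not matches:
        return 0.0
    t = (
        sum(
            a != b
            for a, b in zip(
                [c for f, c in zip(flags1, s1) if f],
                [c for f, c in zip(flags2, s2) if f],
            )
        )
        / 2
    )
    jaro = (
        matches / len(s1) + matches / len(s2) + (matches - t) / matches
    ) / 3
    ell = 0
    for a, b in zip(s1, s2):
        if a != b or ell == 4:
            break
        ell += 1
    return jaro + ell * p * (1 - jaro)


ALL_SHORT = [
    "".join(t) for n in range(4) for t in itertools.product("abc", repeat=n)
]


class TestLevenshtein:
    def test_figure_typo_example(self):
        assert levenshtein("paracetomol", "paracetamol") == 1

    @given(st.text(max_size=12))
    def test_identity(self, s):
        assert levenshtein(s, s) == 0

    def test_all_insertions(self):
        assert levenshtein("", "abc") == 3

    def test_exhaustive_small_strings_match_oracle(self):
        for a in ALL_SHORT:
            for b in ALL_SHORT:
                assert levenshtein(a, b) == lev_oracle(a, b)

    @given(st.text(alphabet="abc", min_size=4, max_size=6),
           st.text(alphabet="abc", min_size=4, max_size=6))
    def test_longer_strings_match_oracle(self, a, b):
        assert levenshtein(a, b) == lev_oracle(a, b)

    @given(st.text(alphabet="abcd", max_size=8), st.text(alphabet="abcd", max_size=8),
           st.text(alphabet="abcd", max_size=8))
    def test_metric_axioms(self, a, b, c):
        assert levenshtein(a, b) == levenshtein(b, a)
        assert (levenshtein(a, b) == 0) == (a == b)
        assert levenshtein(a, c) <= levenshtein(a, b) + levenshtein(b, c)


class TestLevSimilarity:
    def test_identical(self):
        assert lev_similarity("abc", "abc") == 1.0
        assert lev_similarity("", "") == 1.0

    def test_disjoint_single_chars(self):
        assert lev_similarity("a", "b") == 0.0

    def test_typo_similarity_value(self):
        assert lev_similarity("paracetomol", "paracetamol") == pytest.approx(1 - 1 / 11)


class TestJaroWinkler:
    def test_identity(self):
        assert jaro_winkler("hémoglobine", "hémoglobine") == 1.0

    def test_disjoint_alphabets(self):
        assert jaro_winkler("aaaa", "bbbb") == 0.0

    def test_classic_hand_value(self):
        # m=6, t=1, jaro=0.9444, prefix length 3 -> 0.9611
        assert jaro_winkler("martha", "marhta") == pytest.approx(0.9611, abs=1e-4)

    @given(st.text(alphabet="abcde", max_size=8), st.text(alphabet="abcde", max_size=8))
    def test_matches_reference_and_bounds(self, a, b):
        v = jaro_winkler(a, b)
        assert v == pytest.approx(jaro_winkler_reference(a, b), abs=1e-12)
        assert 0.0 <= v <= 1.0
        assert v == pytest.approx(jaro_winkler(b, a))
        assert (v == 1.0) == (a == b)

    def test_prefix_scale_bounds_enforced(self):
        with pytest.raises(ValueError):
            StringSimilarityParams(prefix_scale=0.3)


class TestEmbedding:
    def test_unit_norm(self):
        v = embed_term("hydroxychloroquine")
        assert sum(x * x for x in v.values()) == pytest.approx(1.0)

    def test_self_cosine_is_one(self):
        v = embed_term("paracetamol")
        assert cosine(v, v) == pytest.approx(1.0)

    def test_disjoint_trigrams_cosine_zero(self):
        assert cosine(embed_term("aaaa"), embed_term("bbbb")) == 0.0

    def test_empty_term_rejected(self):
        with pytest.raises(ValueError):
            embed_term("")


class TestNormalizeTerm:
    def test_typo_resolves_to_right_code(self, toy_drug_dict):
        m = normalize_term("paracetomol", toy_drug_dict, "jaro_winkler")
        assert m.code == "N02BE01"
        assert m.matched_synonym == "paracetamol"

    def test_exact_synonym_scores_one(self, toy_drug_dict):
        m = normalize_term("ibuprofene", toy_drug_dict, "jaro_winkler")
        assert (m.code, m.score) == ("M01AE01", 1.0)

    def test_gibberish_below_threshold(self, toy_drug_dict):
        assert normalize_term("zzzz", toy_drug_dict, "jaro_winkler") is None

    def test_folding_before_scoring(self, toy_drug_dict):
        m = normalize_term("Paracétamol", toy_drug_dict, "jaro_winkler")
        assert (m.code, m.score) == ("N02BE01", 1.0)

    def test_zero_threshold_always_matches(self, toy_drug_dict):
        assert normalize_term("zzzz", toy_drug_dict, "jaro_winkler", threshold=0.0)

    @given(term=st.sampled_from(["paracetomol", "ibuprofen", "zzzz", "hydroxychloroquine"]),
           tau=st.floats(0.0, 1.0))
    def test_raising_threshold_never_changes_the_code(self, term, tau):
        from phenonote.documents import DictionaryEntry, KnowledgeDictionary

        d = KnowledgeDictionary(
            [
                DictionaryEntry("N02BE01", "paracetamol", "fr", "ATC"),
                DictionaryEntry("M01AE01", "ibuprofene", "fr", "ATC"),
                DictionaryEntry("P01BA02", "hydroxychloroquine", "fr", "ATC"),
            ]
        )
        base = normalize_term(term, d, "jaro_winkler", threshold=0.0)
        gated = normalize_term(term, d, "jaro_winkler", threshold=tau)
        assert gated is None or gated.code == base.code

    def test_tie_broken_by_smallest_code(self):
        from phenonote.documents import DictionaryEntry, KnowledgeDictionary

        d = KnowledgeDictionary(
            [
                DictionaryEntry("B99", "abcd", "fr", "X"),
                DictionaryEntry("A01", "abcd", "fr", "X"),
            ]
        )
        m = normalize_term("abcd", d, "levenshtein", threshold=0.0)
        assert m.code == "A01"

    def test_embedding_method_recovers_exact_synonym(self, toy_drug_dict):
        m = normalize_term("hydroxychloroquine", toy_drug_dict, "embedding")
        assert m.code == "P01BA02" and m.score == pytest.approx(1.0)
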