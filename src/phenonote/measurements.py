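"""Extraction and standardization of laboratory measurements.

A "complete laboratory test" span contains a test name together with its
result (e.g. ``"Hémoglobine : 9 g/dL"`` or ``"AAN positifs"``).  The
procedure is:

1. blank out the nested test-name span(s), keeping separators;
2. extract the value and unit by pattern rules, with precedence
   titer > numeric > qualitative and leftmost match within each class;
3. standardize: qualitative results are graded 1.0 (positive family),
   0.0 (negative family) or 0.5 (normal family); numeric units are converted
   to conventional standards through a configurable unit table; titers
   ``1/N`` become value N with unit ``"titer"`` (larger N = stronger
   positivity, so a ≥ 1/80 threshold is a simple numeric comparison).

French decimal commas are normalized to dots.  All tables (unit
conversions, qualitative lexicon) are TSV config shipped with the package
and fully replaceable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Optional

from .documents import Entity, Measurement
from .fold import fold

# ---------------------------------------------------------------------------
# unit table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class UnitRule:
    pattern: str  # folded source form
    canonical: str
    factor: float


@dataclass
class UnitTable:
    rules: list[UnitRule]

    def __post_init__(self) -> None:
        if any(r.factor <= 0 for r in self.rules):
            raise ValueError("conversion factors must be positive")
        canon = {r.canonical for r in self.rules}
        identities = {
            r.canonical for r in self.rules if fold(r.canonical) == r.pattern and r.factor == 1.0
        }
        missing = canon - identities
        if missing:
            raise ValueError(f"canonical units without identity rows: {sorted(missing)}")

    def lookup(self, raw_unit: str) -> Optional[UnitRule]:
        f = fold(raw_unit).strip()
        for r in self.rules:
            if r.pattern == f:
                return r
        return None


def read_unit_table(tsv_text: str) -> UnitTable:
    rules = []
    for lineno, line in enumerate(tsv_text.splitlines(), start=1):
        if not line.strip():
            continue
        cols = line.rstrip("\n").split("\t")
        if cols[0].strip().lower() == "pattern":
            continue
        if len(cols) != 3:
            raise ValueError(f"unit table line {lineno}: expected 3 columns")
        rules.append(UnitRule(fold(cols[0].strip()), cols[1].strip(), float(cols[2])))
    return UnitTable(rules)


def default_unit_table() -> UnitTable:
    text = (
        resources.files("phenonote").joinpath("data/unit_table.tsv").read_text("utf-8")
    )
    return read_unit_table(text)


# ---------------------------------------------------------------------------
# qualitative lexicon
# ---------------------------------------------------------------------------


def read_qualitative_lexicon(tsv_text: str) -> dict[str, float]:
    """Folded token -> graded value (1.0 / 0.0 / 0.5)."""
    lex: dict[str, float] = {}
    for lineno, line in enumerate(tsv_text.splitlines(), start=1):
        if not line.strip():
            continue
        cols = line.rstrip("\n").split("\t")
        if cols[0].strip().lower() == "token":
            continue
        if len(cols) != 2:
            raise ValueError(f"qualitative lexicon line {lineno}: expected 2 columns")
        value = float(cols[1])
        if value not in (0.0, 0.5, 1.0):
            raise ValueError(f"qualitative lexicon line {lineno}: grade must be 0/0.5/1")
        lex[fold(cols[0].strip())] = value
    return lex


def default_qualitative_lexicon() -> dict[str, float]:
    text = (
        resources.files("phenonote")
        .joinpath("data/qualitative_lexicon.tsv")
        .read_text("utf-8")
    )
    return read_qualitative_lexicon(text)


# ---------------------------------------------------------------------------
# extraction steps
# ---------------------------------------------------------------------------


def strip_test_name(complete: Entity, names: list[Entity]) -> str:
    """Blank the nested test-name character ranges out of the complete span,
    preserving separators (colons, equal signs, spacing)."""
    chars = list(complete.surface)
    for name in names:
        if name.start < complete.start or name.end > complete.end:
            raise ValueError("test-name span lies outside the complete span")
        for k in range(name.start - complete.start, name.end - complete.start):
            chars[k] = " "
    return "".join(chars)


_TITER_RE = re.compile(r"1\s*/\s*(\d+)")
_NUMBER_RE = re.compile(r"\d+(?:[.,]\d+)?")
# a unit directly attached or separated by at most one space from the number
_UNIT_RE = re.compile(r"\s?([A-Za-zµ%][A-Za-z0-9/%µ]*)")


def extract_value_unit(residual: str) -> tuple[str, str]:
    """Extract (raw value token, raw unit token or '') from the residual.

    Precedence: titer pattern ``1/N`` first, then a decimal number (dot or
    comma) with an optionally attached unit, then a qualitative keyword.
    Returns ``("", "")`` when nothing matches.
    """
    m = _TITER_RE.search(residual)
    if m:
        return (m.group(0), "")
    m = _NUMBER_RE.search(residual)
    if m:
        um = _UNIT_RE.match(residual, m.end())
        return (m.group(0), um.group(1) if um else "")
    lex = default_qualitative_lexicon()
    token = _find_qualitative(residual, lex)
    if token is not None:
        return (token, "")
    return ("", "")


def _find_qualitative(residual: str, lexicon: dict[str, float]) -> Optional[str]:
    """Leftmost (then longest) lexicon keyword occurring on word boundaries in
    the folded residual; returns the raw (unfolded) matched token."""
    folded = fold(residual)
    best: Optional[tuple[int, int]] = None  # (start, -len)
    for key in lexicon:
        pos = folded.find(key)
        while pos != -1:
            before_ok = pos == 0 or not folded[pos - 1].isalnum()
            end = pos + len(key)
            after_ok = end == len(folded) or not folded[end].isalnum()
            if before_ok and after_ok:
                cand = (pos, -len(key))
                if best is None or cand < best:
                    best = cand
            pos = folded.find(key, pos + 1)
    if best is None:
        return None
    start, neg_len = best
    return residual[start : start - neg_len]


def standardize_qualitative(
    token: str, lexicon: Optional[dict[str, float]] = None
) -> Optional[float]:
    """Map a qualitative result token to its grade; None when unknown."""
    lex = lexicon if lexicon is not None else default_qualitative_lexicon()
    return lex.get(fold(token).strip())


def convert_unit(
    value: float, raw_unit: str, table: Optional[UnitTable] = None
) -> tuple[float, str, bool]:
    """Convert to the canonical unit; returns (value, unit, known).

    Unmatched units pass through verbatim with ``known=False`` so no
    measurement is silently dropped.
    """
    tbl = table if table is not None else default_unit_table()
    rule = tbl.lookup(raw_unit)
    if rule is None:
        return (value, raw_unit, False)
    return (value * rule.factor, rule.canonical, True)


def parse_complete_lab(
    complete: Entity,
    names: list[Entity],
    unit_table: Optional[UnitTable] = None,
    qualitative_lexicon: Optional[dict[str, float]] = None,
) -> Optional[Measurement]:
    """Full measurement extraction for one complete laboratory test entity.

    Returns None when no value can be found (never raises).
    """
    if complete.label != "lab_complete":
        raise ValueError("measurement extraction expects a lab_complete entity")
    residual = strip_test_name(complete, names)

    m = _TITER_RE.search(residual)
    if m:
        return Measurement(
            value=float(m.group(1)), unit="titer", is_qualitative=False, raw=m.group(0)
        )
    m = _NUMBER_RE.search(residual)
    if m:
        raw_value = m.group(0)
        value = float(raw_value.replace(",", "."))
        um = _UNIT_RE.match(residual, m.end())
        raw_unit = um.group(1) if um else ""
        if raw_unit:
            value, unit, known = convert_unit(value, raw_unit, unit_table)
            return Measurement(
                value=value,
                unit=unit,
                is_qualitative=False,
                raw=f"{raw_value} {raw_unit}".strip(),
                unit_unknown=not known,
            )
        return Measurement(value=value, unit="", is_qualitative=False, raw=raw_value)
    lex = (
        qualitative_lexicon
        if qualitative_lexicon is not None
        else default_qualitative_lexicon()
    )
    token = _find_qualitative(residual, lex)
    if token is not None:
        grade = standardize_qualitative(token, lex)
        if grade is not None:
            return Measurement(value=grade, unit="", is_qualitative=True, raw=token)
    return None
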