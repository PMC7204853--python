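"""Rule-based detection of quoted-speech spans in clinical free text.

Clinicians sometimes record a patient's words verbatim inside quotation
marks.  This module finds those quoted spans with a small deterministic
rule set designed to minimise false positives on messy clinical prose:

* five delimiter characters are recognised — straight double ``"``,
  curly double ``“ ”``, straight single ``'`` and curly single
  ``‘ ’`` — and a quote only ever closes with a delimiter of its
  own class (no cross-style pairing, which on clinical text produces far
  more false positives than it recovers);
* single-quote characters that behave like apostrophes (contractions such
  as ``can't``, possessives such as ``patients'``) are never treated as
  delimiters;
* quotations nested inside a quotation are absorbed into the outer span;
* a candidate whose content exceeds ``max_quote_chars`` (default 1500) is
  discarded outright — an unclosed opener must not swallow the document;
* spans whose entire content is an email address or URL are dropped.

Offsets are 0-based, half-open; ``content`` excludes the delimiters.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable

__all__ = [
    "DocType",
    "RawDocument",
    "ExtractionConfig",
    "QuotedSpan",
    "QuoteRole",
    "classify_quote_character",
    "extract_quoted_spans",
    "count_tokens",
    "quotes_per_token",
    "UndefinedRateError",
]

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


class DocType(str, enum.Enum):
    CORRESPONDENCE = "correspondence"
    CASE_NOTE = "case_note"
    OTHER = "other"


@dataclass(frozen=True)
class RawDocument:
    """One clinical note: free text plus patient/date metadata."""

    doc_id: str
    patient_id: str
    timestamp: date
    doc_type: DocType = DocType.OTHER
    text: str = ""


# Delimiter classes, keyed by the opener character.  A class closes only
# with its own closer; the curly classes have distinct open/close glyphs
# and can therefore nest, the straight classes cannot.
_PAIRS: dict[str, str] = {'"': '"', "“": "”", "'": "'", "‘": "’"}
_CLOSER_TO_OPENER: dict[str, str] = {v: k for k, v in _PAIRS.items()}
_SINGLE_QUOTES = {"'", "‘", "’"}
_INVENTORY = set(_PAIRS) | set(_PAIRS.values())

_DEFAULT_SUFFIXES = frozenset({"c", "d", "e", "m", "n", "s", "t", "ve", "re", "ll", "all"})
_DEFAULT_EMAIL = r"[^@\s]+@[^@\s]+\.[^@\s]+"
_DEFAULT_URL = r"(?:[A-Za-z][A-Za-z0-9+.-]*://\S+|www\.\S+)"
# Maximal alphanumeric runs; underscores and punctuation are not tokens.
_DEFAULT_TOKEN = r"[A-Za-z0-9]+"


@dataclass(frozen=True)
class ExtractionConfig:
    """Tunable parameters of the span extractor.

    max_quote_chars: longest admissible quoted content, in characters.
    contraction_suffixes: letter sequences that, directly after a single
        quote preceded by a letter, mark it as an apostrophe.
    email_pattern / url_pattern: a span is dropped when its trimmed
        content fully matches either.
    token_pattern: word-token definition used by :func:`count_tokens`.
    """

    max_quote_chars: int = 1500
    contraction_suffixes: frozenset[str] = _DEFAULT_SUFFIXES
    email_pattern: str = _DEFAULT_EMAIL
    url_pattern: str = _DEFAULT_URL
    token_pattern: str = _DEFAULT_TOKEN

    def __post_init__(self) -> None:
        if self.max_quote_chars <= 0:
            raise ValueError("max_quote_chars must be positive")
        if not self.contraction_suffixes:
            raise ValueError("contraction_suffixes must be non-empty")


@dataclass(frozen=True)
class QuotedSpan:
    """One extracted quotation.

    ``start``/``end`` bracket the delimiters (half-open);
    ``content_start``/``content_end`` bracket the quoted text itself.
    """

    start: int
    end: int
    content_start: int
    content_end: int
    content: str
    delimiter_class: str

    def __post_init__(self) -> None:
        if not (self.start < self.content_start <= self.content_end < self.end):
            raise ValueError("inconsistent span offsets")


class QuoteRole(enum.Enum):
    OPEN = "open"
    CLOSE = "close"
    APOSTROPHE = "apostrophe"
    IGNORE = "ignore"


# ---------------------------------------------------------------------------
# Character classification
# ---------------------------------------------------------------------------


def _suffix_follows(text: str, index: int, suffixes: Iterable[str]) -> bool:
    """True when text[index+1:] starts with a contraction suffix that ends
    at a non-letter boundary (case-insensitive)."""
    tail = text[index + 1 :]
    low = tail.lower()
    for suf in suffixes:
        if low.startswith(suf):
            nxt = tail[len(suf) : len(suf) + 1]
            if not nxt.isalpha():
                return True
    return False


def _is_apostrophe(text: str, index: int, cfg: ExtractionConfig) -> bool:
    left_letter = index > 0 and text[index - 1].isalpha()
    if not left_letter:
        return False
    # between two letters (rock'n'roll) or followed by a contraction
    # suffix ending at a word boundary (can't, we've, patients's)
    if index + 1 < len(text) and text[index + 1].isalpha():
        return True
    return _suffix_follows(text, index, cfg.contraction_suffixes)


def classify_quote_character(
    text: str,
    index: int,
    open_class: str | None = None,
    cfg: ExtractionConfig | None = None,
) -> QuoteRole:
    """Classify the quote-inventory character at ``text[index]``.

    ``open_class`` is the opener character of the currently pending quote,
    or None when scanning outside any quotation.  Single quotes that look
    like apostrophes (contraction suffix after, or letter on both sides)
    classify as APOSTROPHE regardless of pairing state; everything else is
    resolved by class pairing.
    """
    cfg = cfg or ExtractionConfig()
    if not 0 <= index < len(text):
        raise IndexError(f"index {index} out of range for text of length {len(text)}")
    ch = text[index]
    if ch not in _INVENTORY:
        raise ValueError(f"character {ch!r} is not in the quote inventory")

    if ch in _SINGLE_QUOTES and _is_apostrophe(text, index, cfg):
        return QuoteRole.APOSTROPHE

    if ch == '"':
        if open_class == '"':
            return QuoteRole.CLOSE
        return QuoteRole.OPEN if open_class is None else QuoteRole.IGNORE
    if ch == "“":
        return QuoteRole.OPEN if open_class is None else QuoteRole.IGNORE
    if ch == "”":
        return QuoteRole.CLOSE if open_class == "“" else QuoteRole.IGNORE
    if ch == "‘":
        return QuoteRole.OPEN if open_class is None else QuoteRole.IGNORE
    if ch == "’":
        if open_class == "‘":
            return QuoteRole.CLOSE
        # a stray right single quote after a letter is a possessive mark
        if index > 0 and text[index - 1].isalpha():
            return QuoteRole.APOSTROPHE
        return QuoteRole.IGNORE
    # straight single quote
    if open_class == "'":
        return QuoteRole.CLOSE
    if open_class is None:
        if index > 0 and text[index - 1].isalpha():
            # no opener pending and a word immediately left: treat as a
            # trailing possessive apostrophe ("the patients' needs")
            return QuoteRole.APOSTROPHE
        return QuoteRole.OPEN
    return QuoteRole.IGNORE


# ---------------------------------------------------------------------------
# Span extraction
# ---------------------------------------------------------------------------


def _find_closer(text: str, open_idx: int, open_char: str, cfg: ExtractionConfig) -> int | None:
    """Index of the closer matching the opener at ``open_idx``, or None.

    The closer must lie within ``max_quote_chars`` of content.  Curly
    classes track nesting depth so that an inner same-class quotation is
    absorbed; straight classes close at the first non-apostrophe same
    character.
    """
    closer = _PAIRS[open_char]
    nestable = closer != open_char
    limit = open_idx + 1 + cfg.max_quote_chars  # latest admissible closer index
    depth = 0
    j = open_idx + 1
    n = len(text)
    while j < n and j <= limit:
        ch = text[j]
        if ch in _INVENTORY:
            role = classify_quote_character(text, j, open_char, cfg)
            if role is QuoteRole.CLOSE:
                if nestable and depth > 0:
                    depth -= 1
                else:
                    return j
            elif nestable and ch == open_char:
                depth += 1
        j += 1
    return None


def extract_quoted_spans(doc: RawDocument, cfg: ExtractionConfig | None = None) -> list[QuotedSpan]:
    """Extract maximal outer quoted spans from a document.

    Inner quotations are absorbed into the enclosing span.  Candidates
    whose content exceeds ``cfg.max_quote_chars`` are discarded (the
    opener is treated as stray and scanning resumes after it).  Spans
    whose trimmed content fully matches the email or URL pattern are
    removed.  Returned spans are sorted by start and non-overlapping.
    """
    cfg = cfg or ExtractionConfig()
    text = doc.text
    email_re = re.compile(cfg.email_pattern)
    url_re = re.compile(cfg.url_pattern)
    spans: list[QuotedSpan] = []
    i = 0
    n = len(text)
    while i < n:
        ch = text[i]
        if ch in _PAIRS and classify_quote_character(text, i, None, cfg) is QuoteRole.OPEN:
            close = _find_closer(text, i, ch, cfg)
            if close is not None and close > i + 1:
                content = text[i + 1 : close]
                trimmed = content.strip()
                if not (email_re.fullmatch(trimmed) or url_re.fullmatch(trimmed)):
                    spans.append(
                        QuotedSpan(
                            start=i,
                            end=close + 1,
                            content_start=i + 1,
                            content_end=close,
                            content=content,
                            delimiter_class=ch,
                        )
                    )
                i = close + 1
                continue
            if close is not None:
                # empty quotation "" — consume but report nothing
                i = close + 1
                continue
        i += 1
    return spans


# ---------------------------------------------------------------------------
# Tokenisation and exposure rate
# ---------------------------------------------------------------------------


class UndefinedRateError(ZeroDivisionError):
    """Quotes present but no tokens to normalise by."""


def count_tokens(text: str, cfg: ExtractionConfig | None = None) -> int:
    """Number of maximal alphanumeric word tokens in ``text``."""
    pattern = (cfg or ExtractionConfig()).token_pattern
    return sum(1 for _ in re.finditer(pattern, text))


def quotes_per_token(n_quotes: int, n_tokens: int) -> float:
    """Quotations per word token, the length-normalised exposure measure.

    Both zero returns 0.0; quotes without tokens is undefined.
    """
    if n_tokens < 0 or n_quotes < 0:
        raise ValueError("counts must be non-negative")
    if n_tokens == 0:
        if n_quotes == 0:
            return 0.0
        raise UndefinedRateError(f"{n_quotes} quotes in a text with no tokens")
    return n_quotes / n_tokens
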