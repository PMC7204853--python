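"""Brute-force character-by-character reference for quote extraction.

Written directly from the rule statements, independent of the package's
scanner, and used only as a test oracle on small inputs.  It walks the
text one character at a time keeping explicit state (outside / inside a
quote of a given style, with a nesting count for the curly styles) and
applies the apostrophe rules in the most literal way possible.
"""

from __future__ import annotations

import re

STYLES = {'"': '"', "“": "”", "'": "'", "‘": "’"}
SUFFIXES = ("all", "ve", "re", "ll", "c", "d", "e", "m", "n", "s", "t")
EMAIL = re.compile(r"[^@\s]+@[^@\s]+\.[^@\s]+")
URL = re.compile(r"(?:[A-Za-z][A-Za-z0-9+.-]*://\S+|www\.\S+)")


def _letter(text: str, i: int) -> bool:
    return 0 <= i < len(text) and text[i].isalpha()


def _apostrophe_like(text: str, i: int) -> bool:
    """A single quote that is really an apostrophe: letter on the left
    and either a letter on the right or a contraction suffix ending at a
    word boundary."""
    if not _letter(text, i - 1):
        return False
    if _letter(text, i + 1):
        return True
    rest = text[i + 1 :].lower()
    for suf in SUFFIXES:
        if rest.startswith(suf) and not _letter(rest, len(suf)):
            return True
    return False


def _opens(text: str, i: int) -> bool:
    ch = text[i]
    if ch not in STYLES:
        return False
    if ch in ("'",):
        # straight single: never opens when it looks like an apostrophe
        # or trails a word (possessive)
        return not _apostrophe_like(text, i) and not _letter(text, i - 1)
    if ch == "‘":
        return True
    return True  # '"' and '“'


def _closes(text: str, i: int, opener: str) -> bool:
    ch = text[i]
    if ch != STYLES[opener]:
        return False
    if ch in ("'", "’") and _apostrophe_like(text, i):
        return False
    return True


def reference_extract(text: str, max_quote_chars: int = 1500) -> list[tuple[int, int]]:
    """All maximal outer quoted spans as (start, end) offsets including
    the delimiters, per the same rule set as the package extractor."""
    spans: list[tuple[int, int]] = []
    i = 0
    while i < len(text):
        if _opens(text, i):
            opener = text[i]
            closer = STYLES[opener]
            depth = 0
            found = None
            j = i + 1
            while j < len(text) and (j - i - 1) <= max_quote_chars:
                if closer != opener and text[j] == opener:
                    depth += 1
                elif _closes(text, j, opener):
                    if depth > 0:
                        depth -= 1
                    else:
                        found = j
                        break
                j += 1
            if found is not None:
                content = text[i + 1 : found].strip()
                if found > i + 1 and not (EMAIL.fullmatch(content) or URL.fullmatch(content)):
                    spans.append((i, found + 1))
                i = found + 1
                continue
        i += 1
    return spans
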