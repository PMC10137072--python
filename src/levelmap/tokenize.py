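"""Word tokenization shared by vectorization and classification.

A word is a maximal run of word characters (letters, digits, underscore)
in the case-folded text.  Classification uses *distinct* words (set
semantics): a word repeated in a fragment contributes once.
"""

from __future__ import annotations

import re

_WORD_RE = re.compile(r"\w+")


def tokenize(text: str) -> list[str]:
    """All word tokens in order, case-folded, with multiplicity."""
    return _WORD_RE.findall(text.casefold())


def tokenize_distinct(text: str) -> frozenset[str]:
    """The set of distinct case-folded word tokens of ``text``."""
    return frozenset(_WORD_RE.findall(text.casefold()))
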