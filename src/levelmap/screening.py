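"""Dictionary-based screening of fragments into levels of study.

A fragment belongs to a category as soon as it contains at least one of
that category's method terms.  Terms match case-insensitively anywhere in
the text — a term may sit inside a longer word — except for a short list
of whole-word-only terms (e.g. "ria", "gag") that would otherwise fire
inside unrelated longer words.  Matched spans are recorded so fragments
can be rendered with the entity in square brackets and the method terms
in curly brackets for manual review.
"""

from __future__ import annotations

import csv
import importlib.resources
import logging
import re
from dataclasses import dataclass
from functools import lru_cache
from typing import IO, Iterable, Mapping, Sequence

from .categories import CATEGORIES, Category
from .evidence_io import EvidenceFragment

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DictionaryTerm:
    """One method term with its category and matching rule."""

    surface: str
    category: Category
    whole_word_only: bool = False
    source_group: str = ""

    def __post_init__(self) -> None:
        if not self.surface:
            raise ValueError("empty term surface")
        if self.surface != self.surface.casefold():
            object.__setattr__(self, "surface", self.surface.casefold())


class Dictionary:
    """A categorized set of method terms with compiled match patterns."""

    def __init__(self, terms: Iterable[DictionaryTerm]):
        self.terms: tuple[DictionaryTerm, ...] = tuple(terms)
        seen: set[tuple[str, Category]] = set()
        for term in self.terms:
            key = (term.surface, term.category)
            if key in seen:
                raise ValueError(f"duplicate term {key} in dictionary")
            seen.add(key)
        self._patterns = {
            term: _compile(term.surface, term.whole_word_only)
            for term in self.terms
        }

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)

    @property
    def term_count_by_category(self) -> dict[Category, int]:
        counts = {c: 0 for c in CATEGORIES}
        for term in self.terms:
            counts[term.category] += 1
        return counts

    def terms_for(self, category: Category) -> tuple[DictionaryTerm, ...]:
        return tuple(t for t in self.terms if t.category == category)

    def pattern(self, term: DictionaryTerm) -> re.Pattern:
        return self._patterns[term]

    def with_terms(self, extra: Iterable[DictionaryTerm]) -> "Dictionary":
        """A new dictionary with ``extra`` terms appended."""
        return Dictionary([*self.terms, *extra])


def _compile(surface: str, whole_word_only: bool) -> re.Pattern:
    escaped = re.escape(surface)
    if whole_word_only:
        # word boundary = transition between word chars and non-word/edge
        escaped = rf"(?<!\w){escaped}(?!\w)"
    return re.compile(escaped, re.IGNORECASE)


@dataclass(frozen=True)
class ScreenHit:
    """All matches of one category's terms within one fragment.

    ``matches`` holds (term surface, start, end) with 0-based half-open
    character offsets into the original fragment text.
    """

    fragment_id: str
    category: Category
    matches: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        if not self.matches:
            raise ValueError("a ScreenHit must contain at least one match")

    @property
    def matched_terms(self) -> frozenset[str]:
        return frozenset(surface for surface, _, _ in self.matches)


def load_dictionary(source: str | IO[str]) -> Dictionary:
    """Load a term dictionary from TSV.

    Required columns: ``term``, ``category``, ``whole_word_only``; an
    optional ``source_group`` column records the terminology grouping a
    term came from.  Duplicate (term, category) rows are collapsed with a
    warning; an unknown category label is fatal.
    """
    if isinstance(source, str):
        with open(source, encoding="utf-8") as fh:
            return load_dictionary(fh)
    reader = csv.DictReader(source, delimiter="\t")
    terms: dict[tuple[str, Category], DictionaryTerm] = {}
    for lineno, row in enumerate(reader, start=2):
        label = row["category"].strip()
        try:
            category = Category(label)
        except ValueError:
            raise ValueError(
                f"dictionary row {lineno}: unknown category {label!r}"
            ) from None
        term = DictionaryTerm(
            surface=row["term"].strip().casefold(),
            category=category,
            whole_word_only=row["whole_word_only"].strip().casefold()
            in ("true", "1", "yes"),
            source_group=(row.get("source_group") or "").strip(),
        )
        key = (term.surface, term.category)
        if key in terms:
            logger.warning("dictionary row %d: duplicate term %s collapsed", lineno, key)
            continue
        terms[key] = term
    return Dictionary(terms.values())


@lru_cache(maxsize=1)
def default_dictionary() -> Dictionary:
    """The packaged method-term dictionary (IUPAC-style category grouping)."""
    ref = importlib.resources.files("levelmap.data") / "method_terms.tsv"
    with ref.open(encoding="utf-8") as fh:
        return load_dictionary(fh)


def screen_fragment(
    fragment: EvidenceFragment, dictionary: Dictionary
) -> list[ScreenHit]:
    """Match every dictionary term against one fragment.

    Returns at most one :class:`ScreenHit` per category (0-3 hits), each
    carrying every matched span of every matched term of that category.
    """
    by_category: dict[Category, list[tuple[str, int, int]]] = {}
    for term in dictionary:
        for m in dictionary.pattern(term).finditer(fragment.text):
            by_category.setdefault(term.category, []).append(
                (term.surface, m.start(), m.end())
            )
    return [
        ScreenHit(
            fragment_id=fragment.fragment_id,
            category=category,
            matches=tuple(sorted(matches, key=lambda t: (t[1], t[2], t[0]))),
        )
        for category, matches in sorted(by_category.items(), key=lambda kv: kv[0].value)
    ]


@dataclass
class ScreenResult:
    """Corpus-level screening output: per-category membership plus spans."""

    ids_by_category: dict[Category, list[str]]
    hits_by_fragment: dict[str, list[ScreenHit]]

    @property
    def counts(self) -> dict[Category, int]:
        return {c: len(ids) for c, ids in self.ids_by_category.items()}

    def hits_for(self, fragment_id: str, category: Category) -> ScreenHit | None:
        for hit in self.hits_by_fragment.get(fragment_id, []):
            if hit.category == category:
                return hit
        return None


def screen_corpus(
    fragments: Sequence[EvidenceFragment], dictionary: Dictionary
) -> ScreenResult:
    """Screen a corpus; a fragment may belong to several categories."""
    result = ScreenResult(
        ids_by_category={c: [] for c in CATEGORIES}, hits_by_fragment={}
    )
    for fragment in fragments:
        hits = screen_fragment(fragment, dictionary)
        if hits:
            result.hits_by_fragment[fragment.fragment_id] = hits
        for hit in hits:
            result.ids_by_category[hit.category].append(fragment.fragment_id)
    return result


_MARKUP = {"entity": ("[", "]"), "term": ("{", "}")}


def highlight(
    fragment: EvidenceFragment,
    hits: Iterable[ScreenHit],
    target_name: str | None = None,
) -> str:
    """Render a fragment with the entity bracketed and terms braced.

    Occurrences of the target name are wrapped in square brackets and
    matched term spans in curly brackets, e.g. ``identified [Aurora B] as
    an acetylated {protein}``.  Overlapping spans are merged left-greedily:
    same-kind overlaps become one span, a span overlapping an earlier
    span of the other kind is dropped.  Stripping the four bracket
    characters recovers the original text (provided it contained none).
    """
    name = fragment.target_name if target_name is None else target_name
    spans: set[tuple[int, int, str]] = set()
    if name:
        for m in re.finditer(re.escape(name), fragment.text, re.IGNORECASE):
            spans.add((m.start(), m.end(), "entity"))
    for hit in hits:
        for _, start, end in hit.matches:
            spans.add((start, end, "term"))

    merged: list[tuple[int, int, str]] = []
    for start, end, kind in sorted(spans, key=lambda t: (t[0], -t[1])):
        if merged and start < merged[-1][1]:
            prev_start, prev_end, prev_kind = merged[-1]
            if kind == prev_kind:
                merged[-1] = (prev_start, max(prev_end, end), kind)
            continue  # cross-kind overlap: keep the earlier span
        merged.append((start, end, kind))

    out = fragment.text
    for start, end, kind in reversed(merged):
        open_b, close_b = _MARKUP[kind]
        out = out[:start] + open_b + out[start:end] + close_b + out[end:]
    return out


def strip_markup(text: str) -> str:
    """Remove the highlight bracket characters."""
    return text.translate(str.maketrans("", "", "[]{}"))


def write_hits(hits: Iterable[ScreenHit], stream: IO[str]) -> None:
    """Emit matched spans as TSV (fragment_id, category, term, start, end)."""
    stream.write("fragment_id\tcategory\tterm\tstart\tend\n")
    for hit in hits:
        for surface, start, end in hit.matches:
            stream.write(
                f"{hit.fragment_id}\t{hit.category}\t{surface}\t{start}\t{end}\n"
            )
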