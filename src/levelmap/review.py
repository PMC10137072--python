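"""Manual-review outcomes and term-answer association tables.

Each selected fragment is reviewed by answering three questions: (1) does
the fragment allow judging the category of the experimental method, (2)
are the highlighted terms sufficient to judge it, and (3) is the specific
level of study mentioned.  Question 3 decides whether the screened
category is validated; questions 1 and 2 characterize fragments and
terms.  The "answer" tabulated against individual terms is, by default,
the conjunction of questions 1 and 2 (both per-question tallies are also
derivable by passing a different ``answer`` mode).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import IO, Iterable, Literal, Mapping, Sequence

from .categories import Category
from .evidence_io import EvidenceFragment
from .screening import ScreenHit, highlight

REVIEW_QUESTIONS = (
    "Does the text fragment allow us to judge the category of the experimental method?",
    "Are highlighted terms sufficient to judge the category of experimental method?",
    "Is the specific level of the study mentioned in the text fragment?",
)

AnswerMode = Literal["conjunction", "q1", "q2"]


@dataclass(frozen=True)
class ReviewRecord:
    """Consensus three-question review outcome for one screened fragment."""

    fragment_id: str
    screened_category: Category
    q1_method_category_judgeable: bool
    q2_terms_sufficient: bool
    q3_level_mentioned: bool
    validated: bool

    def __post_init__(self) -> None:
        if self.validated and not self.q3_level_mentioned:
            raise ValueError(
                f"fragment {self.fragment_id!r}: validation requires the level "
                "of study to be mentioned (question 3)"
            )

    def answer(self, mode: AnswerMode = "conjunction") -> bool:
        if mode == "q1":
            return self.q1_method_category_judgeable
        if mode == "q2":
            return self.q2_terms_sufficient
        return self.q1_method_category_judgeable and self.q2_terms_sufficient


@dataclass(frozen=True)
class TermAssociation:
    """Counts of positive/negative review answers among fragments matching
    one term."""

    surface: str
    category: Category
    positive_count: int
    negative_count: int

    @property
    def total(self) -> int:
        return self.positive_count + self.negative_count

    @property
    def positive_prevalence(self) -> float:
        return self.positive_count / self.total

    @property
    def negative_prevalence(self) -> float:
        return self.negative_count / self.total


@dataclass(frozen=True)
class ReviewSummary:
    """Per-category validation outcome of the manual review."""

    category: Category
    validated_count: int
    invalidated_count: int

    @property
    def total(self) -> int:
        return self.validated_count + self.invalidated_count

    @property
    def validated_pct(self) -> float:
        return 100.0 * self.validated_count / self.total

    @property
    def false_positive_pct(self) -> float:
        return 100.0 * self.invalidated_count / self.total


def summarize_reviews(
    records: Iterable[ReviewRecord],
) -> dict[Category, ReviewSummary]:
    """Validated/invalidated counts and percentages per screened category.

    Categories with no reviewed fragments are absent from the result
    rather than reported with a zero denominator.
    """
    validated: dict[Category, int] = {}
    invalidated: dict[Category, int] = {}
    for record in records:
        bucket = validated if record.validated else invalidated
        bucket[record.screened_category] = bucket.get(record.screened_category, 0) + 1
    return {
        category: ReviewSummary(
            category=category,
            validated_count=validated.get(category, 0),
            invalidated_count=invalidated.get(category, 0),
        )
        for category in sorted(
            set(validated) | set(invalidated), key=lambda c: c.value
        )
    }


def term_associations(
    records: Sequence[ReviewRecord],
    hits_by_fragment: Mapping[str, Iterable[ScreenHit]],
    answer: AnswerMode = "conjunction",
) -> list[TermAssociation]:
    """Tabulate review answers against the terms matched in each fragment.

    For every term of a record's screened category that matched in the
    fragment, the record contributes one positive or one negative answer.
    Terms that never matched any reviewed fragment are absent.
    """
    positives: dict[tuple[str, Category], int] = {}
    negatives: dict[tuple[str, Category], int] = {}
    for record in records:
        hit = next(
            (
                h
                for h in hits_by_fragment.get(record.fragment_id, [])
                if h.category == record.screened_category
            ),
            None,
        )
        if hit is None:
            raise ValueError(
                f"reviewed fragment {record.fragment_id!r} has no screening hit "
                f"in category {record.screened_category}"
            )
        bucket = positives if record.answer(answer) else negatives
        for surface in hit.matched_terms:
            key = (surface, record.screened_category)
            bucket[key] = bucket.get(key, 0) + 1
    return [
        TermAssociation(
            surface=surface,
            category=category,
            positive_count=positives.get((surface, category), 0),
            negative_count=negatives.get((surface, category), 0),
        )
        for surface, category in sorted(
            set(positives) | set(negatives), key=lambda k: (k[1].value, k[0])
        )
    ]


def rank_terms(
    associations: Sequence[TermAssociation], n: int
) -> tuple[list[TermAssociation], list[TermAssociation]]:
    """Top-n terms by positive prevalence and by negative prevalence.

    Prevalence ties are broken by larger total count, then by term
    surface.  With fewer than 2n terms the two lists may overlap.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    by_positive = sorted(
        associations,
        key=lambda a: (-a.positive_prevalence, -a.total, a.surface),
    )
    by_negative = sorted(
        associations,
        key=lambda a: (-a.negative_prevalence, -a.total, a.surface),
    )
    return by_positive[:n], by_negative[:n]


# ---------------------------------------------------------------------------
# CSV / plain-text interchange

_FIELDS = (
    "fragment_id",
    "screened_category",
    "q1_method_category_judgeable",
    "q2_terms_sufficient",
    "q3_level_mentioned",
    "validated",
)


def write_reviews(records: Iterable[ReviewRecord], stream: IO[str]) -> None:
    """Write review records as CSV, one row per reviewed fragment."""
    writer = csv.writer(stream, lineterminator="\n")
    writer.writerow(_FIELDS)
    for r in records:
        writer.writerow(
            [
                r.fragment_id,
                r.screened_category.value,
                r.q1_method_category_judgeable,
                r.q2_terms_sufficient,
                r.q3_level_mentioned,
                r.validated,
            ]
        )


def read_reviews(stream: IO[str] | Iterable[str]) -> list[ReviewRecord]:
    """Read review records from CSV written by :func:`write_reviews`."""
    records = []
    for row in csv.DictReader(stream):
        records.append(
            ReviewRecord(
                fragment_id=row["fragment_id"],
                screened_category=Category(row["screened_category"]),
                q1_method_category_judgeable=row["q1_method_category_judgeable"] == "True",
                q2_terms_sufficient=row["q2_terms_sufficient"] == "True",
                q3_level_mentioned=row["q3_level_mentioned"] == "True",
                validated=row["validated"] == "True",
            )
        )
    return records


def write_associations(
    associations: Iterable[TermAssociation], stream: IO[str]
) -> None:
    """Write term-answer associations as TSV."""
    stream.write("term\tcategory\tpositive_count\tnegative_count\n")
    for a in associations:
        stream.write(
            f"{a.surface}\t{a.category}\t{a.positive_count}\t{a.negative_count}\n"
        )


def format_review_form(
    fragment: EvidenceFragment,
    hits: Iterable[ScreenHit],
    target_name: str | None = None,
) -> str:
    """Plain-text review form: highlighted fragment plus the three questions.

    This is the content an external labeling UI presents to a reviewer:
    the entity in square brackets, method terms in curly brackets.
    """
    lines = [f"Fragment {fragment.fragment_id}", "", highlight(fragment, hits, target_name), ""]
    for i, question in enumerate(REVIEW_QUESTIONS, start=1):
        lines.append(f"Q{i}. {question} [yes/no]")
    return "\n".join(lines) + "\n"
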