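"""Summary reports: raw, dictionary-size-adjusted and classified counts.

Raw per-category screening counts are not directly comparable because the
dictionary holds a different number of terms per category; the adjusted
count divides each raw count by its category's term count.  Reports are
rendered deterministically so identical inputs give byte-identical TSV
and text output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable, Mapping, Sequence

from .categories import Category
from .naive_bayes import ClassificationSummary
from .review import ReviewSummary
from .screening import Dictionary


@dataclass(frozen=True)
class CategoryReport:
    """Screening and classification tallies for one category."""

    category: Category
    raw_count: int
    term_count: int
    confirmed_count: int = 0
    unrelated_count: int = 0

    def __post_init__(self) -> None:
        if self.term_count <= 0:
            raise ValueError(f"{self.category}: term count must be positive")

    @property
    def adjusted_count(self) -> float:
        return self.raw_count / self.term_count


def adjust_counts(
    raw: Mapping[Category, int], dictionary: Dictionary
) -> dict[Category, float]:
    """Raw count divided by the number of dictionary terms per category."""
    term_counts = dictionary.term_count_by_category
    adjusted = {}
    for category, count in raw.items():
        terms = term_counts.get(category, 0)
        if terms <= 0:
            raise ValueError(f"{category}: dictionary has no terms")
        adjusted[category] = count / terms
    return adjusted


def build_reports(
    raw: Mapping[Category, int],
    dictionary: Dictionary,
    classification: Mapping[Category, ClassificationSummary] | None = None,
) -> list[CategoryReport]:
    """Assemble per-category reports in stable (category-name) order."""
    term_counts = dictionary.term_count_by_category
    reports = []
    for category in sorted(raw, key=lambda c: c.value):
        summary = (classification or {}).get(category)
        reports.append(
            CategoryReport(
                category=category,
                raw_count=raw[category],
                term_count=term_counts[category],
                confirmed_count=summary.confirmed_count if summary else 0,
                unrelated_count=summary.unrelated_count if summary else 0,
            )
        )
    return reports


_COLUMNS = (
    "category",
    "raw_count",
    "term_count",
    "adjusted_count",
    "confirmed_count",
    "unrelated_count",
)


def render_reports(
    reports: Sequence[CategoryReport],
    review_summaries: Mapping[Category, ReviewSummary] | None = None,
) -> tuple[str, str]:
    """Render reports as (TSV, plain-text summary).

    The TSV carries adjusted counts at full precision and round-trips
    through :func:`read_reports`; the text summary rounds to two
    decimals and appends manual-review percentages when provided.
    """
    rows = ["\t".join(_COLUMNS)]
    for r in sorted(reports, key=lambda r: r.category.value):
        rows.append(
            f"{r.category}\t{r.raw_count}\t{r.term_count}\t"
            f"{r.adjusted_count!r}\t{r.confirmed_count}\t{r.unrelated_count}"
        )
    tsv = "\n".join(rows) + "\n"

    lines = ["Screening summary", "-----------------"]
    for r in sorted(reports, key=lambda r: r.category.value):
        lines.append(
            f"{r.category}: {r.raw_count} fragments "
            f"({r.adjusted_count:.2f} per dictionary term; {r.term_count} terms)"
        )
        if r.confirmed_count or r.unrelated_count:
            total = r.confirmed_count + r.unrelated_count
            lines.append(
                f"  automated review: {r.confirmed_count}/{total} confirmed, "
                f"{r.unrelated_count}/{total} "
                f"({100.0 * r.unrelated_count / total:.1f}%) unrelated"
            )
    if review_summaries:
        lines += ["", "Manual review", "-------------"]
        for category in sorted(review_summaries, key=lambda c: c.value):
            s = review_summaries[category]
            lines.append(
                f"{category}: {s.validated_count}/{s.total} validated "
                f"({s.validated_pct:.1f}%), {s.invalidated_count}/{s.total} "
                f"false positives ({s.false_positive_pct:.1f}%)"
            )
    return tsv, "\n".join(lines) + "\n"


def read_reports(tsv: str | IO[str] | Iterable[str]) -> list[CategoryReport]:
    """Parse the TSV produced by :func:`render_reports`."""
    if not isinstance(tsv, str):
        tsv = "".join(tsv)
    lines = [line for line in tsv.splitlines() if line.strip()]
    header = tuple(lines[0].split("\t"))
    if header != _COLUMNS:
        raise ValueError(f"unexpected report header {header!r}")
    reports = []
    for line in lines[1:]:
        category, raw, terms, _adjusted, confirmed, unrelated = line.split("\t")
        reports.append(
            CategoryReport(
                category=Category(category),
                raw_count=int(raw),
                term_count=int(terms),
                confirmed_count=int(confirmed),
                unrelated_count=int(unrelated),
            )
        )
    return reports
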