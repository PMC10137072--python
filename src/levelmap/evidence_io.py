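"""Reading, deduplication and annotation-based filtering of evidence fragments.

Literature evidence arrives as JSON Lines, one object per line, shaped like
Open Targets europepmc literature evidence (key names are configurable).
Each record ties a target gene to a disease through a sentence from a
publication.  Protein annotation records in the style of the neXtProt
knowledge base carry quality grades and evidence descriptors; only
fragments whose (Ensembl gene id, PubMed id) pair is backed by a
high-quality publication-supported annotation are retained for screening.
"""

from __future__ import annotations

import csv
import json
import logging
from collections import Counter
from dataclasses import dataclass, field, fields
from typing import IO, Iterable, Iterator, Mapping, Sequence

logger = logging.getLogger(__name__)

#: Default JSONL key names (Open Targets v21.04 europepmc evidence shape).
DEFAULT_EVIDENCE_KEYS: Mapping[str, str] = {
    "fragment_id": "id",
    "target_ensembl_id": "targetId",
    "target_name": "targetFromSource",
    "disease_id": "diseaseId",
    "pmid": "pmid",
    "text": "text",
}


@dataclass(frozen=True)
class EvidenceFragment:
    """One literature sentence linking a therapeutic target and a disease."""

    fragment_id: str
    target_ensembl_id: str
    target_name: str
    disease_id: str
    pmid: str
    text: str

    def __post_init__(self) -> None:
        if not self.text.strip():
            raise ValueError(f"fragment {self.fragment_id!r}: empty text")


@dataclass(frozen=True)
class AnnotationRecord:
    """One protein-annotation evidence record with quality metadata."""

    protein_accession: str
    ensembl_gene_ids: frozenset[str]
    protein_existence_level: str  # "protein_level" or "other"
    annotation_group: str  # hierarchy path, e.g. "general-annotation; medical"
    annotation_category: str
    annotation_quality: str  # GOLD / SILVER / BRONZE
    has_negative_evidence: bool
    evidence_quality: str  # GOLD / SILVER / BRONZE
    evidence_type: str
    eco_terms: frozenset[str]
    pmid: str | None = None

    _QUALITIES = frozenset({"GOLD", "SILVER", "BRONZE"})

    def __post_init__(self) -> None:
        for attr in ("annotation_quality", "evidence_quality"):
            if getattr(self, attr) not in self._QUALITIES:
                raise ValueError(
                    f"{self.protein_accession}: {attr} must be one of "
                    f"{sorted(self._QUALITIES)}, got {getattr(self, attr)!r}"
                )


@dataclass(frozen=True)
class FilterCriteria:
    """The record-selection criteria for high-confidence annotation evidence.

    Defaults encode the nine criteria used to pick candidate fragments:
    protein-level existence, an allowed annotation-hierarchy group, GOLD
    annotation quality, no forbidden annotation category, no negative
    evidence, GOLD evidence quality, publication-type evidence with a
    PubMed id, an allowed evidence descriptor, and a one-to-one
    Ensembl-gene mapping.
    """

    allowed_groups: frozenset[str] = frozenset(
        {
            "general-annotation; generic-function",
            "general-annotation",
            "general-annotation; generic-interaction",
            "general-annotation; medical",
        }
    )
    forbidden_categories: frozenset[str] = frozenset(
        {"caution", "domain-info", "sequence-caution", "variant-info"}
    )
    allowed_eco_terms: frozenset[str] = frozenset(
        {
            "physical interaction evidence used in manual assertion",
            "experimental evidence used in manual assertion",
            "direct assay evidence used in manual assertion",
            "experimental evidence",
        }
    )
    required_annotation_quality: str = "GOLD"
    required_evidence_quality: str = "GOLD"
    required_evidence_type: str = "publication"


#: Criterion labels used for exclusion attribution, in evaluation order.
CRITERIA: tuple[str, ...] = (
    "protein_level_existence",
    "annotation_group",
    "annotation_quality",
    "annotation_category",
    "negative_evidence",
    "evidence_quality",
    "publication_with_pmid",
    "eco_term",
    "ensembl_one_to_one",
)


@dataclass
class ReadResult:
    """Fragments parsed from a JSONL stream plus skipped-line bookkeeping."""

    fragments: list[EvidenceFragment]
    skipped: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_skipped(self) -> int:
        return len(self.skipped)


def read_evidence(
    stream: IO[str] | Iterable[str],
    keys: Mapping[str, str] | None = None,
) -> ReadResult:
    """Parse evidence fragments from a JSON Lines stream.

    Each line must be a standalone JSON object carrying the six payload
    fields under the (configurable) ``keys`` names.  Malformed lines —
    broken JSON, missing keys, empty text, non-positive PubMed ids — are
    skipped with a warning; input order is preserved for valid lines.
    """
    key_map = dict(DEFAULT_EVIDENCE_KEYS)
    if keys:
        key_map.update(keys)
    result = ReadResult(fragments=[])
    for lineno, line in enumerate(stream, start=1):
        if not line.strip():
            continue
        try:
            obj = json.loads(line)
            if not isinstance(obj, dict):
                raise ValueError("line is not a JSON object")
            payload = {}
            for attr, key in key_map.items():
                if key not in obj:
                    raise KeyError(f"missing key {key!r}")
                payload[attr] = str(obj[key])
            if not payload["pmid"].isdigit() or int(payload["pmid"]) <= 0:
                raise ValueError(f"invalid pmid {payload['pmid']!r}")
            result.fragments.append(EvidenceFragment(**payload))
        except (json.JSONDecodeError, KeyError, ValueError) as exc:
            logger.warning("skipping evidence line %d: %s", lineno, exc)
            result.skipped.append((lineno, str(exc)))
    return result


def _duplicate_key(fragment: EvidenceFragment) -> tuple[str, str, str]:
    normalized = " ".join(fragment.text.casefold().split())
    return (normalized, fragment.target_ensembl_id, fragment.disease_id)


def deduplicate(
    fragments: Sequence[EvidenceFragment],
) -> list[EvidenceFragment]:
    """Drop repeated records, keeping the first occurrence of each.

    Two records are duplicates when they agree on the case-folded,
    whitespace-collapsed text, the target gene and the disease; the same
    sentence attached to a different target-disease claim is kept.
    """
    seen: set[tuple[str, str, str]] = set()
    kept = []
    for fragment in fragments:
        key = _duplicate_key(fragment)
        if key not in seen:
            seen.add(key)
            kept.append(fragment)
    return kept


def failed_criteria(
    record: AnnotationRecord, criteria: FilterCriteria
) -> tuple[str, ...]:
    """Labels of every selection criterion ``record`` violates."""
    failures = []
    if record.protein_existence_level != "protein_level":
        failures.append("protein_level_existence")
    if record.annotation_group not in criteria.allowed_groups:
        failures.append("annotation_group")
    if record.annotation_quality != criteria.required_annotation_quality:
        failures.append("annotation_quality")
    if record.annotation_category in criteria.forbidden_categories:
        failures.append("annotation_category")
    if record.has_negative_evidence:
        failures.append("negative_evidence")
    if record.evidence_quality != criteria.required_evidence_quality:
        failures.append("evidence_quality")
    if record.evidence_type != criteria.required_evidence_type or not record.pmid:
        failures.append("publication_with_pmid")
    if not (record.eco_terms & criteria.allowed_eco_terms):
        failures.append("eco_term")
    if len(record.ensembl_gene_ids) != 1:
        failures.append("ensembl_one_to_one")
    return tuple(failures)


@dataclass
class FilterResult:
    """Accepted (gene, pmid) pairs and per-criterion exclusion tallies."""

    pairs: set[tuple[str, str]]
    n_records: int
    n_passed: int
    exclusions: Counter

    @property
    def n_excluded(self) -> int:
        return self.n_records - self.n_passed


def filter_annotations(
    records: Iterable[AnnotationRecord],
    criteria: FilterCriteria | None = None,
) -> FilterResult:
    """Select (Ensembl gene id, PubMed id) pairs backed by records passing
    every criterion.

    A record contributes its pair only when all nine criteria hold; an
    excluded record is tallied under every criterion it violates.
    """
    criteria = criteria or FilterCriteria()
    result = FilterResult(pairs=set(), n_records=0, n_passed=0, exclusions=Counter())
    for record in records:
        result.n_records += 1
        failures = failed_criteria(record, criteria)
        if failures:
            result.exclusions.update(failures)
            continue
        result.n_passed += 1
        (gene_id,) = record.ensembl_gene_ids
        result.pairs.add((gene_id, record.pmid))
    for criterion, count in sorted(result.exclusions.items()):
        logger.info("filter_annotations: %d record(s) excluded by %s", count, criterion)
    return result


def join_candidates(
    fragments: Sequence[EvidenceFragment],
    accepted_pairs: set[tuple[str, str]],
) -> list[EvidenceFragment]:
    """Keep fragments whose (target gene, PubMed id) pair was accepted."""
    return [
        f for f in fragments if (f.target_ensembl_id, f.pmid) in accepted_pairs
    ]


# ---------------------------------------------------------------------------
# Streaming readers/writers for the tabular interchange formats.

_BOOL = {"true": True, "false": False, "1": True, "0": False}


def read_annotations_jsonl(
    stream: IO[str] | Iterable[str],
) -> Iterator[AnnotationRecord]:
    """Stream annotation records from JSON Lines (one object per line)."""
    for lineno, line in enumerate(stream, start=1):
        if not line.strip():
            continue
        obj = json.loads(line)
        yield _annotation_from_mapping(obj, where=f"line {lineno}")


def read_annotations_tsv(
    stream: IO[str] | Iterable[str],
) -> Iterator[AnnotationRecord]:
    """Stream annotation records from TSV; set-valued columns use ``|``."""
    reader = csv.DictReader(stream, delimiter="\t")
    for lineno, row in enumerate(reader, start=2):
        row = dict(row)
        row["ensembl_gene_ids"] = [
            g for g in (row.get("ensembl_gene_ids") or "").split("|") if g
        ]
        row["eco_terms"] = [
            t for t in (row.get("eco_terms") or "").split("|") if t
        ]
        row["has_negative_evidence"] = _BOOL[
            str(row["has_negative_evidence"]).strip().casefold()
        ]
        if not row.get("pmid"):
            row["pmid"] = None
        yield _annotation_from_mapping(row, where=f"line {lineno}")


def _annotation_from_mapping(obj: Mapping, where: str) -> AnnotationRecord:
    try:
        return AnnotationRecord(
            protein_accession=str(obj["protein_accession"]),
            ensembl_gene_ids=frozenset(obj["ensembl_gene_ids"]),
            protein_existence_level=str(obj["protein_existence_level"]),
            annotation_group=str(obj["annotation_group"]),
            annotation_category=str(obj["annotation_category"]),
            annotation_quality=str(obj["annotation_quality"]),
            has_negative_evidence=bool(obj["has_negative_evidence"]),
            evidence_quality=str(obj["evidence_quality"]),
            evidence_type=str(obj["evidence_type"]),
            eco_terms=frozenset(obj["eco_terms"]),
            pmid=None if obj.get("pmid") is None else str(obj["pmid"]),
        )
    except KeyError as exc:
        raise ValueError(f"annotation record at {where}: missing {exc}") from exc


def write_pairs(pairs: Iterable[tuple[str, str]], stream: IO[str]) -> None:
    """Write accepted (gene, pmid) pairs as a sorted two-column TSV."""
    stream.write("ensembl_gene_id\tpmid\n")
    for gene, pmid in sorted(pairs):
        stream.write(f"{gene}\t{pmid}\n")


def read_pairs(stream: IO[str] | Iterable[str]) -> set[tuple[str, str]]:
    """Read a two-column (gene, pmid) TSV written by :func:`write_pairs`."""
    it = iter(stream)
    next(it, None)  # header
    pairs = set()
    for line in it:
        if line.strip():
            gene, pmid = line.rstrip("\n").split("\t")
            pairs.add((gene, pmid))
    return pairs
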