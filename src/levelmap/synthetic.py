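"""Synthetic corpora with known ground truth for every pipeline stage.

The generator emulates the structural properties of literature-evidence
corpora that the pipeline must handle — dictionary terms embedded in
background text, short homograph terms hidden inside longer words,
exact-duplicate records, and screening false positives (a method term
used in a non-method sense) — without attempting linguistically
realistic sentences.

Class separability is controlled exactly: a *valid* fragment carries,
with probability ``context_clarity``, tokens from a positive-context
vocabulary block and an *invalid* fragment likewise from a disjoint
negative-context block; fragments without context tokens are
uninformative.  Because context tokens are class-pure, the Bayes-optimal
balanced accuracy has the closed form (1 + context_clarity) / 2
regardless of the planted false-positive rate: the optimal rule is right
on every context-bearing fragment and cannot beat majority guessing on
the rest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import yaml

from .categories import CATEGORIES, Category
from .evidence_io import DEFAULT_EVIDENCE_KEYS, EvidenceFragment
from .review import ReviewRecord
from .screening import Dictionary, default_dictionary
from .tokenize import tokenize_distinct

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the corpus generator.

    ``duplicate_rate`` is the fraction of the emitted corpus that is
    duplicate records (so deduplication retains ``1 - duplicate_rate`` of
    it), ``false_positive_rate`` the probability that a term-bearing
    fragment is planted as invalid, and ``context_clarity`` the
    probability that a fragment carries class-pure context tokens; the
    latter fixes the Bayes-optimal balanced accuracy at
    ``(1 + context_clarity) / 2``.
    """

    seed: int = 0
    n_per_category: int = 500
    background_vocab_size: int = 500
    term_injection_rate: float = 1.0
    homograph_rate: float = 0.05
    false_positive_rate: float = 0.4
    duplicate_rate: float = 0.17
    fragment_length: tuple[int, int] = (8, 30)
    context_clarity: float = 0.44
    context_block_size: int = 20
    context_tokens_per_fragment: int = 3

    def __post_init__(self) -> None:
        for name in (
            "term_injection_rate",
            "homograph_rate",
            "false_positive_rate",
            "duplicate_rate",
            "context_clarity",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        lo, hi = self.fragment_length
        if lo > hi or lo < 1:
            raise ValueError(f"invalid fragment_length {self.fragment_length}")
        if self.duplicate_rate >= 1.0:
            raise ValueError("duplicate_rate must be < 1")
        if self.background_vocab_size < hi:
            raise ValueError(
                "degenerate config: background vocabulary smaller than the "
                "maximum fragment length"
            )

    @property
    def bayes_optimal_balanced_accuracy(self) -> float:
        """Closed-form optimum achievable by any classifier on this corpus."""
        return (1.0 + self.context_clarity) / 2.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fragment_length"] = list(self.fragment_length)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticConfig":
        d = dict(d)
        if "fragment_length" in d:
            d["fragment_length"] = tuple(d["fragment_length"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, source: str | IO[str]) -> "SyntheticConfig":
        """Load a config from a YAML/TOML-style key-value file."""
        if isinstance(source, str):
            with open(source, encoding="utf-8") as fh:
                return cls.from_dict(yaml.safe_load(fh) or {})
        return cls.from_dict(yaml.safe_load(source) or {})

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass(frozen=True)
class TruthEntry:
    category: Category | None
    planted_valid: bool
    is_duplicate: bool


@dataclass
class TruthTable:
    """Ground truth for every emitted fragment id."""

    entries: dict[str, TruthEntry] = field(default_factory=dict)

    def __getitem__(self, fragment_id: str) -> TruthEntry:
        return self.entries[fragment_id]

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, fragment_id: str) -> bool:
        return fragment_id in self.entries


def _context_token(kind: str, category_index: int, j: int) -> str:
    # letter+digit tokens cannot contain any dictionary term as a substring
    return f"{kind}{category_index}ctx{j:02d}"


def generate_corpus(
    cfg: SyntheticConfig, dictionary: Dictionary | None = None
) -> tuple[list[EvidenceFragment], TruthTable]:
    """Generate an evidence corpus with a complete truth table.

    Per category, ``cfg.n_per_category`` base fragments of background
    tokens are drawn; with probability ``term_injection_rate`` a fragment
    receives one of the category's ordinary (substring-matching)
    dictionary terms and its true category, otherwise it stays
    category-free.  Validity, context tokens, homograph traps and
    duplicate records are planted per the config.  Reproducible: the same
    config (including seed) yields a byte-identical corpus.
    """
    dictionary = dictionary or default_dictionary()
    rng = np.random.default_rng(cfg.seed)
    logger.info(
        "generate_corpus: seed=%d config_hash=%s", cfg.seed, cfg.config_hash
    )

    background = [f"w{j:04d}" for j in range(cfg.background_vocab_size)]
    whole_word_terms = [t for t in dictionary if t.whole_word_only]
    plain_terms = {
        category: [
            t for t in dictionary.terms_for(category) if not t.whole_word_only
        ]
        for category in CATEGORIES
    }
    for category, terms in plain_terms.items():
        if not terms:
            raise ValueError(f"dictionary has no substring terms for {category}")

    fragments: list[EvidenceFragment] = []
    truth = TruthTable()
    idx = 0
    for cat_index, category in enumerate(CATEGORIES):
        for _ in range(cfg.n_per_category):
            lo, hi = cfg.fragment_length
            length = int(rng.integers(lo, hi + 1))
            words = list(rng.choice(background, size=length, replace=False))

            injected = rng.random() < cfg.term_injection_rate
            valid = True
            if injected:
                term = plain_terms[category][
                    int(rng.integers(len(plain_terms[category])))
                ]
                valid = not (rng.random() < cfg.false_positive_rate)
                if rng.random() < cfg.context_clarity:
                    block = "p" if valid else "n"
                    picks = rng.choice(
                        cfg.context_block_size,
                        size=min(cfg.context_tokens_per_fragment, cfg.context_block_size),
                        replace=False,
                    )
                    for j in picks:
                        words.insert(
                            int(rng.integers(len(words) + 1)),
                            _context_token(block, cat_index, int(j)),
                        )
            if whole_word_terms and rng.random() < cfg.homograph_rate:
                trap = whole_word_terms[int(rng.integers(len(whole_word_terms)))]
                words.insert(
                    int(rng.integers(len(words) + 1)), f"x{trap.surface}x"
                )
            if injected:
                # inserted last so nothing can split a multi-word phrase
                pos = int(rng.integers(len(words) + 1))
                words[pos:pos] = term.surface.split()

            fragment = EvidenceFragment(
                fragment_id=f"frag{idx:06d}",
                target_ensembl_id=f"ENSG{idx:011d}",
                target_name=f"GENE{idx}",
                disease_id=f"EFO_{idx % 7:07d}",
                pmid=str(20_000_000 + idx),
                text=" ".join(words),
            )
            fragments.append(fragment)
            truth.entries[fragment.fragment_id] = TruthEntry(
                category=category if injected else None,
                planted_valid=valid,
                is_duplicate=False,
            )
            idx += 1

    n_base = len(fragments)
    n_dup = int(round(n_base * cfg.duplicate_rate / (1.0 - cfg.duplicate_rate)))
    duplicates = []
    if n_dup:
        originals = rng.integers(0, n_base, size=n_dup)
        for j, orig_idx in enumerate(originals):
            orig = fragments[int(orig_idx)]
            dup = EvidenceFragment(
                fragment_id=f"{orig.fragment_id}dup{j}",
                target_ensembl_id=orig.target_ensembl_id,
                target_name=orig.target_name,
                disease_id=orig.disease_id,
                pmid=orig.pmid,
                text=orig.text,
            )
            duplicates.append(dup)
            base = truth.entries[orig.fragment_id]
            truth.entries[dup.fragment_id] = TruthEntry(
                category=base.category,
                planted_valid=base.planted_valid,
                is_duplicate=True,
            )
    emitted = fragments + duplicates
    order = rng.permutation(len(emitted))
    return [emitted[i] for i in order], truth


def simulate_reviews(
    fragment_ids: Iterable[str], truth: TruthTable
) -> list[ReviewRecord]:
    """Consensus review outcomes implied by the planted validity labels.

    A planted-valid fragment answers yes to all three questions; a
    planted-invalid one answers no (the term was used in a non-method
    sense, so neither the fragment nor the highlighted terms support the
    category).  Fragments without a true category are skipped.
    """
    records = []
    for fid in fragment_ids:
        entry = truth[fid]
        if entry.category is None:
            continue
        records.append(
            ReviewRecord(
                fragment_id=fid,
                screened_category=entry.category,
                q1_method_category_judgeable=entry.planted_valid,
                q2_terms_sufficient=entry.planted_valid,
                q3_level_mentioned=entry.planted_valid,
                validated=entry.planted_valid,
            )
        )
    return records


def labeled_from_truth(
    fragments: Sequence[EvidenceFragment],
    truth: TruthTable,
    category: Category,
) -> list[tuple[str, frozenset[str], bool]]:
    """(fragment_id, token set, planted validity) for one category's pool."""
    return [
        (f.fragment_id, tokenize_distinct(f.text), truth[f.fragment_id].planted_valid)
        for f in fragments
        if truth[f.fragment_id].category == category
    ]


# ---------------------------------------------------------------------------
# Annotation fixture

from .evidence_io import AnnotationRecord, CRITERIA  # noqa: E402


@dataclass
class AnnotationFixture:
    """Annotation records plus the criterion each violator breaks."""

    records: list[AnnotationRecord]
    violations: dict[str, str]  # protein_accession -> violated criterion


def _passing_record(
    accession: str, gene: str, pmid: str | None, **overrides
) -> AnnotationRecord:
    payload = dict(
        protein_accession=accession,
        ensembl_gene_ids=frozenset({gene}),
        protein_existence_level="protein_level",
        annotation_group="general-annotation; generic-function",
        annotation_category="function",
        annotation_quality="GOLD",
        has_negative_evidence=False,
        evidence_quality="GOLD",
        evidence_type="publication",
        eco_terms=frozenset({"experimental evidence used in manual assertion"}),
        pmid=pmid,
    )
    payload.update(overrides)
    return AnnotationRecord(**payload)


def generate_annotation_fixture(
    cfg: SyntheticConfig,
    pairs: Iterable[tuple[str, str]] | None = None,
) -> AnnotationFixture:
    """Records exercising each selection criterion exactly once.

    Emits one passing record per (gene, pmid) pair — taken from a corpus
    generated with ``cfg`` when ``pairs`` is not given — plus, for each
    of the nine criteria, exactly one record violating only that
    criterion.
    """
    if pairs is None:
        fragments, _ = generate_corpus(cfg)
        pairs = sorted({(f.target_ensembl_id, f.pmid) for f in fragments})
    records = [
        _passing_record(f"NX_PASS{i:05d}", gene, pmid)
        for i, (gene, pmid) in enumerate(sorted(set(pairs)))
    ]

    gene, pmid = "ENSG99999999999", "99999999"
    single_violation_overrides: dict[str, dict] = {
        "protein_level_existence": {"protein_existence_level": "other"},
        "annotation_group": {"annotation_group": "sequence; topology"},
        "annotation_quality": {"annotation_quality": "SILVER"},
        "annotation_category": {"annotation_category": "caution"},
        "negative_evidence": {"has_negative_evidence": True},
        "evidence_quality": {"evidence_quality": "SILVER"},
        "publication_with_pmid": {"pmid": None},
        "eco_term": {"eco_terms": frozenset({"sequence similarity evidence"})},
        "ensembl_one_to_one": {
            "ensembl_gene_ids": frozenset({gene, "ENSG88888888888"})
        },
    }
    assert set(single_violation_overrides) == set(CRITERIA)
    violations = {}
    for criterion in CRITERIA:
        accession = f"NX_VIOL_{criterion}"
        records.append(
            _passing_record(
                accession, gene, **{"pmid": pmid, **single_violation_overrides[criterion]}
            )
        )
        violations[accession] = criterion
    return AnnotationFixture(records=records, violations=violations)


def write_corpus_jsonl(
    fragments: Iterable[EvidenceFragment],
    stream: IO[str],
    keys: Mapping[str, str] | None = None,
) -> None:
    """Emit fragments in the JSONL dialect :func:`read_evidence` consumes."""
    key_map = dict(DEFAULT_EVIDENCE_KEYS)
    if keys:
        key_map.update(keys)
    for f in fragments:
        obj = {key_map[attr]: getattr(f, attr) for attr in key_map}
        stream.write(json.dumps(obj, sort_keys=True) + "\n")
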