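"""Per-category Bernoulli naive Bayes review of screened fragments.

One binary classifier per level-of-study category is trained on the
manual-review labels: fragments whose category membership was validated
are positive examples, the other reviewed fragments of the same screened
pool are negative.  Fragments are tokenized by distinct words (presence/
absence), which motivates the Bernoulli event model; a multinomial
variant over token counts is available behind the ``event_model``
switch.  Model quality is assessed by stratified 5-fold cross-validated
balanced accuracy, and the fitted models then classify every fragment
that passed dictionary screening as confirmed or unrelated.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .categories import Category
from .tokenize import tokenize_distinct  # re-exported: part of this module's surface

__all__ = [
    "tokenize_distinct",
    "NBModel",
    "fit",
    "predict",
    "cross_validate",
    "classify_corpus",
    "balanced_accuracy",
    "CVReport",
    "FoldMetrics",
    "ClassificationSummary",
    "model_to_json",
    "model_from_json",
    "write_predictions",
]


@dataclass
class NBModel:
    """Binary naive Bayes model for one category.

    ``p_pos``/``p_neg`` hold the smoothed conditional probabilities
    P(token present | class) for the positive (validated) and negative
    class; priors are the training class frequencies.  For the
    multinomial event model the dictionaries hold P(token | class) over
    the vocabulary instead.
    """

    category: Category | None
    prior_positive: float
    alpha: float
    p_pos: dict[str, float]
    p_neg: dict[str, float]
    event_model: str = "bernoulli"
    _cache: tuple | None = field(default=None, repr=False, compare=False)

    @property
    def vocabulary(self) -> frozenset[str]:
        return frozenset(self.p_pos)

    def _scores(self) -> tuple:
        """Precomputed log terms: (base_pos, base_neg, delta dicts)."""
        if self._cache is None:
            if self.event_model == "bernoulli":
                base_pos = sum(math.log1p(-p) for p in self.p_pos.values())
                base_neg = sum(math.log1p(-p) for p in self.p_neg.values())
                delta_pos = {
                    t: math.log(p) - math.log1p(-p) for t, p in self.p_pos.items()
                }
                delta_neg = {
                    t: math.log(p) - math.log1p(-p) for t, p in self.p_neg.items()
                }
            else:
                base_pos = base_neg = 0.0
                delta_pos = {t: math.log(p) for t, p in self.p_pos.items()}
                delta_neg = {t: math.log(p) for t, p in self.p_neg.items()}
            self._cache = (base_pos, base_neg, delta_pos, delta_neg)
        return self._cache


def fit(
    labeled: Sequence[tuple[Iterable[str] | Mapping[str, int], bool]],
    alpha: float = 1.0,
    category: Category | None = None,
    event_model: str = "bernoulli",
) -> NBModel:
    """Fit a smoothed naive Bayes model on (token set, label) pairs.

    Bernoulli conditionals: P(t | c) = (docs of class c containing t +
    alpha) / (docs of class c + 2*alpha); priors are class frequencies.
    Multinomial conditionals divide smoothed token counts by the class
    token total.  Both classes must be present.
    """
    if alpha <= 0:
        raise ValueError("smoothing constant alpha must be positive")
    if event_model not in ("bernoulli", "multinomial"):
        raise ValueError(f"unknown event model {event_model!r}")
    n_pos = sum(1 for _, label in labeled if label)
    n_neg = len(labeled) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("training data must contain both classes")

    vocabulary: set[str] = set()
    for tokens, _ in labeled:
        vocabulary.update(tokens)

    counts = {True: {t: 0.0 for t in vocabulary}, False: {t: 0.0 for t in vocabulary}}
    for tokens, label in labeled:
        if event_model == "bernoulli":
            for t in set(tokens):
                counts[label][t] += 1
        else:
            items = tokens.items() if isinstance(tokens, Mapping) else (
                (t, 1) for t in tokens
            )
            for t, c in items:
                counts[label][t] += c

    if event_model == "bernoulli":
        denom = {True: n_pos + 2 * alpha, False: n_neg + 2 * alpha}
    else:
        denom = {
            label: sum(counts[label].values()) + alpha * len(vocabulary)
            for label in (True, False)
        }
    p_pos = {t: (counts[True][t] + alpha) / denom[True] for t in sorted(vocabulary)}
    p_neg = {t: (counts[False][t] + alpha) / denom[False] for t in sorted(vocabulary)}
    return NBModel(
        category=category,
        prior_positive=n_pos / len(labeled),
        alpha=alpha,
        p_pos=p_pos,
        p_neg=p_neg,
        event_model=event_model,
    )


def predict(model: NBModel, tokens: Iterable[str]) -> tuple[bool, float]:
    """Label a token set; returns (label, posterior of the positive class).

    The full Bernoulli likelihood over the model vocabulary is used:
    absent vocabulary tokens contribute 1 - P(t|c), tokens outside the
    vocabulary are ignored.  The label is positive iff the posterior
    exceeds 0.5; an exact tie goes to the negative ("unrelated") class.
    """
    base_pos, base_neg, delta_pos, delta_neg = model._scores()
    log_pos = math.log(model.prior_positive) + base_pos
    log_neg = math.log(1.0 - model.prior_positive) + base_neg
    present = set(tokens) & model.vocabulary
    for t in present:
        log_pos += delta_pos[t]
        log_neg += delta_neg[t]
    # posterior = 1 / (1 + exp(log_neg - log_pos))
    diff = log_neg - log_pos
    if diff > 700:
        posterior = 0.0
    elif diff < -700:
        posterior = 1.0
    else:
        posterior = 1.0 / (1.0 + math.exp(diff))
    return posterior > 0.5, posterior


def balanced_accuracy(
    y_true: Sequence[bool], y_pred: Sequence[bool]
) -> float:
    """(sensitivity + specificity) / 2; both classes must occur in y_true."""
    y_true = np.asarray(y_true, dtype=bool)
    y_pred = np.asarray(y_pred, dtype=bool)
    pos = y_true.sum()
    neg = (~y_true).sum()
    if pos == 0 or neg == 0:
        raise ValueError("balanced accuracy needs both classes in y_true")
    sensitivity = (y_pred & y_true).sum() / pos
    specificity = (~y_pred & ~y_true).sum() / neg
    return float((sensitivity + specificity) / 2.0)


@dataclass(frozen=True)
class FoldMetrics:
    fold: int
    sensitivity: float
    specificity: float

    @property
    def balanced_accuracy(self) -> float:
        return (self.sensitivity + self.specificity) / 2.0


@dataclass
class CVReport:
    """Stratified k-fold cross-validation outcome for one category."""

    category: Category | None
    fold_assignments: dict[str, int]  # fragment_id -> fold (1-based)
    folds: list[FoldMetrics]

    @property
    def mean_balanced_accuracy(self) -> float:
        return float(np.mean([f.balanced_accuracy for f in self.folds]))

    def to_json(self) -> str:
        return json.dumps(
            {
                "category": None if self.category is None else self.category.value,
                "fold_assignments": self.fold_assignments,
                "folds": [
                    {
                        "fold": f.fold,
                        "sensitivity": f.sensitivity,
                        "specificity": f.specificity,
                        "balanced_accuracy": f.balanced_accuracy,
                    }
                    for f in self.folds
                ],
                "mean_balanced_accuracy": self.mean_balanced_accuracy,
            },
            indent=2,
            sort_keys=True,
        )


def cross_validate(
    labeled: Sequence[tuple[str, Iterable[str], bool]],
    folds: int = 5,
    seed: int = 0,
    alpha: float = 1.0,
    category: Category | None = None,
    event_model: str = "bernoulli",
) -> CVReport:
    """Stratified k-fold CV of the naive Bayes model.

    ``labeled`` holds (fragment_id, token set, label) triples.  Folds come
    from a seeded stratified shuffle, so the class ratio per fold is
    preserved within one example and the assignment is reproducible.
    Examples are ordered by fragment id before the shuffle, making the
    report invariant to input order.  Requires at least ``folds``
    examples in each class.
    """
    labeled = sorted(labeled, key=lambda triple: triple[0])
    ids = [fid for fid, _, _ in labeled]
    tokens = [toks for _, toks, _ in labeled]
    labels = np.array([lab for _, _, lab in labeled], dtype=bool)
    for cls in (True, False):
        if (labels == cls).sum() < folds:
            raise ValueError(
                f"class {cls} has fewer than {folds} examples; cannot "
                f"stratify into {folds} folds"
            )
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    assignments: dict[str, int] = {}
    metrics: list[FoldMetrics] = []
    for fold_no, (train_idx, test_idx) in enumerate(
        splitter.split(np.zeros(len(labels)), labels), start=1
    ):
        for i in test_idx:
            assignments[ids[i]] = fold_no
        model = fit(
            [(tokens[i], bool(labels[i])) for i in train_idx],
            alpha=alpha,
            category=category,
            event_model=event_model,
        )
        predictions = np.array(
            [predict(model, tokens[i])[0] for i in test_idx], dtype=bool
        )
        truth = labels[test_idx]
        sensitivity = float((predictions & truth).sum() / truth.sum())
        specificity = float((~predictions & ~truth).sum() / (~truth).sum())
        metrics.append(FoldMetrics(fold_no, sensitivity, specificity))
    return CVReport(category=category, fold_assignments=assignments, folds=metrics)


@dataclass(frozen=True)
class ClassificationSummary:
    """Corpus-wide automated review outcome for one category."""

    category: Category
    confirmed_count: int
    unrelated_count: int

    @property
    def total(self) -> int:
        return self.confirmed_count + self.unrelated_count

    @property
    def unrelated_pct(self) -> float:
        return 100.0 * self.unrelated_count / self.total if self.total else 0.0


def classify_corpus(
    models: Mapping[Category, NBModel],
    screened: Mapping[Category, Sequence[tuple[str, Iterable[str]]]],
) -> dict[Category, ClassificationSummary]:
    """Score every screened fragment with its category's model.

    Each category's screened list is partitioned into confirmed
    (positive) and unrelated (negative) fragments.
    """
    summaries = {}
    for category, items in screened.items():
        model = models[category]
        confirmed = sum(1 for _, tokens in items if predict(model, tokens)[0])
        summaries[category] = ClassificationSummary(
            category=category,
            confirmed_count=confirmed,
            unrelated_count=len(items) - confirmed,
        )
    return summaries


# ---------------------------------------------------------------------------
# Serialization

def model_to_json(model: NBModel) -> str:
    return json.dumps(
        {
            "category": None if model.category is None else model.category.value,
            "prior_positive": model.prior_positive,
            "alpha": model.alpha,
            "event_model": model.event_model,
            "p_pos": model.p_pos,
            "p_neg": model.p_neg,
        },
        indent=2,
        sort_keys=True,
    )


def model_from_json(payload: str) -> NBModel:
    obj = json.loads(payload)
    return NBModel(
        category=None if obj["category"] is None else Category(obj["category"]),
        prior_positive=obj["prior_positive"],
        alpha=obj["alpha"],
        p_pos=obj["p_pos"],
        p_neg=obj["p_neg"],
        event_model=obj["event_model"],
    )


def write_predictions(
    rows: Iterable[tuple[str, Category, float, bool]], stream: IO[str]
) -> None:
    """TSV of (fragment_id, category, posterior, label)."""
    stream.write("fragment_id\tcategory\tposterior\tlabel\n")
    for fid, category, posterior, label in rows:
        stream.write(f"{fid}\t{category}\t{posterior!r}\t{label}\n")
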