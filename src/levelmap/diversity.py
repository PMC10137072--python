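"""Diversity-maximizing selection of a manual-review sample.

The review sample is the size-k subset of screened fragments minimizing
the total pairwise cosine similarity of (a) the whole fragment texts and
(b) the profiles of dictionary terms matched in them, combined with
configurable weights.  The optimizer is a fixed-size-subset genetic
algorithm (tournament selection, union crossover, swap mutation) in the
style commonly used for k-of-n selection; an exhaustive-enumeration
solver is provided as an exact oracle for small instances.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import IO, Callable, Iterable, Mapping, Sequence

import numpy as np
from sklearn.metrics.pairwise import cosine_similarity

from .screening import ScreenHit
from .tokenize import tokenize


@dataclass
class DocTermMatrix:
    """Fragment-by-token count matrix with stable row order."""

    ids: list[str]
    vocabulary: list[str]
    counts: np.ndarray  # shape (n_docs, n_tokens), nonnegative ints

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.ids), len(self.vocabulary)):
            raise ValueError("counts shape does not match ids/vocabulary")


def build_matrix(
    ids: Sequence[str],
    texts: Sequence[str],
    tokenizer: Callable[[str], list[str]] = tokenize,
) -> DocTermMatrix:
    """Count case-folded word tokens per document.

    The vocabulary is the sorted union of tokens over all documents, so
    no all-zero column can occur.  All-empty input is fatal.
    """
    if len(ids) != len(texts):
        raise ValueError("ids and texts must have equal length")
    if not texts:
        raise ValueError("no texts to vectorize")
    token_lists = [tokenizer(t) for t in texts]
    vocabulary = sorted(set(itertools.chain.from_iterable(token_lists)))
    if not vocabulary:
        raise ValueError("all texts are empty after tokenization")
    index = {tok: j for j, tok in enumerate(vocabulary)}
    counts = np.zeros((len(texts), len(vocabulary)), dtype=np.int64)
    for i, tokens in enumerate(token_lists):
        for tok, c in Counter(tokens).items():
            counts[i, index[tok]] = c
    return DocTermMatrix(ids=list(ids), vocabulary=vocabulary, counts=counts)


def term_profile_matrix(
    ids: Sequence[str],
    hits_by_fragment: Mapping[str, Iterable[ScreenHit]],
) -> DocTermMatrix:
    """Counts of matched dictionary-term occurrences per fragment.

    The vocabulary is the set of matched term surfaces, not the full text
    vocabulary; a fragment with no hits gets an all-zero row.
    """
    profiles: list[Counter] = []
    for fid in ids:
        counter: Counter = Counter()
        for hit in hits_by_fragment.get(fid, []):
            for surface, _, _ in hit.matches:
                counter[surface] += 1
        profiles.append(counter)
    vocabulary = sorted(set(itertools.chain.from_iterable(profiles)))
    index = {tok: j for j, tok in enumerate(vocabulary)}
    counts = np.zeros((len(ids), max(len(vocabulary), 1)), dtype=np.int64)
    for i, counter in enumerate(profiles):
        for tok, c in counter.items():
            counts[i, index[tok]] = c
    return DocTermMatrix(
        ids=list(ids), vocabulary=vocabulary or ["<none>"], counts=counts
    )


def cosine_matrix(matrix: DocTermMatrix) -> np.ndarray:
    """Symmetric cosine-similarity matrix of the document rows.

    With nonnegative counts every entry lies in [0, 1]; the diagonal is 1
    for nonzero rows and, by convention, 0 for all-zero rows (which are
    similar to nothing).
    """
    sims = cosine_similarity(matrix.counts)
    nonzero = matrix.counts.any(axis=1)
    sims[~nonzero, :] = 0.0
    sims[:, ~nonzero] = 0.0
    np.fill_diagonal(sims, np.where(nonzero, 1.0, 0.0))
    np.clip(sims, 0.0, 1.0, out=sims)
    return (sims + sims.T) / 2.0


@dataclass(frozen=True)
class SelectionConfig:
    """Subset size, seed, GA hyperparameters and objective weights."""

    k: int
    seed: int = 0
    population_size: int = 100
    generations: int = 200
    tournament_size: int = 2
    mutation_probability: float = 0.01
    weight_text: float = 1.0
    weight_terms: float = 1.0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be positive")
        if self.weight_text == 0 and self.weight_terms == 0:
            raise ValueError("objective weights must not both be zero")


@dataclass
class SelectionResult:
    """Selected fragment ids, achieved objective and per-generation trace."""

    selected_ids: tuple[str, ...]
    objective: float
    trace: list[float] = field(default_factory=list)


def objective(
    subset: Sequence[int],
    sim_text: np.ndarray,
    sim_terms: np.ndarray | None = None,
    weights: tuple[float, float] = (1.0, 1.0),
) -> float:
    """Weighted sum of pairwise similarities inside ``subset`` (indices).

    ``weight_text * sum_{i<j} sim_text[i,j] + weight_terms * sum_{i<j}
    sim_terms[i,j]``; empty and singleton subsets score 0.
    """
    idx = np.asarray(sorted(subset), dtype=np.intp)
    if len(idx) != len(set(subset)):
        raise ValueError("subset contains repeated indices")
    if idx.size < 2:
        return 0.0
    total = 0.0
    for sim, w in ((sim_text, weights[0]), (sim_terms, weights[1])):
        if sim is None or w == 0:
            continue
        block = sim[np.ix_(idx, idx)]
        total += w * (block.sum() - np.trace(block)) / 2.0
    return float(total)


def _combined_similarity(
    sim_text: np.ndarray,
    sim_terms: np.ndarray | None,
    weights: tuple[float, float],
) -> np.ndarray:
    combined = weights[0] * np.asarray(sim_text, dtype=float)
    if sim_terms is not None and weights[1] != 0:
        combined = combined + weights[1] * np.asarray(sim_terms, dtype=float)
    return combined


def _pair_sums(population: np.ndarray, sim: np.ndarray) -> np.ndarray:
    """Objective value for each size-k subset row of ``population``."""
    blocks = sim[population[:, :, None], population[:, None, :]]
    diagonals = sim[population, population]
    return (blocks.sum(axis=(1, 2)) - diagonals.sum(axis=1)) / 2.0


def select_diverse(
    ids: Sequence[str],
    sim_text: np.ndarray,
    sim_terms: np.ndarray | None,
    cfg: SelectionConfig,
) -> SelectionResult:
    """Pick ``cfg.k`` maximally diverse candidates with a subset GA.

    Deterministic for a fixed ``cfg.seed``.  The initial population is
    ``cfg.population_size`` seeded random subsets and the best individual
    is carried over each generation, so the result is never worse than
    the best of those random subsets.  Ties in the final population are
    broken by the lexicographically smallest id subset.
    """
    n = len(ids)
    if cfg.k > n:
        raise ValueError(f"cannot select k={cfg.k} from n={n} candidates")
    sim = _combined_similarity(sim_text, sim_terms, (cfg.weight_text, cfg.weight_terms))
    if sim.shape != (n, n):
        raise ValueError("similarity matrix shape does not match candidates")
    full = objective(range(n), sim)
    if cfg.k == n:
        return SelectionResult(tuple(sorted(ids)), full, [full])

    rng = np.random.default_rng(cfg.seed)
    pop_size, k = cfg.population_size, cfg.k
    population = np.stack(
        [np.sort(rng.choice(n, size=k, replace=False)) for _ in range(pop_size)]
    )
    fitness = _pair_sums(population, sim)
    trace = [float(fitness.min())]

    for _ in range(cfg.generations):
        children = np.empty_like(population)
        children[0] = population[np.argmin(fitness)]  # elitism
        for c in range(1, pop_size):
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, pop_size, size=cfg.tournament_size)
                parents.append(population[contenders[np.argmin(fitness[contenders])]])
            pool = np.union1d(parents[0], parents[1])
            child = rng.choice(pool, size=k, replace=False)
            mutate = rng.random(k) < cfg.mutation_probability
            if mutate.any():
                members = set(child.tolist())
                outside = np.array(
                    [i for i in range(n) if i not in members], dtype=np.intp
                )
                for pos in np.flatnonzero(mutate):
                    if outside.size == 0:
                        break
                    j = rng.integers(0, outside.size)
                    members.discard(int(child[pos]))
                    child[pos], outside[j] = outside[j], child[pos]
                    members.add(int(child[pos]))
            children[c] = np.sort(child)
        population = children
        fitness = _pair_sums(population, sim)
        trace.append(float(fitness.min()))

    best = fitness.min()
    tied = population[fitness <= best + 1e-12]
    best_ids = min(
        tuple(sorted(ids[i] for i in row)) for row in np.unique(tied, axis=0)
    )
    return SelectionResult(selected_ids=best_ids, objective=float(best), trace=trace)


def brute_force_select(
    ids: Sequence[str],
    sim_text: np.ndarray,
    sim_terms: np.ndarray | None,
    k: int,
    weights: tuple[float, float] = (1.0, 1.0),
    max_subsets: int = 10**6,
) -> SelectionResult:
    """Exact optimum by enumerating every size-k subset (test oracle).

    Ties are broken by the lexicographically smallest id subset.  Fatal
    when C(n, k) exceeds ``max_subsets``.
    """
    n = len(ids)
    if k > n:
        raise ValueError(f"cannot select k={k} from n={n}")
    if math.comb(n, k) > max_subsets:
        raise ValueError(f"C({n},{k}) exceeds the enumeration limit {max_subsets}")
    sim = _combined_similarity(sim_text, sim_terms, weights)
    best_value = math.inf
    best_ids: tuple[str, ...] | None = None
    for combo in itertools.combinations(range(n), k):
        idx = np.asarray(combo, dtype=np.intp)
        block = sim[np.ix_(idx, idx)]
        value = (block.sum() - np.trace(block)) / 2.0
        candidate = tuple(sorted(ids[i] for i in combo))
        if value < best_value - 1e-12 or (
            abs(value - best_value) <= 1e-12 and candidate < best_ids
        ):
            best_value = value
            best_ids = candidate
    assert best_ids is not None
    return SelectionResult(selected_ids=best_ids, objective=float(best_value))


def write_selection(result: SelectionResult, stream: IO[str]) -> None:
    """Write selected ids as a one-column TSV."""
    stream.write("fragment_id\n")
    for fid in result.selected_ids:
        stream.write(f"{fid}\n")


def write_trace(result: SelectionResult, stream: IO[str]) -> None:
    """Write the best objective per generation as a two-column TSV."""
    stream.write("generation\tobjective\n")
    for gen, value in enumerate(result.trace):
        stream.write(f"{gen}\t{value!r}\n")
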