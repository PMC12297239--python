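"""Before/after ranking evaluation with Tanimoto structural-similarity metrics.

Given analog-search results for a cohort of queries with known true
structures, this module measures how functional-group-informed reranking
changes (i) the best Tanimoto similarity among the top-1 and top-5 hits and
(ii) the rank of the most structurally similar match, and evaluates top-k
accuracy for candidate lists where the true structure itself may be present.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np

from .chemcore import ChemError, canonical_smiles, fingerprint, tanimoto
from .reactions import Reaction
from .specsearch import AnalogMatch, fg_consistent

__all__ = [
    "QueryCase",
    "QueryEvaluation",
    "CohortMetrics",
    "CandidateList",
    "filter_by_best_analog",
    "topk_best_tanimoto",
    "rank_of_best",
    "evaluate_query",
    "compare_rankings",
    "rerank_candidate_list",
    "topk_accuracy",
]


@lru_cache(maxsize=65536)
def _similarity(truth: str, other: str) -> float:
    return tanimoto(fingerprint(truth), fingerprint(other))


@dataclass(frozen=True)
class QueryCase:
    """One query: its true structure plus ranked analog matches."""

    query_id: str
    true_structure: str
    matches: tuple[AnalogMatch, ...]


@dataclass(frozen=True)
class QueryEvaluation:
    query_id: str
    true_structure: str
    top1_before: float
    top1_after: float
    top5_before: float
    top5_after: float
    rank_of_best_before: int
    rank_of_best_after: int

    def __post_init__(self) -> None:
        if self.top5_before < self.top1_before or self.top5_after < self.top1_after:
            raise ChemError("top-5 best similarity cannot fall below top-1")


@dataclass(frozen=True)
class MetricSplit:
    n_improved: int
    n_decreased: int
    n_unchanged: int
    mean_before: float
    mean_after: float

    @property
    def relative_improvement(self) -> float:
        """(after - before) / before; positive when the metric rose."""
        return (self.mean_after - self.mean_before) / self.mean_before


@dataclass(frozen=True)
class CohortMetrics:
    n_queries: int
    top1: MetricSplit
    top5: MetricSplit
    rank_of_best: MetricSplit


def best_analog_similarity(case: QueryCase) -> float | None:
    """Highest Tanimoto similarity of any match to the true structure."""
    if not case.matches:
        return None
    return max(
        _similarity(canonical_smiles(case.true_structure), canonical_smiles(m.structure))
        for m in case.matches
        if m.structure is not None
    )


def filter_by_best_analog(
    cases: list[QueryCase], min_similarity: float = 0.5
) -> list[QueryCase]:
    """Keep queries with at least one analog >= min_similarity (inclusive).

    This restricts evaluation to queries for which a genuinely similar
    structure exists in the library at all; queries with no matches drop out.
    """
    kept = []
    for case in cases:
        best = best_analog_similarity(case)
        if best is not None and best >= min_similarity:
            kept.append(case)
    return kept


def topk_best_tanimoto(
    matches: list[AnalogMatch] | tuple[AnalogMatch, ...], truth: str, k: int
) -> float | None:
    """Best Tanimoto to truth among the first min(k, n) matches; None if empty."""
    if k < 1:
        raise ChemError("k must be >= 1")
    truth_c = canonical_smiles(truth)
    head = [m for m in list(matches)[:k] if m.structure is not None]
    if not head:
        return None
    return max(_similarity(truth_c, canonical_smiles(m.structure)) for m in head)


def rank_of_best(
    matches: list[AnalogMatch] | tuple[AnalogMatch, ...], truth: str
) -> int | None:
    """1-based position of the match most similar to truth (earliest on ties)."""
    matches = list(matches)
    if not matches:
        return None
    truth_c = canonical_smiles(truth)
    sims = [
        _similarity(truth_c, canonical_smiles(m.structure))
        if m.structure is not None
        else -1.0
        for m in matches
    ]
    return int(np.argmax(sims)) + 1


def evaluate_query(
    before: QueryCase, after_matches: tuple[AnalogMatch, ...]
) -> QueryEvaluation:
    """Per-query before/after metrics for one reranked match list."""
    _check_same_matches(before.matches, after_matches, before.query_id)
    t = before.true_structure
    return QueryEvaluation(
        query_id=before.query_id,
        true_structure=t,
        top1_before=topk_best_tanimoto(before.matches, t, 1),
        top1_after=topk_best_tanimoto(after_matches, t, 1),
        top5_before=topk_best_tanimoto(before.matches, t, 5),
        top5_after=topk_best_tanimoto(after_matches, t, 5),
        rank_of_best_before=rank_of_best(before.matches, t),
        rank_of_best_after=rank_of_best(after_matches, t),
    )


def _check_same_matches(before, after, qid) -> None:
    if sorted(m.library_id for m in before) != sorted(m.library_id for m in after):
        raise ChemError(f"query {qid}: before/after match sets differ")


def _split(pairs: list[tuple[float, float]], higher_is_better: bool) -> MetricSplit:
    before = np.array([b for b, _ in pairs], dtype=float)
    after = np.array([a for _, a in pairs], dtype=float)
    delta = after - before
    if not higher_is_better:
        delta = -delta
    return MetricSplit(
        n_improved=int((delta > 0).sum()),
        n_decreased=int((delta < 0).sum()),
        n_unchanged=int((delta == 0).sum()),
        mean_before=float(before.mean()),
        mean_after=float(after.mean()),
    )


def compare_rankings(
    before: list[QueryCase], after: dict[str, tuple[AnalogMatch, ...]]
) -> CohortMetrics:
    """Cohort-level improved/decreased/unchanged splits and means.

    ``after`` maps query id to the reranked match tuple, which must be a
    permutation of the corresponding before-matches.  Similarity metrics
    count strict changes; equal values are unchanged.  Rank-of-best improves
    when it decreases.
    """
    if {c.query_id for c in before} != set(after):
        raise ChemError("before/after query sets differ")
    evals = [evaluate_query(c, after[c.query_id]) for c in before]
    return CohortMetrics(
        n_queries=len(evals),
        top1=_split([(e.top1_before, e.top1_after) for e in evals], True),
        top5=_split([(e.top5_before, e.top5_after) for e in evals], True),
        rank_of_best=_split(
            [(e.rank_of_best_before, e.rank_of_best_after) for e in evals], False
        ),
    )


@dataclass(frozen=True)
class CandidateList:
    """A ranked in-silico candidate list for one query spectrum."""

    query_id: str
    true_structure: str
    candidates: tuple[tuple[str, float], ...]  # (structure SMILES, score)
    rank_of_truth: int | None = None

    def with_recomputed_rank(self) -> "CandidateList":
        truth_c = canonical_smiles(self.true_structure)
        rank = None
        for i, (structure, _) in enumerate(self.candidates, start=1):
            try:
                if canonical_smiles(structure) == truth_c:
                    rank = i
                    break
            except ChemError:
                continue
        return replace(self, rank_of_truth=rank)


def rerank_candidate_list(
    clist: CandidateList,
    observed: set[str],
    registry: list[Reaction],
    mode: str = "all",
) -> CandidateList:
    """FG-first stable partition of a candidate list; recomputes rank_of_truth.

    Candidates whose structure carries the groups evidenced by every observed
    reaction move ahead of the rest, preserving relative order inside each
    block.  When the true structure carries every observed group (error-free
    chemistry), its rank can only improve or stay.
    """
    if not observed:
        return clist.with_recomputed_rank()
    consistent, rest = [], []
    for structure, score in clist.candidates:
        try:
            ok = fg_consistent(structure, observed, registry, mode)
        except ChemError:
            ok = False
        (consistent if ok else rest).append((structure, score))
    return replace(
        clist, candidates=tuple(consistent + rest)
    ).with_recomputed_rank()


def topk_accuracy(
    lists: list[CandidateList], ks: list[int]
) -> dict[int, float | None]:
    """Fraction of queries whose true structure ranks within the top k.

    Only queries whose truth is present in the candidate set enter the
    denominator; with no such queries the accuracy is None.
    """
    ranked = [c.with_recomputed_rank() for c in lists]
    present = [c.rank_of_truth for c in ranked if c.rank_of_truth is not None]
    return {
        k: (sum(r <= k for r in present) / len(present)) if present else None
        for k in ks
    }
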