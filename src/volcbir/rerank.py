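"""Second-stage re-ranking of top-M candidate volumes.

Two re-rankers over the first-stage candidate lists:

**C-MIR** (ColBERT-inspired late interaction).  Slices play the role of
ColBERT's tokens and volumes the role of passages.  For a query volume with
row-normalized embedding matrix ``M_Q`` (n x L) and a candidate with matrix
``M_C`` (m x L), the similarity matrix ``S = M_Q @ M_C.T`` holds every
pairwise slice cosine; the candidate's rank score is the sum over query
slices of the best-matching candidate slice::

    RS(C) = sum_i max_j S[i, j]

so ``RS <= n`` always, with equality exactly when every query slice has a
perfect match.  Candidates are reordered by descending RS; ties preserve the
incoming first-stage order (stable re-ranking).  Because the row-max picks
out whichever candidate slices resemble the informative query slices, C-MIR
localizes the relevant region implicitly -- no organ segmentation of the
database is needed.

**RRF** (reciprocal rank fusion).  Fuses the three first-stage lists
(count, max_score, sum_sim) by summing reciprocal ranks,
``RRF(V) = sum_l 1 / (k + rank(V, L_l))`` with 1-based ranks and smoothing
``k = 60``; a volume absent from a list contributes a zero summand for it.
RRF depends only on ranks, never on score magnitudes.
"""

from __future__ import annotations

import numpy as np

from .datamodel import Cohort, VolumeRecord
from .retrieval import RankedList

__all__ = [
    "similarity_matrix",
    "cmir_rank_score",
    "cmir_rerank",
    "rrf_scores",
    "rrf_rerank",
]


def similarity_matrix(m_q: np.ndarray, m_w: np.ndarray) -> np.ndarray:
    """All pairwise slice cosines between two row-normalized matrices.

    Entry ``(i, j)`` is the inner product of query row ``i`` and candidate
    row ``j``; for unit rows this is their cosine similarity, so every entry
    lies in [-1, 1] up to rounding.
    """
    m_q = np.asarray(m_q, dtype=np.float64)
    m_w = np.asarray(m_w, dtype=np.float64)
    if m_q.ndim != 2 or m_w.ndim != 2 or m_q.shape[1] != m_w.shape[1]:
        raise ValueError(
            f"incompatible matrix shapes {m_q.shape} and {m_w.shape}"
        )
    return m_q @ m_w.T


def cmir_rank_score(sim: np.ndarray) -> float:
    """Late-interaction rank score: sum over rows of the row maximum."""
    sim = np.asarray(sim, dtype=np.float64)
    if sim.ndim != 2 or sim.size == 0:
        raise ValueError("similarity matrix must be 2D and non-empty")
    return float(sim.max(axis=1).sum())


def cmir_rerank(
    query: VolumeRecord,
    candidates: RankedList,
    cohort: Cohort,
    M: int = 20,
) -> RankedList:
    """Reorder the top-``M`` first-stage candidates by C-MIR rank score.

    Uses each candidate's *full* embedding matrix (not just its hit slices),
    fetched from ``cohort`` one at a time so the working set stays at one
    query matrix plus one candidate matrix.  Membership of the list is
    unchanged: re-ranking only permutes.  Equal rank scores keep their
    incoming relative order.
    """
    head = candidates.items[:M]
    missing = [v for v, _ in head if v not in cohort]
    if missing:
        raise KeyError(f"candidate volume(s) not in cohort: {missing}")
    scores = np.empty(len(head))
    for i, (vid, _) in enumerate(head):
        sim = similarity_matrix(query.matrix, cohort[vid].matrix)
        scores[i] = cmir_rank_score(sim)
    order = np.argsort(-scores, kind="stable")
    return RankedList(
        method="cmir",
        query_id=candidates.query_id,
        items=[(head[i][0], float(scores[i])) for i in order],
    )


def rrf_scores(lists: list[RankedList], k_smooth: int = 60) -> dict[str, float]:
    """Reciprocal-rank-fusion score for every volume in the union of 3 lists.

    Exactly three lists are expected (the count / max_score / sum_sim top-M
    lists for one query).  A volume absent from a list has rank +inf there
    and contributes nothing for that list.
    """
    if len(lists) != 3:
        raise ValueError(f"RRF fuses exactly 3 ranked lists, got {len(lists)}")
    if k_smooth <= 0:
        raise ValueError("k_smooth must be positive")
    scores: dict[str, float] = {}
    for lst in lists:
        for rank, (vid, _) in enumerate(lst.items, start=1):
            scores[vid] = scores.get(vid, 0.0) + 1.0 / (k_smooth + rank)
    return scores


def rrf_rerank(lists: list[RankedList], k_smooth: int = 60) -> RankedList:
    """Order the union of the three lists by descending RRF score.

    Ties are broken by ascending volume id for determinism.
    """
    scores = rrf_scores(lists, k_smooth)
    order = sorted(scores, key=lambda v: (-scores[v], v))
    return RankedList(
        method="rrf",
        query_id=lists[0].query_id,
        items=[(v, scores[v]) for v in order],
    )
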