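"""Retrieval evaluation: relevance rules, P@k, AP, seeded runs, Wilcoxon.

Two retrieval tasks define relevance of a retrieved volume for a query:

``flagging``
    Relevant iff the retrieved volume's tumor status *in the target organ*
    matches the query's.  A liver-task volume retrieved for a lung query
    counts as lung-negative even though its liver carries a tumor.
``staging``
    Relevant iff both are tumor-free in the target organ, or both are
    positive with the same stage (strict stage equality).

Metrics follow standard retrieval practice over the top-10 ranked list:
precision at k (k in {3, 5, 10}) and average precision
``AP = sum_n (R_n - R_{n-1}) P_n`` with the recall denominator taken as the
number of relevant items *within the top-10 list* (lists shorter than 10 are
padded with non-relevant slots).  Method comparisons use the two-sided
Wilcoxon signed-rank test on per-seed mean AP, with zero differences dropped
and the exact null distribution (tie-aware, computed by dynamic programming
over signed midranks) for n <= 25.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import Cohort, VolumeRecord
from .retrieval import RankedList

__all__ = [
    "TASKS",
    "P_AT_KS",
    "AP_DEPTH",
    "RelevanceJudgment",
    "judge",
    "precision_at_k",
    "average_precision",
    "wilcoxon_paired",
    "evaluate_ranked_list",
    "run_experiment",
    "compare_methods",
]

TASKS = ("flagging", "staging")
P_AT_KS = (3, 5, 10)
AP_DEPTH = 10


@dataclass
class RelevanceJudgment:
    """Per-retrieved-volume relevance booleans for one query and task."""

    task: str
    query_id: str
    relevant: list[bool]


def _effective_status(rec: VolumeRecord, target_organ: str | None) -> tuple[bool, str | None]:
    """Tumor flag/stage of ``rec`` as seen from the target organ."""
    if target_organ is None or rec.organ == target_organ:
        return rec.tumor_flag, rec.stage
    return False, None


def judge(
    query: VolumeRecord,
    ranked: RankedList,
    cohort: Cohort,
    task: str,
    target_organ: str | None = None,
) -> RelevanceJudgment:
    """Judge each retrieved volume relevant or not for ``query``.

    ``target_organ`` defaults to the query's own organ when omitted and the
    query is evaluated against a multi-organ database; pass ``None`` only
    when raw volume-level labels are wanted.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")
    q_flag, q_stage = _effective_status(query, target_organ)
    rel: list[bool] = []
    for vid, _ in ranked.items:
        c_flag, c_stage = _effective_status(cohort[vid], target_organ)
        if task == "flagging":
            rel.append(c_flag == q_flag)
        else:
            if q_flag and c_flag:
                if q_stage is None or c_stage is None:
                    raise ValueError(
                        f"staging task but stage missing on {ranked.query_id}/{vid}"
                    )
                rel.append(q_stage == c_stage)
            else:
                rel.append(q_flag == c_flag)
    return RelevanceJudgment(task=task, query_id=query.volume_id, relevant=rel)


def precision_at_k(judgment: RelevanceJudgment, k: int) -> float:
    """Fraction of relevant items among the top ``k`` (missing slots count
    as non-relevant)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    top = judgment.relevant[:k]
    return sum(top) / k


def average_precision(judgment: RelevanceJudgment, depth: int = AP_DEPTH) -> float:
    """Rank-weighted precision over the top ``depth`` retrieved items.

    ``AP = sum_{n=1..depth} (R_n - R_{n-1}) P_n`` where ``P_n`` is the
    precision at rank ``n`` and ``R_n`` the recall with denominator equal to
    the number of relevant items in the top-``depth`` list; 0 when nothing
    relevant was retrieved.  Algebraically this is the mean of ``P_n`` over
    relevant ranks ``n``.
    """
    rel = np.asarray(judgment.relevant[:depth], dtype=bool)
    n_rel = int(rel.sum())
    if n_rel == 0:
        return 0.0
    ranks = np.arange(1, rel.size + 1)
    precisions = np.cumsum(rel) / ranks
    return float(precisions[rel].sum() / n_rel)


def _exact_signed_rank_p(ranks2: np.ndarray, w2: float) -> float:
    """Exact two-sided signed-rank p-value via DP over doubled midranks.

    ``ranks2`` are the doubled (hence integral) midranks of |differences|;
    ``w2`` is the doubled positive-rank sum.  Enumerates the full null
    distribution of W+ (each sign pattern equally likely), which is valid
    with ties because midranks are fixed by |d|.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in ranks2.astype(int):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2i = int(round(w2))
    p_le = counts[: w2i + 1].sum()
    p_ge = counts[w2i:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_paired(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    Zero differences are dropped (Wilcoxon's original treatment); if all
    differences are zero the samples are indistinguishable and p = 1 is
    returned with a warning.  For n <= 25 retained pairs the exact, tie-aware
    null distribution is used; larger samples fall back to the normal
    approximation with tie correction.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equally sized 1D samples of length >= 2")
    d = a - b
    d = d[d != 0.0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; p-value is 1")
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    if d.size <= 25:
        ranks2 = np.round(2.0 * ranks)
        w2 = float(ranks2[d > 0].sum())
        return _exact_signed_rank_p(ranks2, w2)
    res = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided", method="approx")
    return float(res.pvalue)


def evaluate_ranked_list(
    query: VolumeRecord,
    ranked: RankedList,
    cohort: Cohort,
    task: str,
    target_organ: str | None = None,
) -> dict:
    """P@{3,5,10} and AP for one (query, ranked list) pair."""
    j = judge(query, ranked, cohort, task, target_organ)
    out = {f"p{k}": precision_at_k(j, k) for k in P_AT_KS}
    out["ap"] = average_precision(j)
    return out


def run_experiment(
    setup_builder: Callable[[int], tuple],
    methods: Sequence[str],
    seeds: Sequence[int],
    task: str,
    rank_fn: Callable[..., dict] | None = None,
    **rank_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Repeat the full evaluation over seeds and summarise per seed.

    ``setup_builder(seed)`` must return ``(cohort, split, index)`` -- a
    freshly sampled query/database split and an index over the database side.
    Every query is ranked under every method by
    :func:`volcbir.experiment.rank_all_methods` (or ``rank_fn`` if given)
    and judged under ``task``.  Returns the per-query record table and the
    per-seed mean table (one row per seed x method), the machine twin of the
    published results-table layout.
    """
    if not seeds:
        raise ValueError("need at least one seed")
    if rank_fn is None:
        from .experiment import rank_all_methods

        rank_fn = rank_all_methods
    records: list[dict] = []
    for seed in seeds:
        cohort, split, index = setup_builder(int(seed))
        for qid in split.query_ids:
            query = cohort[qid]
            ranked_by_method = rank_fn(query, index, cohort, methods=methods, **rank_kwargs)
            target = split.query_targets.get(qid)
            for method in methods:
                metrics = evaluate_ranked_list(
                    query, ranked_by_method[method], cohort, task, target
                )
                records.append(
                    {
                        "seed": seed,
                        "method": method,
                        "query_id": qid,
                        "organ": target,
                        "task": task,
                        **metrics,
                    }
                )
    per_query = pd.DataFrame.from_records(records)
    per_seed = (
        per_query.groupby(["seed", "method"], as_index=False)[
            ["p3", "p5", "p10", "ap"]
        ]
        .mean()
        .rename(columns={k: f"mean_{k}" for k in ("p3", "p5", "p10", "ap")})
    )
    return per_query, per_seed


def compare_methods(
    per_seed: pd.DataFrame, baseline: str = "cmir"
) -> pd.DataFrame:
    """Paired Wilcoxon tests of ``baseline`` against every other method.

    Pairs per-seed mean AP vectors (aligned on seed).  Returns one row per
    comparison: method_a, method_b, mean AP of each, and the two-sided
    p-value.
    """
    methods = sorted(per_seed["method"].unique())
    if baseline not in methods:
        raise ValueError(f"baseline {baseline!r} not among methods {methods}")
    pivot = per_seed.pivot(index="seed", columns="method", values="mean_ap")
    rows = []
    for other in methods:
        if other == baseline:
            continue
        a, b = pivot[baseline].to_numpy(), pivot[other].to_numpy()
        rows.append(
            {
                "method_a": baseline,
                "method_b": other,
                "mean_ap_a": float(a.mean()),
                "mean_ap_b": float(b.mean()),
                "p_value": wilcoxon_paired(a, b),
                "n_seeds": int(a.size),
            }
        )
    return pd.DataFrame(rows)
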