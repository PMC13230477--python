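"""Volume-level first-stage retrieval via hit-table aggregation.

For a query volume with ``n`` slices, each slice is searched against the
slice index and its top ``n_neighbors`` (default 20) hits are recorded in a
*hit table* -- one ordered row of (volume, slice, cosine) per query slice.
Database volumes are then ranked by one of three aggregations over their
hit-table entries:

``count``
    Number of hits belonging to the volume (Count-base).
``max_score``
    The volume's single best cosine score (Max-Score).
``sum_sim``
    Sum of all the volume's hit cosines (Sum-Sim).

Multiple hits of the same volume within one row all contribute; the hit
table records slices, not volumes, so a volume whose several slices resemble
one query slice accumulates evidence.  Ties in aggregate score are broken by
higher summed similarity, then ascending volume id, making rankings
deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .datamodel import VolumeRecord
from .index import SliceHit, SliceIndex, search

__all__ = [
    "AGGREGATION_METHODS",
    "HitTable",
    "RankedList",
    "build_hit_table",
    "aggregate_count",
    "aggregate_max_score",
    "aggregate_sum_sim",
    "retrieve_top_volumes",
]

AGGREGATION_METHODS = ("count", "max_score", "sum_sim")


@dataclass
class HitTable:
    """Per-query-slice ordered slice hits."""

    query_id: str
    rows: list[list[SliceHit]]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("hit table must have at least one row")

    @property
    def n_rows(self) -> int:
        return len(self.rows)


@dataclass
class RankedList:
    """Ordered candidate volumes for one query, tagged with the method."""

    method: str
    query_id: str
    items: list[tuple[str, float]] = field(default_factory=list)

    @property
    def volume_ids(self) -> list[str]:
        return [v for v, _ in self.items]

    def __len__(self) -> int:
        return len(self.items)

    def rank_of(self, volume_id: str) -> int | None:
        """1-based rank of ``volume_id``, or None if absent."""
        for i, (v, _) in enumerate(self.items, start=1):
            if v == volume_id:
                return i
        return None


def build_hit_table(
    query: VolumeRecord, index: SliceIndex, n_neighbors: int = 20
) -> HitTable:
    """Search every query slice and collect its ordered hits.

    The query's own volume id is excluded from every row, so the hit table is
    valid even when query and database volumes share one index (splits are
    disjoint by construction, but planted-copy fixtures are not).
    """
    rows = [
        search(index, query.matrix[i], n_neighbors, exclude_volume=query.volume_id)
        for i in range(query.n_slices)
    ]
    return HitTable(query_id=query.volume_id, rows=rows)


def _gather(ht: HitTable) -> dict[str, tuple[int, float, float]]:
    """Per volume: (hit count, max score, summed score) over all rows.

    The sum uses exact float summation over sorted scores so aggregate values
    are bit-identical under any reordering of rows or hits.
    """
    import math

    scores: dict[str, list[float]] = {}
    for row in ht.rows:
        for hit in row:
            scores.setdefault(hit.ref.volume_id, []).append(hit.score)
    return {
        v: (len(s), max(s), math.fsum(sorted(s))) for v, s in scores.items()
    }


def _ranked(ht: HitTable, method: str, primary: dict[str, float]) -> RankedList:
    stats = _gather(ht)
    # tie rule: primary score desc, then sum_sim desc, then volume_id asc
    order = sorted(
        primary, key=lambda v: (-primary[v], -stats[v][2], v)
    )
    return RankedList(
        method=method,
        query_id=ht.query_id,
        items=[(v, float(primary[v])) for v in order],
    )


def aggregate_count(ht: HitTable) -> RankedList:
    """Rank volumes by number of hit-table entries (Count-base)."""
    stats = _gather(ht)
    return _ranked(ht, "count", {v: float(c) for v, (c, _, _) in stats.items()})


def aggregate_max_score(ht: HitTable) -> RankedList:
    """Rank volumes by their single highest hit cosine (Max-Score)."""
    stats = _gather(ht)
    return _ranked(ht, "max_score", {v: mx for v, (_, mx, _) in stats.items()})


def aggregate_sum_sim(ht: HitTable) -> RankedList:
    """Rank volumes by the sum of their hit cosines (Sum-Sim)."""
    stats = _gather(ht)
    return _ranked(ht, "sum_sim", {v: sm for v, (_, _, sm) in stats.items()})


_AGGREGATORS = {
    "count": aggregate_count,
    "max_score": aggregate_max_score,
    "sum_sim": aggregate_sum_sim,
}


def retrieve_top_volumes(ht: HitTable, method: str, k: int = 20) -> RankedList:
    """Top-``k`` volumes under the chosen aggregation."""
    if method not in _AGGREGATORS:
        raise ValueError(
            f"unknown aggregation {method!r}; expected one of {AGGREGATION_METHODS}"
        )
    if k == 0:
        warnings.warn("retrieve_top_volumes called with k=0; returning empty list")
    if k < 0:
        raise ValueError("k must be >= 0")
    full = _AGGREGATORS[method](ht)
    return RankedList(method=method, query_id=ht.query_id, items=full.items[:k])
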