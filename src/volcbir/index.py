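"""Slice-level nearest-neighbour search over a cohort's slice embeddings.

Every slice of every indexed volume becomes one entry; queries return the
slices with the largest inner product, which equals cosine similarity since
all vectors are unit-norm.  Two backends share the interface:

``exact``
    Dense matrix scan; returns the true top-n for every query and serves as
    the oracle the approximate backend is validated against.
``ann``
    Graph-based approximate nearest-neighbour index (NN-descent, via
    pynndescent).  Candidate sets are approximate; the returned scores are
    recomputed exactly and ordered under the same deterministic tie rule as
    the exact backend, so only *recall* is approximate.

Ties in score are broken ascending by ``(volume_id, slice_index)`` so that
searches are reproducible across platforms and indexing order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .datamodel import Cohort, _check_unit_rows

__all__ = [
    "SliceRef",
    "SliceHit",
    "SliceIndex",
    "DEFAULT_ANN_PARAMS",
    "build_index",
    "search",
    "save_index",
    "load_index",
]

#: Default graph parameters for the approximate backend: graph degree,
#: construction breadth (candidate pool during graph build) and search
#: breadth (epsilon-controlled backtracking at query time).
DEFAULT_ANN_PARAMS: dict = {
    "n_neighbors_graph": 32,
    "construction_breadth": 100,
    "search_breadth": 128,
    "seed": 0,
}


@dataclass(frozen=True, order=True)
class SliceRef:
    """Reference to one slice row of one indexed volume."""

    volume_id: str
    slice_index: int


@dataclass(frozen=True)
class SliceHit:
    """A retrieved slice and its cosine similarity to the query slice."""

    ref: SliceRef
    score: float


class SliceIndex:
    """Searchable flat store of unit-norm slice embeddings.

    Not constructed directly -- use :func:`build_index`.
    """

    def __init__(
        self,
        backend: str,
        vectors: np.ndarray,
        volume_ids: list[str],
        slice_indices: np.ndarray,
        params: dict,
    ) -> None:
        self.backend = backend
        self._vectors = vectors  # (entries, L) float32, unit rows
        self._volume_ids = volume_ids  # per entry
        self._slice_indices = slice_indices  # per entry, int64
        self.params = params
        # ranks of volume ids in lexicographic order, for the tie rule
        uniq = sorted(set(volume_ids))
        vol_rank = {v: i for i, v in enumerate(uniq)}
        self._vol_rank = np.asarray([vol_rank[v] for v in volume_ids], dtype=np.int64)
        self._vol_counts: dict[str, int] = {}
        for v in volume_ids:
            self._vol_counts[v] = self._vol_counts.get(v, 0) + 1
        self._nnd = None

    @property
    def entries(self) -> int:
        return int(self._vectors.shape[0])

    @property
    def embedding_dim(self) -> int:
        return int(self._vectors.shape[1])

    def ref(self, internal_id: int) -> SliceRef:
        """Total mapping from internal entry id to :class:`SliceRef`."""
        return SliceRef(self._volume_ids[internal_id], int(self._slice_indices[internal_id]))

    def _fit_ann(self) -> None:
        from pynndescent import NNDescent

        p = self.params
        self._nnd = NNDescent(
            self._vectors,
            metric="cosine",
            n_neighbors=min(int(p["n_neighbors_graph"]), self.entries - 1),
            # breadth above the entry count trips allocation failures upstream
            max_candidates=min(int(p["construction_breadth"]), self.entries - 1),
            random_state=int(p["seed"]),
            compressed=False,
            verbose=False,
        )
        self._nnd.prepare()


def build_index(
    cohort: Cohort,
    backend: str = "exact",
    params: Mapping | None = None,
    slice_masks: Mapping[str, np.ndarray] | None = None,
    volume_ids: Sequence[str] | None = None,
) -> SliceIndex:
    """Index every searchable slice of ``cohort`` exactly once.

    Parameters
    ----------
    backend
        ``"exact"`` or ``"ann"``.
    params
        Backend parameters; for ``"ann"`` defaults to
        :data:`DEFAULT_ANN_PARAMS`, updated with any keys given.
    slice_masks
        Optional map volume_id -> slice indices that are searchable (e.g. a
        segmentation-restricted database keeps only the slices showing the
        target organ).  Volumes absent from the map contribute all slices.
    volume_ids
        Optional subset of volumes to index (e.g. the database side of a
        split); defaults to the whole cohort.
    """
    if backend not in ("exact", "ann"):
        raise ValueError(f"unknown backend {backend!r}; expected 'exact' or 'ann'")
    ids = list(volume_ids) if volume_ids is not None else cohort.volume_ids
    if not ids:
        raise ValueError("cannot index an empty cohort")
    blocks: list[np.ndarray] = []
    ent_vols: list[str] = []
    ent_slices: list[np.ndarray] = []
    for vid in ids:
        rec = cohort[vid]
        if slice_masks is not None and vid in slice_masks:
            keep = np.asarray(slice_masks[vid], dtype=np.int64)
        else:
            keep = np.arange(rec.n_slices, dtype=np.int64)
        if keep.size == 0:
            continue
        blocks.append(rec.matrix[keep])
        ent_vols.extend([vid] * keep.size)
        ent_slices.append(keep)
    if not blocks:
        raise ValueError("no searchable slices after applying slice masks")
    vectors = np.vstack(blocks)
    merged = dict(DEFAULT_ANN_PARAMS) if backend == "ann" else {}
    if params:
        merged.update(params)
    idx = SliceIndex(
        backend=backend,
        vectors=vectors,
        volume_ids=ent_vols,
        slice_indices=np.concatenate(ent_slices),
        params=merged,
    )
    if backend == "ann":
        idx._fit_ann()
    return idx


def _order_and_trim(
    index: SliceIndex,
    candidate_ids: np.ndarray,
    scores: np.ndarray,
    n_neighbors: int,
    exclude_volume: str | None,
) -> list[SliceHit]:
    """Apply the deterministic tie rule and truncate to ``n_neighbors``."""
    if exclude_volume is not None:
        keep = np.asarray(
            [index._volume_ids[i] != exclude_volume for i in candidate_ids], dtype=bool
        )
        candidate_ids, scores = candidate_ids[keep], scores[keep]
    # primary: score descending; then volume_id, slice_index ascending
    order = np.lexsort(
        (
            index._slice_indices[candidate_ids],
            index._vol_rank[candidate_ids],
            -scores,
        )
    )[:n_neighbors]
    return [
        SliceHit(ref=index.ref(int(candidate_ids[i])), score=float(scores[i]))
        for i in order
    ]


def search(
    index: SliceIndex,
    q: np.ndarray,
    n_neighbors: int = 20,
    exclude_volume: str | None = None,
) -> list[SliceHit]:
    """Return the ``n_neighbors`` most cosine-similar indexed slices to ``q``.

    ``q`` must be a unit-norm vector of the index's embedding dimension.
    Scores are non-increasing; ties are broken ascending by
    ``(volume_id, slice_index)``.  ``exclude_volume`` removes all slices of
    one volume from consideration (used to keep a query volume out of its
    own hit table when both sides live in one store).
    """
    q = np.asarray(q, dtype=np.float64).ravel()
    if q.shape[0] != index.embedding_dim:
        raise ValueError(
            f"query dim {q.shape[0]} != index dim {index.embedding_dim}"
        )
    if abs(np.linalg.norm(q) - 1.0) > 1e-5:
        raise ValueError("query embedding must be unit-norm")
    if n_neighbors < 1:
        raise ValueError("n_neighbors must be >= 1")

    if index.backend == "exact":
        scores = index._vectors.astype(np.float64) @ q
        cand = np.arange(index.entries, dtype=np.int64)
        # pre-select by score alone (keeping every boundary tie) so the
        # tie-rule lexsort runs over a small candidate set
        need = n_neighbors
        if exclude_volume is not None:
            need += index._vol_counts.get(exclude_volume, 0)
        if index.entries > 2 * need + 64:
            part = np.argpartition(-scores, need)[:need]
            thr = scores[part].min()
            cand = np.where(scores >= thr)[0]
            scores = scores[cand]
        return _order_and_trim(index, cand, scores, n_neighbors, exclude_volume)

    # ANN: over-fetch so that exclusion cannot shorten the result, then
    # recompute exact scores for the candidate set.
    overfetch = n_neighbors
    if exclude_volume is not None:
        overfetch += index._vol_counts.get(exclude_volume, 0)
    overfetch = min(overfetch + int(index.params["search_breadth"]) // 4, index.entries)
    ids, _ = index._nnd.query(q[None, :].astype(np.float32), k=overfetch)
    cand = np.unique(ids[0].astype(np.int64))
    cand = cand[cand >= 0]
    scores = index._vectors[cand].astype(np.float64) @ q
    return _order_and_trim(index, cand, scores, n_neighbors, exclude_volume)


def save_index(index: SliceIndex, out_dir: str | Path) -> None:
    """Persist an index as ``vectors.npz`` plus an ``idmap.json`` sidecar.

    The ANN graph itself is not serialized; loading an ANN index rebuilds the
    graph deterministically from the stored vectors and params.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savez(
        out / "vectors.npz",
        vectors=index._vectors,
        slice_indices=index._slice_indices,
    )
    (out / "idmap.json").write_text(
        json.dumps(
            {
                "backend": index.backend,
                "params": index.params,
                "volume_ids": index._volume_ids,
            }
        )
    )


def load_index(in_dir: str | Path) -> SliceIndex:
    in_dir = Path(in_dir)
    meta = json.loads((in_dir / "idmap.json").read_text())
    data = np.load(in_dir / "vectors.npz")
    idx = SliceIndex(
        backend=meta["backend"],
        vectors=np.asarray(data["vectors"], dtype=np.float32),
        volume_ids=list(meta["volume_ids"]),
        slice_indices=np.asarray(data["slice_indices"], dtype=np.int64),
        params=meta["params"],
    )
    if idx.backend == "ann":
        idx._fit_ann()
    return idx
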