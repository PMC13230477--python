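"""Core domain types for volumetric retrieval cohorts.

A *cohort* is a collection of 3D image volumes, each represented not by its
pixels but by a stack of per-slice feature embeddings: volume ``V`` with ``n``
axial slices becomes an ``n x L`` matrix ``M_V`` whose rows are the
L2-normalized slice embeddings.  All similarity computations downstream
(slice search, hit-table aggregation, late-interaction re-ranking) are inner
products between such unit rows, which coincide with cosine similarity.

Volumes carry the metadata the retrieval tasks need: the organ the volume
was acquired for, whether that organ contains a tumor, the tumor stage
(S1..S4, or ``None`` for tumor-free volumes), and optionally a per-organ map
of which slice indices show each organ ("organ presence", standing in for
segmentation-derived slice selection).

Embeddings are produced outside this package by any feature extractor that
maps a 2D slice to a fixed-length vector (see :data:`SliceEmbedder` for the
adapter contract); the synthetic generator in :mod:`volcbir.synth` produces
cohorts with planted class structure for testing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterator, Mapping, Sequence

import h5py
import numpy as np

__all__ = [
    "STAGES",
    "SliceEmbedder",
    "VolumeRecord",
    "Cohort",
    "normalize_embedding",
    "build_embedding_matrix",
    "save_cohort",
    "load_cohort",
]

#: Valid tumor stages (T of TNM, derived from tumor size).  Tumor-free
#: volumes have ``stage is None``.
STAGES = ("S1", "S2", "S3", "S4")

#: Adapter contract for real feature extractors: a callable mapping one 2D
#: slice (any array-like the extractor understands) to a length-L 1D vector.
#: The package never calls this itself -- it documents how precomputed
#: embedding matrices are expected to have been produced.
SliceEmbedder = Callable[[np.ndarray], np.ndarray]

_NORM_ATOL = 1e-6


def normalize_embedding(v: np.ndarray | Sequence[float]) -> np.ndarray:
    """Return ``v / ||v||_2`` as a float32 unit vector.

    Raises
    ------
    ValueError
        If ``v`` is empty, contains non-finite entries, or is all zero.
    """
    arr = np.asarray(v, dtype=np.float64)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("embedding must be a non-empty 1D vector")
    if not np.all(np.isfinite(arr)):
        raise ValueError("embedding contains non-finite entries")
    norm = float(np.linalg.norm(arr))
    if norm == 0.0:
        raise ValueError("cannot normalize a zero embedding")
    out = (arr / norm).astype(np.float32)
    # second pass in float32 so the stored representation itself is unit-norm
    out /= np.float32(np.linalg.norm(out.astype(np.float64)))
    return out


def build_embedding_matrix(slices: Sequence[np.ndarray | Sequence[float]]) -> np.ndarray:
    """Stack per-slice embeddings into a row-normalized ``n x L`` matrix.

    Row ``i`` is ``normalize_embedding(slices[i])``; slice order is preserved.
    """
    if len(slices) == 0:
        raise ValueError("need at least one slice embedding")
    rows = [normalize_embedding(s) for s in slices]
    lengths = {r.shape[0] for r in rows}
    if len(lengths) > 1:
        raise ValueError(f"mixed embedding lengths: {sorted(lengths)}")
    return np.vstack(rows)


def _check_unit_rows(matrix: np.ndarray, who: str) -> None:
    norms = np.linalg.norm(matrix.astype(np.float64), axis=1)
    bad = np.where(np.abs(norms - 1.0) > _NORM_ATOL)[0]
    if bad.size:
        raise ValueError(f"{who}: rows {bad[:5].tolist()} are not unit-norm")


@dataclass
class VolumeRecord:
    """One volume: metadata plus its row-normalized slice-embedding matrix.

    Parameters
    ----------
    volume_id
        Unique identifier within a cohort.
    organ
        The organ/task this volume belongs to (e.g. ``"lung"``).
    tumor_flag
        Whether the volume's organ contains a tumor.
    stage
        Tumor stage in ``STAGES`` iff ``tumor_flag``; ``None`` otherwise.
    matrix
        ``n x L`` float32 matrix, rows unit-norm.
    organ_presence
        Optional map organ -> sorted array of slice indices where that organ
        appears.  Stands in for segmentation-derived slice selection; may
        include organs other than ``organ`` (a chest/abdomen volume shows
        several organs).
    """

    volume_id: str
    organ: str
    tumor_flag: bool
    stage: str | None
    matrix: np.ndarray
    organ_presence: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float32)
        if self.matrix.ndim != 2 or self.matrix.shape[0] == 0:
            raise ValueError(f"{self.volume_id}: matrix must be 2D with >=1 row")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError(f"{self.volume_id}: matrix has non-finite entries")
        _check_unit_rows(self.matrix, self.volume_id)
        if self.tumor_flag:
            if self.stage not in STAGES:
                raise ValueError(
                    f"{self.volume_id}: tumor-positive volume needs stage in {STAGES}, "
                    f"got {self.stage!r}"
                )
        elif self.stage is not None:
            raise ValueError(f"{self.volume_id}: tumor-free volume must have stage=None")
        cleaned: dict[str, np.ndarray] = {}
        for org, idx in self.organ_presence.items():
            idx = np.asarray(idx, dtype=np.int64)
            idx = np.unique(idx)
            if idx.size and (idx[0] < 0 or idx[-1] >= self.n_slices):
                raise ValueError(
                    f"{self.volume_id}: organ_presence[{org!r}] indices out of [0, {self.n_slices})"
                )
            cleaned[org] = idx
        self.organ_presence = cleaned

    @property
    def n_slices(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def embedding_dim(self) -> int:
        return int(self.matrix.shape[1])


@dataclass
class Cohort:
    """A collection of :class:`VolumeRecord` sharing one embedding dimension."""

    records: list[VolumeRecord]
    embedding_dim: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("cohort must contain at least one volume")
        ids = [r.volume_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate volume_id(s): {dupes}")
        for r in self.records:
            if r.embedding_dim != self.embedding_dim:
                raise ValueError(
                    f"{r.volume_id}: embedding dim {r.embedding_dim} != cohort {self.embedding_dim}"
                )
        self._by_id = {r.volume_id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[VolumeRecord]:
        return iter(self.records)

    def __contains__(self, volume_id: str) -> bool:
        return volume_id in self._by_id

    def __getitem__(self, volume_id: str) -> VolumeRecord:
        try:
            return self._by_id[volume_id]
        except KeyError:
            raise KeyError(f"unknown volume_id {volume_id!r}") from None

    @property
    def volume_ids(self) -> list[str]:
        return [r.volume_id for r in self.records]

    @property
    def total_slices(self) -> int:
        return sum(r.n_slices for r in self.records)

    def subset(self, volume_ids: Sequence[str]) -> "Cohort":
        """New cohort restricted to ``volume_ids`` (order follows the argument)."""
        return Cohort(
            records=[self[v] for v in volume_ids],
            embedding_dim=self.embedding_dim,
            provenance=dict(self.provenance),
        )


def _manifest_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json") if path.suffix != ".json" else path


def save_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort to one HDF5 file plus a sidecar JSON manifest.

    Layout: one HDF5 group per volume (named by ``volume_id``) holding the
    float32 dataset ``embeddings`` (n x L) with attributes ``organ``,
    ``tumor_flag``, ``stage`` ("NONE" for tumor-free) and ``order`` (position
    in the cohort), plus one int dataset ``organ_presence/<organ>`` per
    recorded organ.  The manifest ``<path>.json`` records ``embedding_dim``,
    ``n_volumes`` and the provenance map.  Round-trips are bit-exact.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.attrs["embedding_dim"] = cohort.embedding_dim
        for order, rec in enumerate(cohort.records):
            g = f.create_group(rec.volume_id)
            g.create_dataset("embeddings", data=rec.matrix, dtype="float32")
            g.attrs["organ"] = rec.organ
            g.attrs["tumor_flag"] = bool(rec.tumor_flag)
            g.attrs["stage"] = rec.stage if rec.stage is not None else "NONE"
            g.attrs["order"] = order
            if rec.organ_presence:
                op = g.create_group("organ_presence")
                for org, idx in rec.organ_presence.items():
                    op.create_dataset(org, data=np.asarray(idx, dtype=np.int64))
    manifest = {
        "format": "volcbir-cohort-v1",
        "embedding_dim": cohort.embedding_dim,
        "n_volumes": len(cohort),
        "provenance": cohort.provenance,
    }
    _manifest_path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))


def load_cohort(path: str | Path) -> Cohort:
    """Load a cohort written by :func:`save_cohort`.

    Raises
    ------
    ValueError
        Naming the offending ``volume_id`` if a stored matrix has the wrong
        embedding dimension, bad norms, or inconsistent metadata.
    """
    path = Path(path)
    manifest_file = _manifest_path(path)
    provenance: dict = {}
    expected_dim: int | None = None
    if manifest_file.exists():
        manifest = json.loads(manifest_file.read_text())
        provenance = manifest.get("provenance", {})
        expected_dim = manifest.get("embedding_dim")
    records: list[tuple[int, VolumeRecord]] = []
    with h5py.File(path, "r") as f:
        dim = int(f.attrs.get("embedding_dim", expected_dim or 0))
        if expected_dim is not None and dim != expected_dim:
            raise ValueError(
                f"embedding_dim mismatch: file says {dim}, manifest says {expected_dim}"
            )
        for volume_id, g in f.items():
            matrix = np.asarray(g["embeddings"], dtype=np.float32)
            if matrix.ndim != 2 or matrix.shape[1] != dim:
                raise ValueError(
                    f"{volume_id}: embeddings shape {matrix.shape} incompatible with L={dim}"
                )
            stage = str(g.attrs["stage"])
            presence: dict[str, np.ndarray] = {}
            if "organ_presence" in g:
                for org, ds in g["organ_presence"].items():
                    presence[org] = np.asarray(ds, dtype=np.int64)
            try:
                rec = VolumeRecord(
                    volume_id=str(volume_id),
                    organ=str(g.attrs["organ"]),
                    tumor_flag=bool(g.attrs["tumor_flag"]),
                    stage=None if stage == "NONE" else stage,
                    matrix=matrix,
                    organ_presence=presence,
                )
            except ValueError as exc:
                raise ValueError(f"malformed volume {volume_id!r}: {exc}") from exc
            records.append((int(g.attrs.get("order", len(records))), rec))
    records.sort(key=lambda t: t[0])
    return Cohort(
        records=[r for _, r in records],
        embedding_dim=dim,
        provenance=provenance,
    )
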