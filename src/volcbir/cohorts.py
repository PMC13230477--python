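"""Query/database split construction.

Three database configurations are supported, mirroring how a retrieval
archive might be organised:

``organ_specific_seg``
    One database per target organ, restricted to volumes containing that
    organ, with the searchable slices further limited to the slices that
    actually show the organ (segmentation-derived slice selection).
``organ_specific_noseg``
    Same volumes, but all slices searchable (no segmentation assumed).
``organ_agnostic``
    One pooled database over every organ, all slices searchable -- the
    heterogeneous-PACS scenario.

Query sampling is stage-stratified: per stage a fraction ``p_query``
(default 25%) of the tumor-positive volumes of the target organ is drawn
(round half up, at least one per non-empty stratum), and an equal number of
tumor-free-in-that-organ volumes is drawn as negatives, preferentially from
other organs' tasks (a liver-task volume whose lungs are healthy is a valid
lung-negative).  Draws are without replacement within one seed; across
seeds draws are independent, so different repetitions may overlap.  All
remaining volumes form the database.  Splits are at the volume level: no
volume ever contributes slices to both sides, and the query set is identical
between the seg and noseg configurations for the same seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datamodel import STAGES, Cohort

__all__ = [
    "SPLIT_CONFIGS",
    "SplitSpec",
    "Split",
    "sample_query_set",
    "apply_database_config",
    "build_agnostic_split",
    "build_split",
    "save_split",
    "load_split",
]

SPLIT_CONFIGS = ("organ_specific_seg", "organ_specific_noseg", "organ_agnostic")


@dataclass(frozen=True)
class SplitSpec:
    """Parameters of one query/database split."""

    config: str
    organ: str = "ALL"
    p_query: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.config not in SPLIT_CONFIGS:
            raise ValueError(f"unknown config {self.config!r}; expected {SPLIT_CONFIGS}")
        if not 0.0 < self.p_query < 1.0:
            raise ValueError("p_query must be in (0, 1)")
        if self.config == "organ_agnostic" and self.organ != "ALL":
            raise ValueError("organ_agnostic splits use organ='ALL'")
        if self.config != "organ_agnostic" and self.organ == "ALL":
            raise ValueError("organ-specific splits need a concrete organ")


@dataclass
class Split:
    """A volume-level query/database partition plus searchable slice masks.

    ``query_targets`` maps each query volume to the organ whose tumor status
    that query probes (a negative lung query drawn from a liver-task volume
    has target ``lung``).  ``slice_masks`` maps database volumes to the slice
    indices the index may search; volumes absent from the map expose all
    slices.
    """

    spec: SplitSpec
    query_ids: list[str]
    database_ids: list[str]
    query_targets: dict[str, str]
    slice_masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.query_ids) & set(self.database_ids)
        if overlap:
            raise ValueError(f"query/database sets overlap: {sorted(overlap)[:5]}")


def _contains_organ(rec, organ: str) -> bool:
    if rec.organ == organ:
        return True
    return organ in rec.organ_presence and rec.organ_presence[organ].size > 0


def _stratum_size_to_draw(n: int, p: float) -> int:
    """Round-half-up count, at least 1 for a non-empty stratum."""
    if n == 0:
        return 0
    return max(1, int(np.floor(n * p + 0.5)))


def sample_query_set(cohort: Cohort, spec: SplitSpec) -> Split:
    """Stage-stratified query sampling for one target organ.

    Positives: per stage, ``p_query`` of the tumor-positive volumes of
    ``spec.organ``.  Negatives: the same total number of volumes that contain
    the organ tumor-free.  Everything else containing the organ goes to the
    database side (masks applied later by :func:`apply_database_config`).
    """
    organ = spec.organ
    rng = np.random.default_rng(spec.seed)
    universe = [r for r in cohort if _contains_organ(r, organ)]
    positives = {s: [r.volume_id for r in universe if r.organ == organ and r.tumor_flag and r.stage == s] for s in STAGES}
    if not any(positives.values()):
        raise ValueError(f"no tumor-positive {organ} volumes in cohort")

    query_pos: list[str] = []
    for stage in STAGES:
        pool = sorted(positives[stage])
        n_draw = _stratum_size_to_draw(len(pool), spec.p_query)
        if n_draw:
            query_pos.extend(rng.choice(pool, size=n_draw, replace=False).tolist())

    neg_pool = sorted(
        r.volume_id
        for r in universe
        if not (r.organ == organ and r.tumor_flag) and r.volume_id not in query_pos
    )
    # prefer cross-task negatives (other organs' volumes with a healthy
    # target organ); fall back to same-organ tumor-free volumes
    cross = [v for v in neg_pool if cohort[v].organ != organ]
    same = [v for v in neg_pool if cohort[v].organ == organ]
    n_neg = len(query_pos)
    if len(neg_pool) < n_neg:
        raise ValueError(
            f"not enough {organ}-containing tumor-free volumes for negatives: "
            f"need {n_neg}, have {len(neg_pool)} (deficit {n_neg - len(neg_pool)})"
        )
    take_cross = min(n_neg, len(cross))
    query_neg = rng.choice(cross, size=take_cross, replace=False).tolist()
    if take_cross < n_neg:
        query_neg.extend(rng.choice(same, size=n_neg - take_cross, replace=False).tolist())

    query_ids = query_pos + query_neg
    database_ids = [r.volume_id for r in universe if r.volume_id not in set(query_ids)]
    return Split(
        spec=spec,
        query_ids=query_ids,
        database_ids=database_ids,
        query_targets={v: organ for v in query_ids},
    )


def apply_database_config(split: Split, cohort: Cohort, spec: SplitSpec) -> Split:
    """Attach searchable slice masks according to the database configuration.

    ``organ_specific_seg`` restricts every database volume to the slices
    showing the target organ (requires organ presence on all of them); the
    other configurations leave all slices searchable.  Query volumes are
    never masked -- the query set is identical across configurations.
    """
    if spec.config != "organ_specific_seg":
        split.slice_masks = {}
        return split
    masks: dict[str, np.ndarray] = {}
    missing = []
    for vid in split.database_ids:
        rec = cohort[vid]
        idx = rec.organ_presence.get(spec.organ)
        if idx is None:
            missing.append(vid)
        else:
            masks[vid] = idx
    if missing:
        raise ValueError(
            f"organ_specific_seg needs organ_presence[{spec.organ!r}] on every "
            f"database volume; missing for {missing[:5]}"
        )
    split.slice_masks = masks
    return split


def build_agnostic_split(cohort: Cohort, spec: SplitSpec) -> Split:
    """Pool per-organ query samples into one query set over one database.

    Per organ the sampling rule of :func:`sample_query_set` is applied
    (volumes already claimed by an earlier organ are skipped); all remaining
    volumes form a single unified database with every slice searchable.
    """
    organs = sorted({r.organ for r in cohort})
    rng = np.random.default_rng(spec.seed)
    taken: set[str] = set()
    query_ids: list[str] = []
    targets: dict[str, str] = {}
    for organ in organs:
        universe = [r for r in cohort if _contains_organ(r, organ)]
        query_pos: list[str] = []
        for stage in STAGES:
            pool = sorted(
                r.volume_id
                for r in universe
                if r.organ == organ and r.tumor_flag and r.stage == stage
                and r.volume_id not in taken
            )
            n_draw = _stratum_size_to_draw(len(pool), spec.p_query)
            if n_draw:
                query_pos.extend(rng.choice(pool, size=n_draw, replace=False).tolist())
        neg_pool = sorted(
            r.volume_id
            for r in universe
            if not (r.organ == organ and r.tumor_flag)
            and r.volume_id not in taken
            and r.volume_id not in query_pos
        )
        if len(neg_pool) < len(query_pos):
            raise ValueError(
                f"not enough tumor-free {organ}-containing volumes: need "
                f"{len(query_pos)}, have {len(neg_pool)}"
            )
        query_neg = rng.choice(neg_pool, size=len(query_pos), replace=False).tolist()
        for v in query_pos + query_neg:
            targets[v] = organ
        query_ids.extend(query_pos + query_neg)
        taken.update(query_pos + query_neg)
    database_ids = [r.volume_id for r in cohort if r.volume_id not in taken]
    return Split(
        spec=spec,
        query_ids=query_ids,
        database_ids=database_ids,
        query_targets=targets,
    )


def build_split(cohort: Cohort, spec: SplitSpec) -> Split:
    """Build a split for any configuration (sampling + database masks)."""
    if spec.config == "organ_agnostic":
        return build_agnostic_split(cohort, spec)
    split = sample_query_set(cohort, spec)
    return apply_database_config(split, cohort, spec)


def save_split(split: Split, path: str | Path) -> None:
    """Write a split manifest as JSON."""
    payload = {
        "config": split.spec.config,
        "organ": split.spec.organ,
        "p_query": split.spec.p_query,
        "seed": split.spec.seed,
        "query_ids": split.query_ids,
        "database_ids": split.database_ids,
        "query_targets": split.query_targets,
        "slice_masks": {v: m.tolist() for v, m in split.slice_masks.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_split(path: str | Path) -> Split:
    d = json.loads(Path(path).read_text())
    spec = SplitSpec(
        config=d["config"], organ=d["organ"], p_query=d["p_query"], seed=d["seed"]
    )
    return Split(
        spec=spec,
        query_ids=list(d["query_ids"]),
        database_ids=list(d["database_ids"]),
        query_targets=dict(d["query_targets"]),
        slice_masks={v: np.asarray(m, dtype=np.int64) for v, m in d["slice_masks"].items()},
    )
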