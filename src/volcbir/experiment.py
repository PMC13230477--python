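"""End-to-end experiment orchestration.

Wires simulate -> split -> index -> retrieve -> re-rank -> evaluate ->
compare with one global seed.  The global seed fans out to per-stage seeds
(cohort generation, split sampling, ANN graph construction) through
:func:`derive_seed`, a documented SeedSequence-based derivation, so the
whole multi-repetition protocol is reproducible from a single integer.

The default protocol evaluates five methods per query -- the three
first-stage aggregations (count, max_score, sum_sim), their RRF fusion, and
C-MIR applied to the count-base top-M list -- over 10 seeded repetitions,
and compares C-MIR against each other method with paired Wilcoxon tests on
per-seed mean AP.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohorts import Split, SplitSpec, build_split
from .datamodel import Cohort, VolumeRecord
from .evaluation import compare_methods, run_experiment
from .index import SliceIndex, build_index
from .rerank import cmir_rerank, rrf_rerank
from .retrieval import (
    AGGREGATION_METHODS,
    RankedList,
    build_hit_table,
    retrieve_top_volumes,
)
from .synth import GeneratorConfig, generate_cohort

__all__ = [
    "ALL_METHODS",
    "RunConfig",
    "derive_seed",
    "rank_all_methods",
    "make_seed_setup_builder",
    "run_full_experiment",
]

ALL_METHODS = ("count", "max_score", "sum_sim", "rrf", "cmir")

_STAGE_CODES = {"cohort": 1, "split": 2, "index": 3}


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31.

    Spawns from ``SeedSequence([global_seed, stage_code])`` so stages draw
    independent streams while the whole run stays reproducible from one
    integer.
    """
    if stage not in _STAGE_CODES:
        raise ValueError(f"unknown stage {stage!r}; expected {sorted(_STAGE_CODES)}")
    ss = np.random.SeedSequence([int(global_seed), _STAGE_CODES[stage]])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full multi-seed retrieval experiment."""

    generator: GeneratorConfig = GeneratorConfig()
    split_config: str = "organ_agnostic"
    organ: str = "ALL"
    task: str = "flagging"
    methods: tuple[str, ...] = ALL_METHODS
    seeds: tuple[int, ...] = tuple(range(10))
    n_neighbors: int = 20  # slice hits per query slice
    M: int = 20  # candidates re-ranked / list depth
    k_smooth: int = 60  # RRF smoothing constant
    p_query: float = 0.25  # query fraction per stage stratum
    backend: str = "exact"
    cmir_first_stage: str = "count"

    def as_dict(self) -> dict:
        d = {
            "split_config": self.split_config,
            "organ": self.organ,
            "task": self.task,
            "methods": list(self.methods),
            "seeds": list(self.seeds),
            "n_neighbors": self.n_neighbors,
            "M": self.M,
            "k_smooth": self.k_smooth,
            "p_query": self.p_query,
            "backend": self.backend,
            "cmir_first_stage": self.cmir_first_stage,
        }
        from .synth import _config_dict

        d["generator"] = _config_dict(self.generator)
        return d


def rank_all_methods(
    query: VolumeRecord,
    index: SliceIndex,
    cohort: Cohort,
    methods: Sequence[str] = ALL_METHODS,
    n_neighbors: int = 20,
    M: int = 20,
    k_smooth: int = 60,
    cmir_first_stage: str = "count",
) -> dict[str, RankedList]:
    """Ranked lists for one query under each requested method.

    The hit table is built once; aggregations, RRF and C-MIR reuse it.
    C-MIR re-ranks the top-``M`` list of ``cmir_first_stage``.
    """
    unknown = set(methods) - set(ALL_METHODS)
    if unknown:
        raise ValueError(f"unknown method(s) {sorted(unknown)}; expected {ALL_METHODS}")
    ht = build_hit_table(query, index, n_neighbors)
    base = {m: retrieve_top_volumes(ht, m, k=M) for m in AGGREGATION_METHODS}
    out: dict[str, RankedList] = {}
    for m in methods:
        if m in AGGREGATION_METHODS:
            out[m] = base[m]
        elif m == "rrf":
            out[m] = rrf_rerank([base[a] for a in AGGREGATION_METHODS], k_smooth)
        elif m == "cmir":
            out[m] = cmir_rerank(query, base[cmir_first_stage], cohort, M=M)
    return out


def make_seed_setup_builder(config: RunConfig):
    """Return ``builder(seed) -> (cohort, split, index)`` for ``config``.

    Per seed: regenerate the cohort (cohort seed derived from the global
    seed so repetitions share the planted geometry only through the config),
    resample the split, and rebuild the index over the database side with
    the configuration's slice masks.
    """

    def builder(seed: int) -> tuple[Cohort, Split, SliceIndex]:
        cohort = generate_cohort(
            replace(config.generator, seed=derive_seed(seed, "cohort"))
        )
        spec = SplitSpec(
            config=config.split_config,
            organ=config.organ,
            p_query=config.p_query,
            seed=derive_seed(seed, "split"),
        )
        split = build_split(cohort, spec)
        params = {"seed": derive_seed(seed, "index")} if config.backend == "ann" else None
        index = build_index(
            cohort,
            backend=config.backend,
            params=params,
            slice_masks=split.slice_masks,
            volume_ids=split.database_ids,
        )
        return cohort, split, index

    return builder


def run_full_experiment(
    config: RunConfig,
    out_dir: str | Path | None = None,
    baseline: str = "cmir",
) -> dict[str, pd.DataFrame]:
    """Run the full grid (seeds x methods) and the method comparisons.

    Returns ``{"per_query", "per_seed", "comparisons"}`` tables; if
    ``out_dir`` is given they are also written as ``results.csv`` (per-seed
    means), ``per_query.csv`` and ``comparisons.csv``, with the config echoed
    to ``config.json`` for provenance.
    """
    builder = make_seed_setup_builder(config)
    per_query, per_seed = run_experiment(
        builder,
        methods=config.methods,
        seeds=config.seeds,
        task=config.task,
        n_neighbors=config.n_neighbors,
        M=config.M,
        k_smooth=config.k_smooth,
        cmir_first_stage=config.cmir_first_stage,
    )
    comparisons = (
        compare_methods(per_seed, baseline=baseline)
        if baseline in config.methods and len(config.seeds) >= 2
        else pd.DataFrame()
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        per_seed.to_csv(out / "results.csv", index=False)
        per_query.to_csv(out / "per_query.csv", index=False)
        comparisons.to_csv(out / "comparisons.csv", index=False)
        import json

        (out / "config.json").write_text(json.dumps(config.as_dict(), indent=2))
    return {"per_query": per_query, "per_seed": per_seed, "comparisons": comparisons}
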