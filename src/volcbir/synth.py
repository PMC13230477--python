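"""Synthetic embedding cohorts with planted organ/stage structure.

Real slice embeddings are not simulated at the pixel level; instead the
generator plants the *statistical* structure the retrieval pipeline is
sensitive to, directly in embedding space:

* every organ has a random unit *organ axis* ``a_o``, a *tumor axis*
  ``u_o`` shared by that organ's tumor stages, and per-stage axes
  ``v_{o,s}``;
* a volume of organ ``o`` and class ``c`` (tumor-free, or stage S1..S4)
  carries the class signal ``a_o`` (tumor-free) or
  ``a_o + u_o + stage_spread * v_{o,s}`` (stage ``s``) on the contiguous
  slab of slices where the organ appears;
* each volume additionally shows a few *other* organs (healthy) on their
  own slabs, the way a CT volume acquired for a liver task still contains
  lungs -- this is what makes cross-task negatives possible;
* slice ``t``'s embedding is ``normalize(separation * signal_t + d_t)``
  where ``d_t = drift * d_{t-1} + noise_t`` is an AR(1) deviation giving
  adjacent slices the slice-to-slice correlation real volumes have.

``separation`` scales signal against noise: at 0 the embeddings are pure
isotropic noise (every class, and every organ, indistinguishable -- retrieval
is at chance), and as it grows volumes of the same class concentrate around
their class direction.  Tumor stages of one organ stay mutually closer than
different organs (they share ``a_o + u_o``), mirroring the real task where
stage confusion is harder than organ confusion.  Slice counts vary uniformly
within ``slice_count_range``.  Everything is deterministic under ``seed``.

Not emulated: pixel content, physical tumor size (the real signal behind
staging), scanner effects, or any particular extractor's embedding geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .datamodel import STAGES, Cohort, VolumeRecord

__all__ = [
    "GeneratorConfig",
    "DESK_PRESET",
    "high_separation",
    "zero_separation",
    "generate_cohort",
    "plant_copy",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic cohort generator.

    Attributes
    ----------
    embedding_dim
        Length L of every slice embedding (unitless).
    organs
        Organ labels; one "task" per organ.
    stages_per_organ
        Number of tumor stages (uses the first ``stages_per_organ`` of
        S1..S4).
    volumes_per_class
        Volumes per (organ, class) cell, classes being tumor-free plus each
        stage.
    slice_count_range
        Inclusive (min, max) of per-volume slice counts, drawn uniformly.
    separation
        Signal amplitude relative to unit noise; 0 means no class signal.
    stage_spread
        Amplitude of the per-stage axes *relative to the noise floor*
        (< 1 keeps stage separation below within-class slice variability at
        every separation level, so stages perturb rather than fragment an
        organ's tumor cluster -- tumor flagging saturates while staging
        stays intrinsically harder, the ordering real cohorts show).
    within_volume_drift
        AR(1) coefficient of the slice-to-slice deviation process, in [0, 1).
    noise
        Standard deviation of the isotropic per-slice noise.
    organ_span_fraction
        Fraction of a volume's slices covered by each organ's contiguous
        slab.
    secondary_organs
        How many additional (healthy) organs each volume shows.
    seed
        Generator seed; identical configs give bit-identical cohorts.
    """

    embedding_dim: int = 64
    organs: tuple[str, ...] = ("colon", "liver", "lung", "pancreas")
    stages_per_organ: int = 4
    volumes_per_class: int = 6
    slice_count_range: tuple[int, int] = (20, 60)
    separation: float = 1.5
    stage_spread: float = 0.5
    within_volume_drift: float = 0.3
    noise: float = 0.2
    organ_span_fraction: float = 0.75
    secondary_organs: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.slice_count_range
        if not (1 <= lo <= hi):
            raise ValueError("slice_count_range must satisfy 1 <= min <= max")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")
        if not 0.0 <= self.within_volume_drift < 1.0:
            raise ValueError("within_volume_drift must be in [0, 1)")
        if self.noise <= 0:
            raise ValueError("noise must be > 0")
        if not 0.0 < self.organ_span_fraction <= 1.0:
            raise ValueError("organ_span_fraction must be in (0, 1]")
        if not 1 <= self.stages_per_organ <= len(STAGES):
            raise ValueError(f"stages_per_organ must be in [1, {len(STAGES)}]")
        if not 0 <= self.secondary_organs < len(self.organs):
            raise ValueError("secondary_organs must be < number of organs")
        if self.volumes_per_class < 1 or self.embedding_dim < 2:
            raise ValueError("volumes_per_class >= 1 and embedding_dim >= 2 required")


#: Desk-scale default: 4 organs x (4 stages + tumor-free) x 6 volumes,
#: 20-60 slices each -- a few thousand slices, large enough for retrieval
#: statistics yet fast on one CPU.  Archive-scale cohorts (1e5 slices) are
#: configured, not a different code path.
DESK_PRESET = GeneratorConfig()


def high_separation(config: GeneratorConfig = DESK_PRESET) -> GeneratorConfig:
    """A strongly separated variant: planted classes are near-recoverable.

    ``separation=6`` with ``noise=0.05`` puts same-class slice cosines near 1
    while cross-class cosines stay well below (tumor vs tumor-free of one
    organ ~ 0.67, different organs ~ 0), so flagging should approach perfect
    precision.
    """
    return replace(config, separation=6.0, noise=0.05)


def zero_separation(config: GeneratorConfig = DESK_PRESET) -> GeneratorConfig:
    """No planted signal at all: retrieval can only perform at chance."""
    return replace(config, separation=0.0)


def _class_signal(
    axes: dict, organ: str, tumor_flag: bool, stage: str | None, stage_amp: float
) -> np.ndarray:
    sig = axes[("organ", organ)].copy()
    if tumor_flag:
        sig += axes[("tumor", organ)] + stage_amp * axes[("stage", organ, stage)]
    return sig


def generate_cohort(config: GeneratorConfig = DESK_PRESET) -> Cohort:
    """Generate a cohort with planted organ/stage structure.

    Volume ids are ``"{organ}-{class}-{i:03d}"`` with class ``neg`` or the
    stage label.  ``organ_presence`` records the slab of every organ shown
    (primary and secondary), so segmentation-restricted databases can be
    built from synthetic cohorts.
    """
    rng = np.random.default_rng(config.seed)
    L = config.embedding_dim
    stages = STAGES[: config.stages_per_organ]

    # mutually orthonormal axes (random rotation of a canonical frame): one
    # organ axis, one tumor axis and one axis per stage, per organ.  Exact
    # orthogonality keeps cross-organ signal leakage at the noise level,
    # which iid random directions (cosines ~ 1/sqrt(L)) would not.
    keys = []
    for organ in config.organs:
        keys.append(("organ", organ))
        keys.append(("tumor", organ))
        keys.extend(("stage", organ, s) for s in stages)
    if len(keys) > L:
        raise ValueError(
            f"embedding_dim={L} too small for {len(keys)} orthonormal class axes"
        )
    basis, _ = np.linalg.qr(rng.standard_normal((L, len(keys))))
    axes: dict = {k: basis[:, i] for i, k in enumerate(keys)}

    lo, hi = config.slice_count_range
    # stage axes stay sub-noise: after the overall `separation` scaling their
    # amplitude is separation/(1+separation) * stage_spread * noise, i.e. a
    # fraction stage_spread of the slice noise even as separation grows
    stage_amp = (
        config.stage_spread
        * config.noise
        * config.separation
        / ((1.0 + config.separation) * max(config.separation, 1e-12))
    )
    records: list[VolumeRecord] = []
    for organ in config.organs:
        others = [o for o in config.organs if o != organ]
        for cls in ("neg", *stages):
            tumor_flag = cls != "neg"
            stage = cls if tumor_flag else None
            for i in range(config.volumes_per_class):
                n = int(rng.integers(lo, hi + 1))
                sec = list(
                    rng.choice(others, size=config.secondary_organs, replace=False)
                ) if config.secondary_organs else []
                # disjoint contiguous slab per shown organ, stacked in the
                # fixed anatomical order of config.organs (axial CT shows
                # different organs at different slice ranges); the primary
                # organ gets organ_span_fraction of the volume, secondary
                # organs share the remainder, leftovers are background
                shown = sorted([organ, *sec], key=config.organs.index)
                p_len = max(1, int(round(config.organ_span_fraction * n)))
                p_len = min(p_len, n - len(sec))  # keep >=1 slice per secondary
                rest = n - p_len
                s_len = rest // max(1, len(sec)) if sec else 0
                spans: dict[str, np.ndarray] = {}
                signal = np.zeros((n, L))
                start = 0
                for org in shown:
                    length = p_len if org == organ else s_len
                    idx = np.arange(start, start + length)
                    start += length
                    spans[org] = idx
                    if org == organ:
                        sig = _class_signal(axes, org, tumor_flag, stage, stage_amp)
                    else:
                        sig = _class_signal(axes, org, False, None, stage_amp)
                    signal[idx] += sig
                # AR(1) deviation, stationary-initialized
                eps = rng.standard_normal((n, L)) * (config.noise / np.sqrt(L))
                rho = config.within_volume_drift
                dev = np.empty((n, L))
                dev[0] = eps[0] / np.sqrt(1.0 - rho**2)
                for t in range(1, n):
                    dev[t] = rho * dev[t - 1] + eps[t]
                raw = config.separation * signal + dev
                norms = np.linalg.norm(raw, axis=1, keepdims=True)
                matrix = (raw / norms).astype(np.float32)
                matrix /= np.linalg.norm(
                    matrix.astype(np.float64), axis=1, keepdims=True
                ).astype(np.float32)
                records.append(
                    VolumeRecord(
                        volume_id=f"{organ}-{cls}-{i:03d}",
                        organ=organ,
                        tumor_flag=tumor_flag,
                        stage=stage,
                        matrix=matrix,
                        organ_presence=spans,
                    )
                )
    provenance = {"generator": "volcbir.synth.generate_cohort", "config": _config_dict(config)}
    return Cohort(records=records, embedding_dim=L, provenance=provenance)


def _config_dict(config: GeneratorConfig) -> dict:
    return {
        "embedding_dim": config.embedding_dim,
        "organs": list(config.organs),
        "stages_per_organ": config.stages_per_organ,
        "volumes_per_class": config.volumes_per_class,
        "slice_count_range": list(config.slice_count_range),
        "separation": config.separation,
        "stage_spread": config.stage_spread,
        "within_volume_drift": config.within_volume_drift,
        "noise": config.noise,
        "organ_span_fraction": config.organ_span_fraction,
        "secondary_organs": config.secondary_organs,
        "seed": config.seed,
    }


def plant_copy(cohort: Cohort, volume_id: str, copy_id: str | None = None) -> Cohort:
    """Return a new cohort with an exact duplicate of ``volume_id`` appended.

    Test fixture for self-retrieval supremacy: the duplicate must come back
    first under every aggregation, and under C-MIR with rank score equal to
    the query's slice count.
    """
    src = cohort[volume_id]
    copy_id = copy_id or f"{volume_id}__copy"
    if copy_id in cohort:
        raise ValueError(f"copy id {copy_id!r} already present")
    dup = VolumeRecord(
        volume_id=copy_id,
        organ=src.organ,
        tumor_flag=src.tumor_flag,
        stage=src.stage,
        matrix=src.matrix.copy(),
        organ_presence={k: v.copy() for k, v in src.organ_presence.items()},
    )
    return Cohort(
        records=[*cohort.records, dup],
        embedding_dim=cohort.embedding_dim,
        provenance=dict(cohort.provenance),
    )
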