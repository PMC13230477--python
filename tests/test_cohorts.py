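import numpy as np
import pytest

from volcbir.cohorts import (
    SplitSpec,
    apply_database_config,
    build_agnostic_split,
    build_split,
    load_split,
    sample_query_set,
    save_split,
)
from volcbir.datamodel import Cohort
from volcbir.synth import GeneratorConfig, generate_cohort

from conftest import make_volume


def _labelled(organ, stage_counts, n_neg, others=()):
    """Cohort with given per-stage positive counts plus negatives.

    ``others`` adds cross-task volumes (their own organ tumor-positive) that
    contain ``organ`` on one slice.
    """
    recs = []
    for stage, n in stage_counts.items():
        for i in range(n):
            recs.append(
                make_volume(
                    f"{organ}-{stage}-{i}", [(1.0, 0.0)] * 2, organ=organ,
                    tumor_flag=True, stage=stage,
                    presence={organ: np.array([0, 1])},
                )
            )
    for i in range(n_neg):
        recs.append(
            make_volume(
                f"{organ}-neg-{i}", [(0.0, 1.0)] * 2, organ=organ,
                presence={organ: np.array([0, 1])},
            )
        )
    for k, other in enumerate(others):
        recs.append(
            make_volume(
                f"{other}-S1-x{k}", [(0.6, 0.8)] * 2, organ=other,
                tumor_flag=True, stage="S1",
                presence={other: np.array([0, 1]), organ: np.array([0])},
            )
        )
    return Cohort(records=recs, embedding_dim=2)


class TestSampling:
    def test_worked_stratum_arithmetic(self):
        # stages {S1:4, S2:4}, p=0.25 -> 1+1 positives, 2 negatives, 4 queries
        cohort = _labelled("lung", {"S1": 4, "S2": 4}, n_neg=4)
        split = sample_query_set(cohort, SplitSpec("organ_specific_noseg", "lung", 0.25, 0))
        pos = [v for v in split.query_ids if cohort[v].tumor_flag]
        neg = [v for v in split.query_ids if not cohort[v].tumor_flag]
        assert len(pos) == 2 and len(neg) == 2
        stages = {cohort[v].stage for v in pos}
        assert stages == {"S1", "S2"}
        assert len(split.database_ids) == 12 - 4

    def test_min_one_per_nonempty_stratum(self):
        # p * |S1| = 0.5 -> still 1 positive drawn
        cohort = _labelled("lung", {"S1": 2}, n_neg=2)
        split = sample_query_set(cohort, SplitSpec("organ_specific_noseg", "lung", 0.25, 0))
        assert sum(cohort[v].tumor_flag for v in split.query_ids) == 1

    def test_balanced_and_disjoint(self):
        cohort = _labelled("lung", {"S1": 8, "S3": 4}, n_neg=8, others=("liver",) * 3)
        split = sample_query_set(cohort, SplitSpec("organ_specific_noseg", "lung", 0.25, 1))
        pos = [v for v in split.query_ids if cohort[v].organ == "lung" and cohort[v].tumor_flag]
        neg = [v for v in split.query_ids if v not in pos]
        assert len(pos) == len(neg)
        assert not set(split.query_ids) & set(split.database_ids)
        assert all(not cohort[v].tumor_flag or cohort[v].organ != "lung" for v in neg)

    def test_cross_task_negatives_preferred(self):
        cohort = _labelled("lung", {"S1": 4}, n_neg=4, others=("liver", "colon", "liver"))
        split = sample_query_set(cohort, SplitSpec("organ_specific_noseg", "lung", 0.25, 5))
        negs = [v for v in split.query_ids if not (cohort[v].organ == "lung" and cohort[v].tumor_flag)]
        assert all(cohort[v].organ != "lung" for v in negs)

    def test_insufficient_negatives_names_deficit(self):
        cohort = _labelled("lung", {"S1": 8, "S2": 8}, n_neg=1)
        with pytest.raises(ValueError, match="deficit"):
            sample_query_set(cohort, SplitSpec("organ_specific_noseg", "lung", 0.25, 0))

    def test_seeded_determinism_and_independent_draws(self):
        cohort = _labelled("lung", {"S1": 8, "S2": 8}, n_neg=8)
        spec = SplitSpec("organ_specific_noseg", "lung", 0.25, 42)
        a = sample_query_set(cohort, spec)
        b = sample_query_set(cohort, spec)
        assert a.query_ids == b.query_ids
        c = sample_query_set(cohort, SplitSpec("organ_specific_noseg", "lung", 0.25, 43))
        assert set(c.query_ids) != set()  # different seed: independent draw
        # within one seed no volume is drawn twice
        assert len(set(a.query_ids)) == len(a.query_ids)


class TestDatabaseConfig:
    @pytest.fixture
    def synth(self):
        return generate_cohort(
            GeneratorConfig(volumes_per_class=2, slice_count_range=(8, 12), seed=4)
        )

    def test_seg_masks_match_presence(self, synth):
        spec = SplitSpec("organ_specific_seg", "lung", 0.25, 0)
        split = apply_database_config(sample_query_set(synth, spec), synth, spec)
        assert set(split.slice_masks) == set(split.database_ids)
        for vid, mask in split.slice_masks.items():
            np.testing.assert_array_equal(mask, synth[vid].organ_presence["lung"])

    def test_noseg_has_no_masks(self, synth):
        spec = SplitSpec("organ_specific_noseg", "lung", 0.25, 0)
        split = build_split(synth, spec)
        assert split.slice_masks == {}

    def test_query_set_identical_between_seg_and_noseg(self, synth):
        seg = build_split(synth, SplitSpec("organ_specific_seg", "lung", 0.25, 3))
        noseg = build_split(synth, SplitSpec("organ_specific_noseg", "lung", 0.25, 3))
        assert seg.query_ids == noseg.query_ids
        assert seg.database_ids == noseg.database_ids

    def test_seg_vs_noseg_entry_counts_differ_by_masked_slices(self, synth):
        from volcbir.index import build_index

        seg = build_split(synth, SplitSpec("organ_specific_seg", "lung", 0.25, 3))
        noseg = build_split(synth, SplitSpec("organ_specific_noseg", "lung", 0.25, 3))
        i_seg = build_index(synth, slice_masks=seg.slice_masks, volume_ids=seg.database_ids)
        i_noseg = build_index(synth, volume_ids=noseg.database_ids)
        masked_out = sum(
            synth[v].n_slices - seg.slice_masks[v].size for v in seg.database_ids
        )
        assert i_noseg.entries - i_seg.entries == masked_out

    def test_missing_presence_rejected(self):
        cohort = _labelled("lung", {"S1": 4}, n_neg=4)
        # strip presence from one database volume
        for rec in cohort.records:
            rec.organ_presence = {}
        spec = SplitSpec("organ_specific_seg", "lung", 0.25, 0)
        split = sample_query_set(cohort, spec)
        with pytest.raises(ValueError, match="organ_presence"):
            apply_database_config(split, cohort, spec)


class TestAgnostic:
    @pytest.fixture
    def synth(self):
        return generate_cohort(
            GeneratorConfig(volumes_per_class=4, slice_count_range=(6, 10), seed=8)
        )

    def test_single_pool_and_conservation(self, synth):
        split = build_split(synth, SplitSpec("organ_agnostic", seed=0))
        per_organ = {}
        for v in split.query_ids:
            per_organ[split.query_targets[v]] = per_organ.get(split.query_targets[v], 0) + 1
        assert sum(per_organ.values()) == len(split.query_ids)
        assert set(per_organ) == {"colon", "liver", "lung", "pancreas"}
        assert len(split.query_ids) + len(split.database_ids) == len(synth)
        assert split.slice_masks == {}

    def test_balanced_per_organ(self, synth):
        split = build_split(synth, SplitSpec("organ_agnostic", seed=1))
        for organ in ("colon", "liver", "lung", "pancreas"):
            q = [v for v, t in split.query_targets.items() if t == organ]
            pos = [v for v in q if synth[v].organ == organ and synth[v].tumor_flag]
            assert len(pos) == len(q) - len(pos)

    def test_seeded_rebuild_identical(self, synth):
        a = build_split(synth, SplitSpec("organ_agnostic", seed=5))
        b = build_split(synth, SplitSpec("organ_agnostic", seed=5))
        assert a.query_ids == b.query_ids and a.database_ids == b.database_ids


class TestSpecAndManifest:
    def test_spec_validation(self):
        with pytest.raises(ValueError):
            SplitSpec("organ_specific_seg", "ALL")
        with pytest.raises(ValueError):
            SplitSpec("organ_agnostic", "lung")
        with pytest.raises(ValueError):
            SplitSpec("organ_agnostic", p_query=1.5)
        with pytest.raises(ValueError):
            SplitSpec("bogus")

    def test_manifest_round_trip(self, tmp_path):
        synth = generate_cohort(
            GeneratorConfig(volumes_per_class=2, slice_count_range=(5, 8), seed=1)
        )
        split = build_split(synth, SplitSpec("organ_specific_seg", "liver", 0.25, 2))
        save_split(split, tmp_path / "split.json")
        back = load_split(tmp_path / "split.json")
        assert back.query_ids == split.query_ids
        assert back.database_ids == split.database_ids
        assert back.query_targets == split.query_targets
        assert set(back.slice_masks) == set(split.slice_masks)
        for v in split.slice_masks:
            np.testing.assert_array_equal(back.slice_masks[v], split.slice_masks[v])
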