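import numpy as np
import pytest

from volcbir.datamodel import Cohort, VolumeRecord, build_embedding_matrix


def make_volume(volume_id, rows, organ="lung", tumor_flag=False, stage=None, presence=None):
    return VolumeRecord(
        volume_id=volume_id,
        organ=organ,
        tumor_flag=tumor_flag,
        stage=stage,
        matrix=build_embedding_matrix(rows),
        organ_presence=presence or {},
    )


@pytest.fixture
def f1_cohort():
    """Hand-checkable 2D fixture: query Q and candidates A, B.

    SIM(Q, A) = [[1, 0.6], [0, 0.8]]  -> RS(A) = 1.0 + 0.8 = 1.8
    SIM(Q, B) = [[0.6, 0], [0.8, 1]]  -> RS(B) = 0.6 + 1.0 = 1.6
    """
    q = make_volume("Q", [(1.0, 0.0), (0.0, 1.0)])
    a = make_volume("A", [(1.0, 0.0), (0.6, 0.8)])
    b = make_volume("B", [(0.6, 0.8), (0.0, 1.0)])
    return Cohort(records=[q, a, b], embedding_dim=2)


@pytest.fixture
def toy_index_cohort():
    """Three single-slice 2D volumes spanning {(1,0), (0,1), (0.6,0.8)}."""
    return Cohort(
        records=[
            make_volume("va", [(1.0, 0.0)]),
            make_volume("vb", [(0.0, 1.0)]),
            make_volume("vc", [(0.6, 0.8)]),
        ],
        embedding_dim=2,
    )


def random_unit_rows(rng, n, L):
    m = rng.standard_normal((n, L))
    m /= np.linalg.norm(m, axis=1, keepdims=True)
    return m
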