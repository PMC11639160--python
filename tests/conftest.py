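import numpy as np
import pytest

from diffreg.ec_data import (
    BULK,
    SINGLE_CELL,
    ECDataset,
    EquivalenceClass,
    FeatureIndex,
    SpliceStatus,
    merge_classes,
)

S, U, A = SpliceStatus.S, SpliceStatus.U, SpliceStatus.A


def make_bulk_index(n: int, lengths=None) -> FeatureIndex:
    ids = tuple(f"T{i}" for i in range(n))
    if lengths is None:
        l_s = np.full(n, 1000.0)
        l_u = np.full(n, 1500.0)
    else:
        l_s, l_u = lengths
    return FeatureIndex(ids, BULK, np.asarray(l_s, float), np.asarray(l_u, float))


def make_sc_index(n: int) -> FeatureIndex:
    return FeatureIndex(tuple(f"G{i}" for i in range(n)), SINGLE_CELL)


def singleton_dataset(counts: np.ndarray, index: FeatureIndex, groups=None) -> ECDataset:
    """Dataset of singleton ECs from an (n_samples, F, K) count array."""
    counts = np.asarray(counts)
    classes = []
    for i in range(counts.shape[0]):
        ecs = [
            EquivalenceClass(((int(f), SpliceStatus(int(k))),), int(counts[i, f, k]))
            for f, k in zip(*np.nonzero(counts[i]))
        ]
        classes.append(merge_classes(ecs))
    sample_ids = [f"s{i}" for i in range(counts.shape[0])]
    ds = ECDataset(index, sample_ids, classes)
    if groups is not None:
        ds.group_labels = list(groups)
    return ds


@pytest.fixture
def bulk_index():
    return make_bulk_index(3)


@pytest.fixture
def sc_index():
    return make_sc_index(3)
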