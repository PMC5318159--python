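import numpy as np
import pytest

from orfstruct import simulate as sim


@pytest.fixture(scope="session")
def small_bundle():
    """Mid-sized simulated dataset shared by read-only tests."""
    return sim.make_dataset(
        seed=11, n_operons=20, paired_fraction=(0.1, 0.7),
        dms_depth=30.0, break_fraction=0.2, n_dms_replicates=2,
    )


@pytest.fixture(scope="session")
def tiny_annotation():
    return sim.make_genome(4, orfs_per_operon=(2, 3), seed=5)


def gini_pairwise(values: np.ndarray) -> float:
    """Independent Gini oracle: mean absolute difference / (2 * mean)."""
    v = np.asarray(values, dtype=float)
    n = v.size
    diff = np.abs(v[:, None] - v[None, :]).sum()
    return diff / (2.0 * n * n * v.mean())
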