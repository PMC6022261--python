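import numpy as np
import pytest

from epimodule import MeripCountSet


@pytest.fixture
def small_counts() -> MeripCountSet:
    """4 sites x 3 samples with hand-typed counts and unit-friendly totals."""
    return MeripCountSet(
        site_ids=["s1", "s2", "s3", "s4"],
        gene_ids=["gA", "gA", "gB", "gC"],
        samples=["c1", "c2", "c3"],
        t=np.array([[10, 0, 5], [3, 4, 1], [100, 50, 20], [0, 0, 0]]),
        c=np.array([[10, 7, 5], [1, 6, 3], [0, 50, 60], [0, 2, 0]]),
    )


@pytest.fixture
def replicate_counts() -> MeripCountSet:
    """2 sites x 4 replicate samples mapping onto 2 conditions."""
    return MeripCountSet(
        site_ids=["s1", "s2"],
        gene_ids=["gA", "gB"],
        samples=["a1", "a2", "b1", "b2"],
        t=np.array([[3, 1, 7, 2], [4, 6, 0, 5]]),
        c=np.array([[2, 2, 1, 1], [0, 3, 4, 4]]),
        condition_of_replicate={"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
    )
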