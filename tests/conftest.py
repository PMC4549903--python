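import numpy as np
import pytest

from nucleokey import (
    LabeledPool,
    OligoPool,
    OligoRecord,
    SyntheticSpec,
    filter_by_affinity,
    generate_pool,
    standard_partitions,
)


@pytest.fixture(scope="session")
def partitions():
    p44, p43, p54 = standard_partitions()
    return {"4-4": p44, "4-3": p43, "5-4": p54}


@pytest.fixture(scope="session")
def p44(partitions):
    return partitions["4-4"]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_pool(rng, n=20, length=150, affinity_scale=1.0):
    """Plain random pool with Gaussian affinities, no planted structure."""
    bases = np.array(list("ACGT"))
    records = [
        OligoRecord(
            f"r{i:04d}",
            "".join(bases[rng.integers(0, 4, size=length)]),
            float(rng.normal(0, affinity_scale)),
        )
        for i in range(n)
    ]
    return OligoPool(records, length)


@pytest.fixture(scope="session")
def small_synthetic(p44):
    """One filtered synthetic pool shared by read-only tests (n=600)."""
    spec = SyntheticSpec(n_sequences=600, seed=42)
    pool, classes, planted = generate_pool(spec, p44)
    labeled = filter_by_affinity(pool)
    return {"pool": pool, "classes": classes, "planted": planted, "labeled": labeled}
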