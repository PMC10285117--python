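import numpy as np
import pytest

from dispmix.io_geno import SiteSet, VariantCounts


@pytest.fixture
def small_counts() -> VariantCounts:
    rng = np.random.default_rng(0)
    n = rng.integers(10, 40, size=(4, 6))
    y = rng.binomial(n, 0.3)
    return VariantCounts(
        [f"site{j}" for j in range(4)], [f"snp{i}" for i in range(6)], y, n
    )


@pytest.fixture
def square_sites() -> SiteSet:
    return SiteSet(
        ["a", "b", "c", "d"],
        np.array([0.0, 10.0, 0.0, 10.0]),
        np.array([0.0, 0.0, 10.0, 10.0]),
    )
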