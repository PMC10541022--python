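import numpy as np
import pytest

from triotau import TraitSpec, TrioCohort

KIND_MIXES = [
    ("quantitative",),
    ("binary",),
    ("ordinal",),
    ("quantitative", "ordinal"),
    ("binary", "ordinal"),
    ("quantitative", "binary", "ordinal"),
]


def random_cohort(rng, n=None, m=None, kinds=None):
    """Small random trio cohort spanning all trait kinds (for oracles)."""
    n = n or rng.integers(3, 9)
    m = m or rng.integers(1, 5)
    kinds = kinds if kinds is not None else KIND_MIXES[rng.integers(len(KIND_MIXES))]
    q = len(kinds)

    def genotypes():
        return rng.integers(0, 3, size=(n, m))

    def traits():
        t = np.empty((n, q))
        for k, kind in enumerate(kinds):
            if kind == "quantitative":
                t[:, k] = rng.normal(size=n)
            elif kind == "binary":
                t[:, k] = rng.integers(0, 2, size=n)
            else:
                t[:, k] = rng.integers(0, 4, size=n)
        return t

    return TrioCohort(
        genotypes(), genotypes(), genotypes(),
        traits(), traits(), traits(), TraitSpec(kinds),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20230926)
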