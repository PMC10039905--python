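import numpy as np
import pytest

import hehsim as h


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """Selection config at a small population size for fast loop tests."""
    return h.SelectionConfig(pop_size=500, max_generations=100)


@pytest.fixture
def diploid():
    return h.CellKaryotype.diploid()


@pytest.fixture
def heh_karyotype():
    """A typical hyperdiploid cell: 2:2 tetrasomy 21, trisomies of the
    strongly selected chromosomes, heterodisomy elsewhere (MCN 55)."""
    copies = {c: (1, 1) for c in h.CHROMOSOMES}
    copies["21"] = (2, 2)
    for c in ("X", "4", "6", "10", "14", "17", "18"):
        copies[c] = (2, 1)
    return h.CellKaryotype(copies)
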