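import numpy as np
import pytest

from planktax.simulate import SimParams, generate_taxon_pool


def random_dna(rng, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20120410)


@pytest.fixture(scope="session")
def small_pool():
    """12 mock species in 4 genera with a mixed registration ledger."""
    params = SimParams(seed=7)
    return generate_taxon_pool(
        n_species=12, n_genera=4, frac_warm=0.25, params=params,
        registration_counts={"species_in_old": 4, "genus_only_in_old": 2,
                             "new_only": 4, "absent": 2})
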