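import pytest
from hypothesis import settings

from plastomarker.synthetic import default_scenario

settings.register_profile("suite", max_examples=50, derandomize=True, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_scenario():
    """Scaled-down four-genotype comparison used by most caller tests."""
    return default_scenario(
        seed=11,
        lsc_len=12_000,
        ir_len=2_500,
        ssc_len=5_000,
        n_snps=12,
        indel_lengths=(2, 9, 15, 30, 153, 458),
        inversions=((9, 17), (3, 22), (23, 29)),
        n_variable_ssrs=8,
        n_invariant_ssrs=5,
    )


@pytest.fixture(scope="session")
def full_scenario():
    """The full-size default scenario (45 SNPs / 17 indels / 5 inversions /
    49 variable SSR tracts on a ~159 kb quadripartite genome)."""
    return default_scenario(seed=1)


def carrier_set(states, positive):
    """Genotypes in a per-genotype state dict equal to ``positive``."""
    return frozenset(g for g, s in states.items() if s == positive)
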