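import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_genome():
    """Small two-chromosome genome with introns on the first two genes."""
    from mutscreen import generate_reference

    return generate_reference(
        n_chrom=2, chrom_len=15_000, n_genes=8, n_sets=3, seed=1, intron_genes=2
    )
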