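import pytest

from ditagdel import SimConfig, get_enzyme, simulate


@pytest.fixture(scope="session")
def taqi():
    return get_enzyme("TaqI")


@pytest.fixture(scope="session")
def hom_sim():
    """Noise-free diploid with homozygous deletions only: the exact-recovery
    substrate (200 kb, 6 planted deletions, depth 6)."""
    config = SimConfig(
        seed=11,
        chrom_length=200_000,
        n_deletions=6,
        hom_fraction=1.0,
        n_snp_sites=0,
        partial_digestion=0.0,
        depth=6.0,
        depth_mode="fixed",
    )
    return simulate(config)


@pytest.fixture(scope="session")
def mixed_sim():
    """Realistic mixture: het+hom deletions, site-killing SNPs, default
    partial digestion, depth 8 (300 kb)."""
    config = SimConfig(
        seed=23,
        chrom_length=300_000,
        n_deletions=10,
        hom_fraction=0.5,
        n_snp_sites=8,
        depth=8.0,
    )
    return simulate(config)
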