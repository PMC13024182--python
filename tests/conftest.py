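import pytest

from bovidy.simulate import FamilySpec, SimConfig, simulate_reads, simulate_sex_chromosomes


@pytest.fixture(scope="session")
def small_sim():
    """One 120 kb chromosome pair with a 20 kb PAR and a 10-copy family
    (2 expressed), shared across tests that only read from it."""
    cfg = SimConfig(seed=1, chrom_len=120_000, par_len=20_000, telomere_len=600,
                    families=[FamilySpec("FAM", 10, 600, expressed_copies=2)])
    x, y, truth = simulate_sex_chromosomes(cfg)
    return cfg, x, y, truth


@pytest.fixture(scope="session")
def small_sim_reads(small_sim):
    cfg, x, y, truth = small_sim
    short_reads, short_alns = simulate_reads(y, truth, "short", cfg)
    long_reads, long_alns = simulate_reads(y, truth, "long", cfg)
    return short_reads, short_alns, long_reads, long_alns
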