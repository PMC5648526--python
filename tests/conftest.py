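import pytest

from opsintron.simulate import SimulationConfig, simulate_family


@pytest.fixture(scope="session")
def noise_free_dataset():
    """Two clades, 3 vs 2 planted intron positions at distinct columns,
    no loss, no jitter, no indels: every truth quantity is exact."""
    config = SimulationConfig(
        seed=7,
        n_clades=2,
        seqs_per_clade=6,
        protein_length=240,
        substitution_rate=0.05,
        planted_introns=[[(60, 0), (120, 1), (180, 2)], [(90, 0), (200, 1)]],
        n_trees=10,
    )
    return simulate_family(config)


@pytest.fixture(scope="session")
def noisy_dataset():
    """Same family with intron loss, jitter and clade-level indels."""
    config = SimulationConfig(
        seed=11,
        n_clades=2,
        seqs_per_clade=8,
        protein_length=240,
        substitution_rate=0.08,
        planted_introns=[[(60, 0), (120, 1), (180, 2)], [(90, 0), (200, 1)]],
        intron_loss_prob=0.1,
        intron_jitter=0,
        indel_rate=0.02,
        n_trees=10,
    )
    return simulate_family(config)
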