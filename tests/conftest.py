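import numpy as np
import pytest

from ctsbench.pwm import random_pwm
from ctsbench.synthetic import (SimConfig, make_grammar, simulate_coverage,
                                simulate_genome_and_peaks)


@pytest.fixture(scope="session")
def small_sim():
    """A small two-cell-type simulation shared by read-only tests."""
    cfg = SimConfig(
        n_cell_types=2,
        chrom_lengths={"chrA": 400_000, "chrB": 400_000},
        n_ubiquitous=40, n_specific_per_type=30,
        n_replicates=2, n_individuals=1,
        overdispersion=0.1, seed=5,
    )
    rng = np.random.default_rng(42)
    pwms = [random_pwm(f"M{i}", 8, rng) for i in range(8)]
    grammar = make_grammar(2, pwms, n_shared=2, n_specific_per_type=2, seed=7)
    genome, truth = simulate_genome_and_peaks(cfg, grammar)
    tracks = simulate_coverage(genome, truth, cfg)
    return {"cfg": cfg, "pwms": pwms, "grammar": grammar, "genome": genome,
            "truth": truth, "tracks": tracks}
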