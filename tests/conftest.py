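import numpy as np
import pytest

import dampeaks as dp


@pytest.fixture
def toy_genome():
    return dp.Genome(chroms=[("chrX", 1000), ("chr2L", 500)])


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated dataset with strong planted enrichment."""
    cfg = dp.SimConfig(
        chrom_lengths=[1_000_000],
        n_sites=10,
        site_effect=8.0,
        depth_treatment=50_000,
        depth_control=50_000,
        seed=7,
    )
    genome = dp.simulate_genome(cfg)
    treatment, control, truth = dp.simulate_reads(genome, cfg)
    return cfg, genome, treatment, control, truth


def write_lines(path, lines):
    path.write_text("".join(line + "\n" for line in lines))
    return path
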