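import numpy as np
import pytest

from poolsel.simdata import SimConfig, SelectedSite, gen_experiment


@pytest.fixture(scope="session")
def small_experiment():
    """A 300-SNP, two-chromosome experiment with one selected site."""
    cfg = SimConfig(
        seed=42,
        n_sites=300,
        chrom_lengths={"I": 300_000, "II": 300_000},
        true_ne=500,
        selected_sites=[SelectedSite(10, 0.15, "BS-PO")],
        freq0_overrides={10: 0.2},
    )
    counts, meta, truth = gen_experiment(cfg)
    return cfg, counts, meta, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
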