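import numpy as np
import pytest

from nbmine import SimConfig, simulate_repertoire, simulate_selection_and_reads


@pytest.fixture(scope="session")
def small_sim():
    """A modest noisy two-sample simulation shared across tests."""
    cfg = SimConfig(
        n_lineages=30,
        n_binders=5,
        variants_per_lineage=4,
        reads_per_sample=4000,
        seed=42,
    )
    truth = simulate_repertoire(cfg)
    reads = simulate_selection_and_reads(truth, cfg)
    return cfg, truth, reads


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_peptide(rng, n, alphabet="ACDEFGHIKLMNPQRSTVWY"):
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=n))
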