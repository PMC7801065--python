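import pytest

from adcscreen.simulate import SimConfig, simulate_dataset, write_dataset

SMALL_CLASS_COUNTS = {label: 5 for label in (
    "candidate", "non_membrane", "no_evidence", "critical_normal_high",
    "low_score", "non_surface_high", "fails_rna", "fails_literature",
    "fails_membranous",
)}


def small_config(seed: int) -> SimConfig:
    return SimConfig(n_genes_per_class=dict(SMALL_CLASS_COUNTS), seed=seed)


@pytest.fixture(scope="session")
def small_sim():
    """One small planted dataset (5 genes per class, seed 1)."""
    return simulate_dataset(small_config(1))


@pytest.fixture(scope="session")
def dataset_dir(tmp_path_factory, small_sim):
    """The same dataset written out in its external table dialects."""
    dataset, truth = small_sim
    out = tmp_path_factory.mktemp("dataset")
    write_dataset(dataset, truth, out)
    return out
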