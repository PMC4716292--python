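import pytest

from ck2phospho import io, merge, simulate


@pytest.fixture(scope="session")
def small_config():
    return simulate.SyntheticConfig(seed=11, n_proteins=120, n_phospho_motifs=300)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """A seeded 300-motif, 3-group synthetic dataset shared across tests."""
    records, design, truth, proteome = simulate.generate_dataset(small_config)
    return {
        "config": small_config,
        "records": records,
        "design": design,
        "truth": truth,
        "proteome": proteome,
    }


@pytest.fixture(scope="session")
def small_motifs(small_dataset):
    phospho = [r for r in small_dataset["records"] if r.is_phospho]
    motifs_list, report = merge.merge_variants(phospho, small_dataset["proteome"])
    return motifs_list, report


@pytest.fixture()
def toy_design():
    return [
        io.SampleDesign("a1", "ctrl", 1),
        io.SampleDesign("a2", "ctrl", 2),
        io.SampleDesign("b1", "treat", 1),
        io.SampleDesign("b2", "treat", 2),
    ]
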