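import pytest

from dieldas.pipeline import run_analysis
from dieldas.synthetic_data import generate_dataset, simulate_genes


@pytest.fixture(scope="session")
def mixed_dataset():
    """Small cohort with DE and isoform-switch genes plus nulls."""
    genes = simulate_genes(
        {"null": 30, "de_up": 5, "das_switch": 5}, seed=7
    )
    return generate_dataset(genes, seed=7)


@pytest.fixture(scope="session")
def mixed_results(mixed_dataset):
    ds = mixed_dataset
    return run_analysis(ds.quant_tables, ds.tx2gene, ds.design)
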