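import numpy as np
import pytest

from omicsrules.discretize import TransactionDB
from omicsrules.synthetic import SynthConfig, generate_paired_omics


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_dataset():
    """Two planted 3-gene modules, 13+13 samples, strong effect."""
    config = SynthConfig(
        n_genes=20,
        n_samples_case=13,
        n_samples_control=13,
        n_modules=2,
        module_size=3,
        effect_size=4.0,
        noise_sd=1.0,
        ppi_background_density=0.05,
        seed=11,
    )
    return generate_paired_omics(config)


def make_db(transactions, sample_ids=None):
    transactions = [frozenset(tx) for tx in transactions]
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(len(transactions))]
    items = sorted({it for tx in transactions for it in tx})
    return TransactionDB(sample_ids=sample_ids, transactions=transactions,
                         item_ids=items)


def random_db(rng, n_items=8, n_transactions=12, density=0.4):
    items = [f"i{k}" for k in range(n_items)]
    transactions = []
    for _ in range(n_transactions):
        mask = rng.random(n_items) < density
        transactions.append(frozenset(np.array(items, dtype=object)[mask]))
    return make_db(transactions)
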