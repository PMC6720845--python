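import numpy as np
import pytest

from domppi.metrics import ConfusionCounts
from domppi.ppi_scorer import InteractionScoreTable
from domppi.synthdata import GeneratorConfig, generate_dataset

# Printed per-threshold evaluation row used as a fixed metric input.
TABLE_COUNTS = ConfusionCounts(tp=413, tn=383, fp=20, fn=14)


@pytest.fixture(scope="session")
def table_counts() -> ConfusionCounts:
    return TABLE_COUNTS


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """A reduced dataset that keeps unit tests fast."""
    return GeneratorConfig(
        n_positive_ppi=60,
        n_negative_ppi=55,
        n_positive_ddi=150,
        n_negative_ddi=150,
        n_domains_per_class=60,
        n_proteins_per_class=40,
        seq_len_range=(40, 120),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_score_table(small_dataset) -> InteractionScoreTable:
    return InteractionScoreTable.from_scores(small_dataset.score_rows)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
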