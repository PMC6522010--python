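import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ciliabayes.containers import DatasetSchema, GeneEvidenceTable, RunConfig, TrainingSets

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def two_binary_schemas():
    return [
        DatasetSchema("ppi", ("found", "not_found"), "not_found"),
        DatasetSchema("tfbs", ("tfbs", "no_tfbs"), "no_tfbs"),
    ]


@pytest.fixture
def toy_evidence(two_binary_schemas):
    """Deterministic toy table: 8 genes, 2 binary datasets."""
    cells = pd.DataFrame(
        {
            "ppi": ["found", "found", "not_found", "found",
                    "not_found", "not_found", "found", "not_found"],
            "tfbs": ["tfbs", "no_tfbs", "tfbs", "no_tfbs",
                     "no_tfbs", "tfbs", "no_tfbs", "no_tfbs"],
        },
        index=pd.Index([f"g{i}" for i in range(8)], name="gene"),
    )
    return GeneEvidenceTable(cells, two_binary_schemas)


@pytest.fixture
def toy_training():
    return TrainingSets(
        positives=frozenset({"g0", "g1", "g2"}),
        negatives=frozenset({"g5", "g6", "g7"}),
    )


def make_random_evidence(
    n_genes: int,
    n_pos: int,
    n_neg: int,
    p_found_pos: float = 0.6,
    p_found_neg: float = 0.1,
    seed: int = 0,
):
    """Single-dataset random evidence with planted class structure."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    is_pos = np.zeros(n_genes, dtype=bool)
    is_pos[:n_pos] = True
    p = np.where(is_pos, p_found_pos, p_found_neg)
    found = rng.random(n_genes) < p
    cells = pd.DataFrame(
        {"ppi": np.where(found, "found", "not_found")},
        index=pd.Index(genes, name="gene"),
    )
    schema = DatasetSchema("ppi", ("found", "not_found"), "not_found")
    training = TrainingSets(
        positives=frozenset(genes[:n_pos]),
        negatives=frozenset(genes[n_pos : n_pos + n_neg]),
    )
    return GeneEvidenceTable(cells, [schema]), training


@pytest.fixture(scope="session")
def paperlike_bundle():
    """One generated study-scale bundle shared across tests."""
    from ciliabayes import synthetic

    return synthetic.generate(synthetic.default_paperlike_config(seed=11))


@pytest.fixture(scope="session")
def default_config():
    return RunConfig()
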