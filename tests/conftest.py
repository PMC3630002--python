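import numpy as np
import pytest

from probesim import (
    CovariationNetwork,
    ProbeSetSimilarity,
    SyntheticSpec,
    generate_dataset,
)


@pytest.fixture(scope="session")
def default_dataset():
    """Default-condition synthetic dataset with planted truth."""
    return generate_dataset(SyntheticSpec(seed=20260922))


@pytest.fixture(scope="session")
def fitted(default_dataset):
    """Fitted similarity results on the default synthetic dataset."""
    dataset, truth = default_dataset
    results = ProbeSetSimilarity(dataset).fit(seed=20260922)
    return dataset, truth, results


def make_network(ids, corr_edges, anti_edges=(), n_comparisons=100, alpha=0.05):
    """Hand-built network from explicit edge lists (ps_a, ps_b, value)."""
    n = len(ids)
    idx = {p: i for i, p in enumerate(ids)}
    corr = np.zeros((n, n))
    anti = np.zeros((n, n))
    stored_corr = np.zeros((n, n), dtype=bool)
    stored_anti = np.zeros((n, n), dtype=bool)
    for a, b, v in corr_edges:
        i, j = idx[a], idx[b]
        corr[i, j] = corr[j, i] = v
        stored_corr[i, j] = stored_corr[j, i] = True
    for a, b, v in anti_edges:
        i, j = idx[a], idx[b]
        anti[i, j] = anti[j, i] = v
        stored_anti[i, j] = stored_anti[j, i] = True
    return CovariationNetwork(
        list(ids), corr, anti, stored_corr, stored_anti, alpha, n_comparisons
    )
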