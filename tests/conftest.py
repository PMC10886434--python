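import numpy as np
import pandas as pd
import pytest

from modulome import (
    SyntheticConfig,
    center_to_reference,
    generate_compendium,
    log_transform,
    robust_ica,
)
from modulome.compendium import ExpressionCompendium


def make_compendium(values, groups, reference_group, state="raw"):
    """Build a compendium from a 2-D array and per-sample group labels."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    gene_ids = [f"g{i + 1:03d}" for i in range(n_genes)]
    sample_ids = [f"s{j + 1}" for j in range(n_samples)]
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "project": "test",
            "condition": groups,
            "replicate_group": groups,
            "is_reference": [g == reference_group for g in groups],
        }
    )
    return ExpressionCompendium(
        values=pd.DataFrame(values, index=gene_ids, columns=sample_ids),
        metadata=meta,
        state=state,
    )


SMALL = SyntheticConfig(
    n_genes=300,
    n_samples=20,
    n_modules=3,
    module_size_range=(8, 12),
    n_replicate_groups=10,
    replicates_per_group=2,
    reference_group="grp00",
    noise_sd=0.05,
    seed=11,
)


@pytest.fixture(scope="session")
def small_truth():
    return generate_compendium(SMALL)


@pytest.fixture(scope="session")
def small_centered(small_truth):
    return center_to_reference(log_transform(small_truth.compendium))


@pytest.fixture(scope="session")
def small_logged(small_truth):
    return log_transform(small_truth.compendium)


@pytest.fixture(scope="session")
def small_decomposition(small_centered):
    return robust_ica(small_centered.values, 3, n_restarts=10, base_seed=21)
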