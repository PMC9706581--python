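import numpy as np
import pandas as pd
import pytest

from uroscore import (
    BulkSimConfig,
    ExpressionMatrix,
    generate_bulk_cohort,
    generate_signature_sets,
    generate_single_cell_bundle,
)


@pytest.fixture(scope="session")
def signature_sets():
    return generate_signature_sets(seed=7)


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-sample cohort, small enough for per-test scoring."""
    return generate_bulk_cohort(BulkSimConfig(n_samples=60, seed=11))


@pytest.fixture(scope="session")
def default_cohort():
    return generate_bulk_cohort(BulkSimConfig(seed=3))


@pytest.fixture()
def random_log_matrix():
    """Factory for random log-scale expression matrices."""

    def make(n_genes=20, n_samples=5, seed=0):
        rng = np.random.default_rng(seed)
        vals = rng.normal(5, 2, size=(n_genes, n_samples))
        return ExpressionMatrix(
            values=pd.DataFrame(
                vals,
                index=[f"g{i:03d}" for i in range(n_genes)],
                columns=[f"s{j}" for j in range(n_samples)],
            ),
            scale_tag="log",
        )

    return make


@pytest.fixture(scope="session")
def sc_bundle():
    """A clean 3-cluster single-cell bundle (no planted violations)."""
    bundle, panel, _ = generate_single_cell_bundle(
        n_clusters=3, cells_per_cluster=60, n_genes=200, seed=5, n_samples=3
    )
    return bundle, panel
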