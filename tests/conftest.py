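import numpy as np
import pytest

from surfscore.preprocess import ExpressionMatrix
from surfscore.synthetic import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_config():
    return SimulationConfig(
        n_genes=100,
        surface_fraction=0.2,
        n_planted=5,
        effect_delta=3.0,
        sigma=1.0,
        n_tumor=5,
        n_normal=5,
        seed=1,
    )


@pytest.fixture
def strong_config():
    """Saturated detection, zero contamination, large effect: the regime
    where every planted target must reach the maximum score."""
    return SimulationConfig(
        n_genes=400,
        surface_fraction=0.25,
        n_planted=15,
        effect_delta=3.0,
        sigma=1.0,
        n_tumor=10,
        n_normal=10,
        detect_intercept=20.0,
        detect_slope=0.0,
        contamination_rate=0.0,
        seed=11,
    )


def make_matrix(values, n_tumor, n_normal, gene_ids=None, dataset_id="DS"):
    values = np.asarray(values, dtype=float)
    n_genes = values.shape[0]
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    sample_ids = [f"T{i}" for i in range(n_tumor)] + [f"N{i}" for i in range(n_normal)]
    groups = ["tumor"] * n_tumor + ["normal"] * n_normal
    return ExpressionMatrix(
        values=values,
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        groups=groups,
        dataset_id=dataset_id,
    )


@pytest.fixture
def matrix_factory():
    return make_matrix
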