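import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from corrflag.io import ExpressionCompendium

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_compendium(values, gene_ids=None, sample_ids=None, series=None, name="test"):
    values = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionCompendium(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        values=values,
        series_of_sample=series or {},
        name=name,
    )


@pytest.fixture
def tiny_comp():
    """3 genes x 4 samples with simple structure."""
    return make_compendium(
        [[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0], [5.0, 5.0, 5.0, 5.0]],
        gene_ids=["gA", "gB", "gC"],
    )


@pytest.fixture
def two_series_comp():
    rng = np.random.default_rng(11)
    values = rng.normal(7, 1, size=(2, 6))
    series = {f"s{j}": ("SER1" if j < 3 else "SER2") for j in range(6)}
    return make_compendium(values, series=series)


@pytest.fixture
def bimodal_gene_comp():
    """One strongly bimodal gene, 40% on, n=300."""
    rng = np.random.default_rng(5)
    on = rng.normal(10.0, 0.4, 120)
    off = rng.normal(6.0, 0.4, 180)
    x = np.concatenate([off, on])
    rng.shuffle(x)
    return make_compendium(x[None, :], gene_ids=["gBim"])
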