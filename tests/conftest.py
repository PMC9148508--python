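import pytest

from fragscan import fixtures as fx
from fragscan.model import write_training_set


@pytest.fixture(scope="session")
def params():
    """A moderately sharp random model."""
    return fx.generate_params(1, symmetric=False, gene_strength=3.0)


@pytest.fixture(scope="session")
def strong_params():
    """A sharply coding-biased model: planted genes decode reliably."""
    return fx.generate_params(1, symmetric=False, gene_strength=6.0)


@pytest.fixture(scope="session")
def symmetric_params():
    """Strand-symmetric by construction (exact mirror scores)."""
    return fx.generate_params(5, symmetric=True, gene_strength=5.0)


@pytest.fixture()
def train_dir(tmp_path, params):
    """A valid training directory written from the random model."""
    root = tmp_path / "train"
    rates_454 = dict(params.rates, match_to_insert=0.02, match_skip=0.02)
    write_training_set(params, root, conditions={"454_10": rates_454})
    return root
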