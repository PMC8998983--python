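import numpy as np
import pytest

from cpinet.dataset import from_synthetic
from cpinet.model import ModelConfig, UnifiedModel
from cpinet.synthetic import SynthConfig, gen_dataset
from cpinet.vocab import build_vocabulary, default_smiles_vocabulary


SMALL_MODEL_KW = dict(smiles_dim=16, sps_dim=16, amino_dim=16, graph_hidden=16,
                      conv_filters=8, attention_dim=8, head_hidden=16,
                      max_smiles_len=40, max_sps_len=60, max_amino_len=160)


@pytest.fixture(scope="session")
def tiny_dataset():
    """40 labeled pairs with mild noise, shared across tests (read-only)."""
    synth = gen_dataset(SynthConfig(n_compounds=15, n_proteins=8, n_pairs=40,
                                    noise_sd=0.1, seed=3))
    return synth, from_synthetic(synth.samples)


@pytest.fixture(scope="session")
def tiny_vocabs(tiny_dataset):
    _, cpi = tiny_dataset
    return {
        "smiles": default_smiles_vocabulary(),
        "sps": build_vocabulary([list(s.sps) for s in cpi.samples], "sps"),
        "amino": build_vocabulary([s.amino for s in cpi.samples], "amino"),
    }


@pytest.fixture()
def small_model(tiny_vocabs):
    cfg = ModelConfig(channels=("smiles", "sps", "graph"), **SMALL_MODEL_KW)
    return UnifiedModel.initialize(cfg, tiny_vocabs, seed=0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
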