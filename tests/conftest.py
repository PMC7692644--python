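import numpy as np
import pytest

from npscreen import Molecule, ReactionClass, ReactionPair
from npscreen.seq2seq import ModelConfig


@pytest.fixture(scope="session")
def benzoic_acid() -> Molecule:
    return Molecule.from_smiles("OC(=O)c1ccccc1")


@pytest.fixture(scope="session")
def tiny_corpus() -> list[ReactionPair]:
    """A handful of esterification pairs for codec/config tests."""
    smiles = [
        ("O=C(O)c1ccccc1", "COC(=O)c1ccccc1"),
        ("O=C(O)c1ccc(C)cc1", "COC(=O)c1ccc(C)cc1"),
        ("O=C(O)c1ccco1", "COC(=O)c1ccco1"),
        ("O=C(O)Cc1ccccc1", "COC(=O)Cc1ccccc1"),
        ("O=C(O)c1cccs1", "COC(=O)c1cccs1"),
        ("O=C(O)c1cccnc1", "COC(=O)c1cccnc1"),
        ("O=C(O)C1CCCCC1", "COC(=O)C1CCCCC1"),
        ("O=C(O)c1ccc(F)cc1", "COC(=O)c1ccc(F)cc1"),
        ("O=C(O)c1ccc(Cl)cc1", "COC(=O)c1ccc(Cl)cc1"),
        ("O=C(O)c1ccc(OC)cc1", "COC(=O)c1ccc(OC)cc1"),
    ]
    from npscreen import canonicalize

    return [
        ReactionPair(canonicalize(r), canonicalize(p), ReactionClass.METHANOL)
        for r, p in smiles
    ]


@pytest.fixture(scope="session")
def small_config() -> ModelConfig:
    """A reduced network for fast unit tests (not the reference defaults)."""
    return ModelConfig(
        epochs=400,
        encoder_latent_dim=32,
        decoder_latent_dim=16,
        output_hidden_dim=24,
        position_dim=8,
        dropout=0.0,
        seed=0,
    )


@pytest.fixture(scope="session")
def trained_tiny_model(tiny_corpus, small_config):
    """A small model memorizing ten esterification pairs; shared for speed."""
    from npscreen.seq2seq import TranslationModel

    return TranslationModel.train(tiny_corpus, small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
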