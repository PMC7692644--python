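import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from npscreen import Molecule
from npscreen.seq2seq import (
    CodecError,
    ConfigurationError,
    IncompatibleModelError,
    ModelConfig,
    SequenceCodec,
    TranslationModel,
    split_dataset,
)
from npscreen.templates import ReactionClass, ReactionPair

MEOH = ReactionClass.METHANOL


class TestCodec:
    def test_alphabet_size_counts_unique_chars_plus_reserved(self):
        codec = SequenceCodec.from_corpus([ReactionPair("CCO", "CCN", MEOH)])
        assert codec.size == 6  # C, O, N + pad/start/end

    def test_round_trip_identity(self):
        codec = SequenceCodec.from_corpus([ReactionPair("CCO", "CCN", MEOH)])
        assert codec.decode(codec.encode("CCO")) == "CCO"

    def test_unknown_character_is_an_error(self):
        codec = SequenceCodec.from_corpus([ReactionPair("CCO", "CCN", MEOH)])
        with pytest.raises(CodecError):
            codec.encode("CCS")

    def test_max_length_is_longest_plus_two(self):
        codec = SequenceCodec.from_corpus(
            [ReactionPair("CCO", "CCCCN", MEOH)]
        )
        assert codec.max_length == 7

    def test_empty_corpus_rejected(self):
        with pytest.raises(ConfigurationError):
            SequenceCodec.from_corpus([])

    @settings(max_examples=50, deadline=None)
    @given(st.text(alphabet="CNOcn1()=#[]@+-", min_size=1, max_size=40))
    def test_round_trip_over_random_strings(self, text):
        codec = SequenceCodec.from_corpus(
            [ReactionPair("CNOcn1()=#[]@+-", text, MEOH)]
        )
        assert codec.decode(codec.encode(text)) == text

    def test_serialization_round_trip(self):
        codec = SequenceCodec.from_corpus([ReactionPair("CCO", "CCN", MEOH)])
        assert SequenceCodec.from_dict(codec.to_dict()) == codec


class TestSplitDataset:
    @pytest.fixture
    def ten_pairs(self):
        return [ReactionPair(f"{'C' * (i + 1)}O", "CCN", MEOH) for i in range(10)]

    def test_eighty_twenty(self, ten_pairs):
        train, val = split_dataset(ten_pairs, 0.8, seed=1)
        assert (len(train), len(val)) == (8, 2)

    def test_partition_property(self, ten_pairs):
        train, val = split_dataset(ten_pairs, 0.8, seed=1)
        assert sorted(train + val, key=str) == sorted(ten_pairs, key=str)
        assert not set(p.reactant for p in train) & set(p.reactant for p in val)

    def test_deterministic(self, ten_pairs):
        assert split_dataset(ten_pairs, 0.8, seed=9) == split_dataset(
            ten_pairs, 0.8, seed=9
        )

    def test_both_sides_nonempty_even_for_extreme_fractions(self, ten_pairs):
        train, val = split_dataset(ten_pairs, 0.99, seed=0)
        assert len(train) >= 1 and len(val) >= 1

    def test_bad_fraction_rejected(self, ten_pairs):
        with pytest.raises(ValueError):
            split_dataset(ten_pairs, 1.0, seed=0)


class TestConfig:
    def test_per_class_epoch_defaults(self):
        assert ModelConfig.for_class(MEOH).epochs == 100
        assert ModelConfig.for_class(ReactionClass.CHLOROFORM).epochs == 1000
        assert ModelConfig.for_class(ReactionClass.WATER).epochs == 500

    def test_reference_dimensions(self):
        cfg = ModelConfig()
        assert cfg.batch_size == 64
        assert cfg.encoder_latent_dim == 256
        assert cfg.decoder_latent_dim == 64
        assert cfg.optimizer_name == "Adam"

    def test_invalid_counts_rejected(self):
        with pytest.raises(ConfigurationError):
            ModelConfig(epochs=0)
        with pytest.raises(ConfigurationError):
            ModelConfig(optimizer_name="SGD")


class TestTraining:
    def test_loss_decreases(self, trained_tiny_model):
        history = trained_tiny_model.loss_history
        assert history[-1] <= history[0]

    def test_training_is_seed_deterministic(self, tiny_corpus, small_config):
        cfg = dataclasses.replace(small_config, epochs=3)
        m1 = TranslationModel.train(tiny_corpus, cfg)
        m2 = TranslationModel.train(tiny_corpus, cfg)
        assert m1.loss_history == pytest.approx(m2.loss_history, rel=1e-5)

    def test_mixed_class_corpus_rejected(self, tiny_corpus, small_config):
        bad = tiny_corpus + [
            ReactionPair("Oc1ccc(O)cc1", "O=C1C=CC(=O)C=C1",
                         ReactionClass.OXIDATION)
        ]
        with pytest.raises(ConfigurationError):
            TranslationModel.train(bad, small_config)

    def test_memorizes_training_pairs(self, trained_tiny_model, tiny_corpus):
        """A small network must reproduce pairs it was trained on."""
        hits = 0
        outcomes = trained_tiny_model.predict_many(
            [Molecule.from_smiles(p.reactant) for p in tiny_corpus]
        )
        for pair, out in zip(tiny_corpus, outcomes):
            target = Molecule.from_smiles(pair.product)
            if out.valid and out.product.structure_key == target.structure_key:
                hits += 1
        assert hits >= 8  # at least 8/10 memorized


class TestPrediction:
    def test_out_of_alphabet_reactant_is_invalid_outcome(
        self, trained_tiny_model
    ):
        bromide = Molecule.from_smiles("BrCCO")  # 'B','r' not in corpus
        outcome = trained_tiny_model.predict(bromide)
        assert outcome.valid is False
        assert outcome.product is None
        assert outcome.generated_smiles == ""

    def test_generated_length_bounded_by_codec(self, trained_tiny_model):
        out = trained_tiny_model.predict(Molecule.from_smiles("O=C(O)c1ccccc1"))
        assert len(out.generated_smiles) <= trained_tiny_model.codec.max_length

    def test_outcome_validity_flag_matches_parser(self, trained_tiny_model):
        out = trained_tiny_model.predict(Molecule.from_smiles("O=C(O)c1ccco1"))
        from npscreen.chemio import is_valid

        assert out.valid == is_valid(out.generated_smiles)
        assert (out.product is not None) == out.valid


class TestSerialization:
    def test_save_load_round_trip_predictions(
        self, trained_tiny_model, tiny_corpus, tmp_path
    ):
        trained_tiny_model.save(tmp_path / "model")
        loaded = TranslationModel.load(tmp_path / "model")
        probes = [Molecule.from_smiles(p.reactant) for p in tiny_corpus]
        before = [o.generated_smiles for o in trained_tiny_model.predict_many(probes)]
        after = [o.generated_smiles for o in loaded.predict_many(probes)]
        assert before == after

    def test_loaded_model_reports_reaction_class(
        self, trained_tiny_model, tmp_path
    ):
        trained_tiny_model.save(tmp_path / "model")
        loaded = TranslationModel.load(tmp_path / "model")
        assert loaded.reaction_class is MEOH
        assert loaded.config == trained_tiny_model.config

    def test_truncated_bundle_is_incompatible(
        self, trained_tiny_model, tmp_path
    ):
        trained_tiny_model.save(tmp_path / "model")
        weights = tmp_path / "model" / "weights.npz"
        weights.write_bytes(weights.read_bytes()[:100])
        with pytest.raises(IncompatibleModelError):
            TranslationModel.load(tmp_path / "model")

    def test_missing_bundle_is_incompatible(self, tmp_path):
        with pytest.raises(IncompatibleModelError):
            TranslationModel.load(tmp_path / "nothing")


def test_greedy_decode_terminates_for_arbitrary_weights(tiny_corpus):
    """Decoding stops at max_length even for an untrained network."""
    codec = SequenceCodec.from_corpus(tiny_corpus)
    cfg = ModelConfig(
        epochs=1, encoder_latent_dim=8, decoder_latent_dim=8,
        output_hidden_dim=8, position_dim=4,
    )
    model = TranslationModel(
        MEOH, codec, cfg,
        TranslationModel._init_params(np.random.default_rng(0), codec.size, cfg),
    )
    out = model.predict(Molecule.from_smiles("O=C(O)c1ccccc1"))
    assert len(out.generated_smiles) <= codec.max_length
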