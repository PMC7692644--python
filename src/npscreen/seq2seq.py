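"""Character-level convolutional translator from reactant to product SMILES.

One model is trained per reaction class.  SMILES strings are treated as
sentences of single characters (so ``Cl`` is two tokens) and embedded as
one-hot vectors over the characters observed in the corpus.  The network
follows a convolutional encoder-decoder with attention:

* encoder — three 1-D convolutional layers over the reactant sequence
  (residual connections, increasing dilation);
* decoder — three causal 1-D convolutional layers over the product
  sequence offset by one position (teacher forcing during training);
* an attention layer combining decoder and encoder states, with a copy
  readout that routes the attended raw input characters straight to the
  output block;
* an output decoder of two further convolutional layers emitting a
  per-position distribution over characters.

Inference is greedy autoregressive decoding from the start symbol until
the end symbol or the length cap.  Generated strings are judged by whether
they parse as molecules; parsing and structure identity go through
:mod:`npscreen.chemio`.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from . import _network as nn
from .chemio import Molecule, is_valid
from .templates import ReactionClass, ReactionPair

log = logging.getLogger(__name__)

PAD, START, END = " ", "^", "$"  # reserved symbols, not legal in SMILES
_FORMAT_VERSION = 1


class CodecError(ValueError):
    """A string cannot be encoded with this codec."""


class ConfigurationError(ValueError):
    """Corpus/codec/config mismatch."""


class IncompatibleModelError(ValueError):
    """A saved model bundle cannot be loaded."""


# Table of per-class training epochs used by the reference configuration.
DEFAULT_EPOCHS = {
    ReactionClass.METHANOL: 100,
    ReactionClass.ETHANOL: 500,
    ReactionClass.ACETONE: 100,
    ReactionClass.DICHLOROMETHANE: 500,
    ReactionClass.CHLOROFORM: 1000,
    ReactionClass.WATER: 500,
    ReactionClass.OXIDATION: 500,
}


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the translation network.

    The headline settings (batch size 64, encoder dimensionality 256,
    decoder dimensionality 64, Adam) are the reference defaults; epochs are
    class-specific (see :data:`DEFAULT_EPOCHS`).  The remaining fields pin
    down details a convolutional seq2seq needs but that admit many
    reasonable choices; the defaults were selected by held-out validation
    performance on template-generated corpora: kernel width 3 with layer
    dilations (1, 3, 9) so the third layer sees most of a short SMILES,
    causal padding on all decoder-side convolutions, a 128-channel hidden
    layer in the output decoder, 16 sinusoidal position channels appended
    to the one-hot embeddings, a soft diagonal attention prior, dropout
    0.15 on the convolutional branches, per-position categorical
    cross-entropy, and Adam under a warmup + cosine schedule with global
    gradient-norm clipping.
    """

    batch_size: int = 64
    epochs: int = 100
    encoder_latent_dim: int = 256
    decoder_latent_dim: int = 64
    optimizer_name: str = "Adam"
    seed: int = 0
    kernel_size: int = 3
    output_hidden_dim: int = 128
    learning_rate: float = 1.5e-2
    max_length: int = 120
    position_dim: int = 16
    attention_prior_width: float = 4.0
    grad_clip_norm: float = 1.0
    lr_schedule: str = "cosine"
    warmup_epochs: int = 5
    dropout: float = 0.15
    weight_decay: float = 0.0
    dilations: tuple[int, int, int] = (1, 3, 9)

    @classmethod
    def for_class(cls, reaction_class: ReactionClass, **overrides) -> "ModelConfig":
        base = cls(epochs=DEFAULT_EPOCHS[reaction_class])
        return replace(base, **overrides)

    def __post_init__(self):
        for name in ("batch_size", "epochs", "encoder_latent_dim",
                     "decoder_latent_dim", "kernel_size", "output_hidden_dim",
                     "max_length"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be positive")
        if self.optimizer_name.lower() != "adam":
            raise ConfigurationError("only the Adam optimizer is supported")


@dataclass(frozen=True)
class SequenceCodec:
    """Bijection between SMILES characters and embedding indices.

    The alphabet is the set of unique characters over all reactant and
    product strings of the corpus plus three reserved symbols (pad, start,
    end); ``max_length`` is the longest corpus string plus two, leaving
    room for the start and end symbols.
    """

    alphabet: tuple[str, ...]
    max_length: int
    char_to_index: dict[str, int] = field(compare=False, repr=False)

    @classmethod
    def from_corpus(
        cls, pairs: Sequence[ReactionPair], length_cap: int = 120
    ) -> "SequenceCodec":
        if not pairs:
            raise ConfigurationError("cannot build a codec from an empty corpus")
        chars: set[str] = set()
        longest = 0
        for p in pairs:
            for s in (p.reactant, p.product):
                chars.update(s)
                longest = max(longest, len(s))
        bad = chars & {PAD, START, END}
        if bad:
            raise ConfigurationError(f"corpus contains reserved symbols {bad}")
        alphabet = (PAD, START, END, *sorted(chars))
        max_length = min(longest + 2, length_cap)
        return cls(
            alphabet=alphabet,
            max_length=max_length,
            char_to_index={c: i for i, c in enumerate(alphabet)},
        )

    @property
    def size(self) -> int:
        return len(self.alphabet)

    def can_encode(self, text: str) -> bool:
        return len(text) + 2 <= self.max_length and all(
            c in self.char_to_index for c in text
        )

    def encode(self, text: str, with_start: bool = False) -> np.ndarray:
        """Index sequence of *text* padded to max_length.

        With ``with_start`` the start symbol is prepended (decoder input
        layout); otherwise the end symbol is appended (encoder layout and
        decoder target layout share it).
        """
        if not self.can_encode(text):
            raise CodecError(f"cannot encode {text!r} with this codec")
        if with_start:
            symbols = [START, *text]
        else:
            symbols = [*text, END]
        idx = [self.char_to_index[c] for c in symbols]
        idx += [0] * (self.max_length - len(idx))
        return np.asarray(idx, dtype=np.int64)

    def decode(self, indices: Sequence[int]) -> str:
        out = []
        for i in indices:
            c = self.alphabet[int(i)]
            if c == END:
                break
            if c in (PAD, START):
                continue
            out.append(c)
        return "".join(out)

    def to_dict(self) -> dict:
        return {"alphabet": list(self.alphabet), "max_length": self.max_length}

    @classmethod
    def from_dict(cls, d: dict) -> "SequenceCodec":
        alphabet = tuple(d["alphabet"])
        return cls(
            alphabet=alphabet,
            max_length=int(d["max_length"]),
            char_to_index={c: i for i, c in enumerate(alphabet)},
        )


@dataclass(frozen=True)
class PredictionOutcome:
    """A single generated product string and its validity judgment."""

    reactant: Molecule
    reaction_class: ReactionClass
    generated_smiles: str
    valid: bool
    product: Molecule | None = None

    @classmethod
    def from_generated(
        cls, reactant: Molecule, reaction_class: ReactionClass, generated: str
    ) -> "PredictionOutcome":
        ok = is_valid(generated)
        return cls(
            reactant=reactant,
            reaction_class=reaction_class,
            generated_smiles=generated,
            valid=ok,
            product=Molecule.from_smiles(generated) if ok else None,
        )


def split_dataset(
    pairs: Sequence[ReactionPair], train_fraction: float, seed: int
) -> tuple[list[ReactionPair], list[ReactionPair]]:
    """Random disjoint train/validation partition, deterministic given seed."""
    if not pairs:
        raise ValueError("no pairs to split")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    n_train = int(round(len(pairs) * train_fraction))
    n_train = min(max(n_train, 1), len(pairs) - 1)
    train = [pairs[i] for i in order[:n_train]]
    val = [pairs[i] for i in order[n_train:]]
    return train, val


class TranslationModel:
    """A trained reactant→product SMILES translator for one reaction class."""

    def __init__(
        self,
        reaction_class: ReactionClass,
        codec: SequenceCodec,
        config: ModelConfig,
        params: dict[str, np.ndarray],
        loss_history: list[float] | None = None,
    ):
        self.reaction_class = reaction_class
        self.codec = codec
        self.config = config
        self.params = params
        self.loss_history = loss_history or []

    # -- architecture -----------------------------------------------------

    @staticmethod
    def _position_features(T: int, P: int) -> np.ndarray:
        """Sinusoidal positional channels, (T, P); concatenated to inputs.

        Convolutions alone only see a narrow window, so attention needs an
        explicit notion of position to align repeated SMILES motifs.
        """
        pos = np.arange(T, dtype=nn.F32)[:, None]
        k = np.arange(P // 2, dtype=nn.F32)[None, :]
        angle = pos / (10000.0 ** (2.0 * k / P))
        out = np.empty((T, P), dtype=nn.F32)
        out[:, 0::2] = np.sin(angle)
        out[:, 1::2] = np.cos(angle)
        return out

    def _pos_bias(self) -> np.ndarray | None:
        if self.config.attention_prior_width <= 0:
            return None
        return nn.diagonal_prior(
            self.codec.max_length, self.config.attention_prior_width
        )

    def _embed(self, indices: np.ndarray) -> np.ndarray:
        """One-hot characters with positional channels appended."""
        B, T = indices.shape
        h = nn.one_hot(indices, self.codec.size)
        pos = self._position_features(T, self.config.position_dim)
        return np.concatenate(
            [h, np.broadcast_to(pos, (B, T, pos.shape[1]))], axis=-1
        )

    @staticmethod
    def _init_params(
        rng: np.random.Generator, V: int, cfg: ModelConfig
    ) -> dict[str, np.ndarray]:
        K, De, Dd, Dh = (
            cfg.kernel_size,
            cfg.encoder_latent_dim,
            cfg.decoder_latent_dim,
            cfg.output_hidden_dim,
        )
        Vin = V + cfg.position_dim
        p = {
            "We1": nn.glorot(rng, (K, Vin, De)), "be1": np.zeros(De, nn.F32),
            "We2": nn.glorot(rng, (K, De, De)), "be2": np.zeros(De, nn.F32),
            "We3": nn.glorot(rng, (K, De, De)), "be3": np.zeros(De, nn.F32),
            "Wd1": nn.glorot(rng, (K, Vin, Dd)), "bd1": np.zeros(Dd, nn.F32),
            "Wd2": nn.glorot(rng, (K, Dd, Dd)), "bd2": np.zeros(Dd, nn.F32),
            "Wd3": nn.glorot(rng, (K, Dd, Dd)), "bd3": np.zeros(Dd, nn.F32),
            "Wa": nn.glorot(rng, (Dd, De)),
            "Wo1": nn.glorot(rng, (K, Dd + De + V, Dh)),
            "bo1": np.zeros(Dh, nn.F32),
            "Wo2": nn.glorot(rng, (Dh, V)), "bo2": np.zeros(V, nn.F32),
        }
        return p

    def _encode_batch(self, x_enc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Run the three encoder convolutions; returns (states, pad mask).

        Layers two and three carry residual connections.
        """
        p = self.params
        d1_, d2_, d3_ = self.config.dilations
        h0 = self._embed(x_enc)
        z1, _ = nn.conv1d_forward(h0, p["We1"], p["be1"], False, d1_)
        h1 = nn.relu(z1)
        z2, _ = nn.conv1d_forward(h1, p["We2"], p["be2"], False, d2_)
        h2 = nn.relu(z2) + h1
        z3, _ = nn.conv1d_forward(h2, p["We3"], p["be3"], False, d3_)
        h3 = nn.relu(z3) + h2
        return h3, x_enc != 0

    def _decode_step_states(
        self,
        x_dec: np.ndarray,
        enc_states: np.ndarray,
        enc_mask: np.ndarray,
        enc_onehot: np.ndarray,
    ) -> np.ndarray:
        """Logits for every position given a (possibly partial) decoder input.

        The output layers see the decoder states, the attended encoder
        context, and a copy readout — the same attention weights applied
        to the raw one-hot encoder characters — so reproducing an input
        character only requires attending to the right position.
        """
        p = self.params
        d1_, d2_, d3_ = self.config.dilations
        h0 = self._embed(x_dec)
        z1, _ = nn.conv1d_forward(h0, p["Wd1"], p["bd1"], True, d1_)
        h1 = nn.relu(z1)
        z2, _ = nn.conv1d_forward(h1, p["Wd2"], p["bd2"], True, d2_)
        h2 = nn.relu(z2) + h1
        z3, _ = nn.conv1d_forward(h2, p["Wd3"], p["bd3"], True, d3_)
        h = nn.relu(z3) + h2
        context, cache = nn.attention_forward(
            h, enc_states, p["Wa"], enc_mask, pos_bias=self._pos_bias()
        )
        copy_readout = cache["attn"] @ enc_onehot
        u = np.concatenate([h, context, copy_readout], axis=-1)
        u, _ = nn.conv1d_forward(u, p["Wo1"], p["bo1"], causal=True)
        u = nn.relu(u)
        return u @ p["Wo2"] + p["bo2"]

    def _forward_backward(
        self,
        x_enc: np.ndarray,
        x_dec: np.ndarray,
        y: np.ndarray,
        drop_rng: np.random.Generator | None = None,
    ) -> tuple[float, dict[str, np.ndarray]]:
        """Training pass: loss and parameter gradients for one batch.

        With a dropout rate configured (and ``drop_rng`` supplied), inverted
        dropout is applied to the convolutional branch of every hidden
        layer; residual paths are left intact.
        """
        p = self.params
        V = self.codec.size
        enc_mask = x_enc != 0
        loss_mask = y != 0

        rate = self.config.dropout if drop_rng is not None else 0.0
        d1_, d2_, d3_ = self.config.dilations

        def drop_mask(shape):
            if rate <= 0.0:
                return None
            keep = 1.0 - rate
            return (
                drop_rng.random(shape) < keep
            ).astype(nn.F32) / nn.F32(keep)

        def dropped(h, mask):
            return h if mask is None else h * mask

        e0 = self._embed(x_enc)
        ze1, xpe1 = nn.conv1d_forward(e0, p["We1"], p["be1"], False, d1_)
        me1 = drop_mask(ze1.shape)
        e1 = dropped(nn.relu(ze1), me1)
        ze2, xpe2 = nn.conv1d_forward(e1, p["We2"], p["be2"], False, d2_)
        me2 = drop_mask(ze2.shape)
        e2 = dropped(nn.relu(ze2), me2) + e1
        ze3, xpe3 = nn.conv1d_forward(e2, p["We3"], p["be3"], False, d3_)
        me3 = drop_mask(ze3.shape)
        enc = dropped(nn.relu(ze3), me3) + e2

        d0 = self._embed(x_dec)
        zd1, xpd1 = nn.conv1d_forward(d0, p["Wd1"], p["bd1"], True, d1_)
        md1 = drop_mask(zd1.shape)
        d1 = dropped(nn.relu(zd1), md1)
        zd2, xpd2 = nn.conv1d_forward(d1, p["Wd2"], p["bd2"], True, d2_)
        md2 = drop_mask(zd2.shape)
        d2 = dropped(nn.relu(zd2), md2) + d1
        zd3, xpd3 = nn.conv1d_forward(d2, p["Wd3"], p["bd3"], True, d3_)
        md3 = drop_mask(zd3.shape)
        dec = dropped(nn.relu(zd3), md3) + d2

        context, attn_cache = nn.attention_forward(
            dec, enc, p["Wa"], enc_mask, pos_bias=self._pos_bias()
        )
        x_onehot = nn.one_hot(x_enc, V)
        copy_readout = attn_cache["attn"] @ x_onehot
        u0 = np.concatenate([dec, context, copy_readout], axis=-1)
        zo1, xpo1 = nn.conv1d_forward(u0, p["Wo1"], p["bo1"], causal=True)
        mo1 = drop_mask(zo1.shape)
        o1 = dropped(nn.relu(zo1), mo1)
        logits = o1 @ p["Wo2"] + p["bo2"]

        loss, dlogits = nn.masked_cross_entropy(logits, y, loss_mask)

        g: dict[str, np.ndarray] = {}
        Dh = o1.shape[-1]
        g["Wo2"] = o1.reshape(-1, Dh).T @ dlogits.reshape(-1, V)
        g["bo2"] = dlogits.sum(axis=(0, 1))
        do1 = dlogits @ p["Wo2"].T
        if mo1 is not None:
            do1 = do1 * mo1
        do1 = do1 * (zo1 > 0)
        du0, g["Wo1"], g["bo1"] = nn.conv1d_backward(do1, xpo1, p["Wo1"], True)
        Dd, De = dec.shape[-1], enc.shape[-1]
        ddec = du0[..., :Dd]
        dcontext = du0[..., Dd : Dd + De]
        dcopy = du0[..., Dd + De :]
        dattn_extra = dcopy @ x_onehot.transpose(0, 2, 1)
        ddec_a, denc, g["Wa"] = nn.attention_backward(
            dcontext, attn_cache, dattn_extra
        )
        d3 = ddec + ddec_a
        def gate(dh, z, mask):
            if mask is not None:
                dh = dh * mask
            return dh * (z > 0)

        dd2, g["Wd3"], g["bd3"] = nn.conv1d_backward(
            gate(d3, zd3, md3), xpd3, p["Wd3"], True, d3_
        )
        dd2 += d3  # residual skip
        dd1, g["Wd2"], g["bd2"] = nn.conv1d_backward(
            gate(dd2, zd2, md2), xpd2, p["Wd2"], True, d2_
        )
        dd1 += dd2
        _, g["Wd1"], g["bd1"] = nn.conv1d_backward(
            gate(dd1, zd1, md1), xpd1, p["Wd1"], True, d1_
        )

        de2, g["We3"], g["be3"] = nn.conv1d_backward(
            gate(denc, ze3, me3), xpe3, p["We3"], False, d3_
        )
        de2 += denc
        de1, g["We2"], g["be2"] = nn.conv1d_backward(
            gate(de2, ze2, me2), xpe2, p["We2"], False, d2_
        )
        de1 += de2
        _, g["We1"], g["be1"] = nn.conv1d_backward(
            gate(de1, ze1, me1), xpe1, p["We1"], False, d1_
        )
        return loss, g

    # -- training ----------------------------------------------------------

    @classmethod
    def train(
        cls,
        pairs: Sequence[ReactionPair],
        config: ModelConfig,
        codec: SequenceCodec | None = None,
        verbose: bool = False,
    ) -> "TranslationModel":
        """Fit the translator on reaction pairs of a single class.

        Pairs whose strings exceed the length cap are excluded with a
        warning.  Training is deterministic given ``config.seed``.
        """
        if not pairs:
            raise ConfigurationError("no training pairs")
        classes = {p.reaction_class for p in pairs}
        if len(classes) != 1:
            raise ConfigurationError("training pairs span multiple classes")
        reaction_class = classes.pop()
        if codec is None:
            codec = SequenceCodec.from_corpus(pairs, length_cap=config.max_length)
        usable = [
            p for p in pairs
            if codec.can_encode(p.reactant) and codec.can_encode(p.product)
        ]
        n_skipped = len(pairs) - len(usable)
        if n_skipped:
            log.warning("excluding %d pair(s) beyond the codec limits", n_skipped)
        if not usable:
            raise ConfigurationError("no pairs fit the codec")

        rng = np.random.default_rng(config.seed)
        model = cls(
            reaction_class,
            codec,
            config,
            cls._init_params(rng, codec.size, config),
        )
        x_enc = np.stack([codec.encode(p.reactant) for p in usable])
        x_dec = np.stack([codec.encode(p.product, with_start=True) for p in usable])
        y = np.stack([codec.encode(p.product) for p in usable])

        opt = nn.Adam(model.params, lr=config.learning_rate)
        n = len(usable)
        n_batches = math.ceil(n / config.batch_size)
        for epoch in range(config.epochs):
            if epoch < config.warmup_epochs:
                lr = config.learning_rate * (epoch + 1) / config.warmup_epochs
            elif config.lr_schedule == "cosine":
                frac = (epoch - config.warmup_epochs) / max(
                    config.epochs - config.warmup_epochs - 1, 1
                )
                lr = config.learning_rate * 0.5 * (1.0 + math.cos(math.pi * frac))
            else:
                lr = config.learning_rate
            order = rng.permutation(n)
            total = 0.0
            for b in range(n_batches):
                sel = order[b * config.batch_size : (b + 1) * config.batch_size]
                loss, grads = model._forward_backward(
                    x_enc[sel], x_dec[sel], y[sel],
                    drop_rng=rng if config.dropout > 0 else None,
                )
                if config.grad_clip_norm > 0:
                    nn.clip_global_norm(grads, config.grad_clip_norm)
                opt.step(
                    model.params, grads, lr=lr,
                    weight_decay=config.weight_decay,
                )
                total += loss * len(sel)
            model.loss_history.append(total / n)
            if verbose:
                log.info(
                    "epoch %d/%d loss %.4f",
                    epoch + 1, config.epochs, model.loss_history[-1],
                )
        return model

    # -- inference ---------------------------------------------------------

    def predict_many(self, reactants: Sequence[Molecule]) -> list[PredictionOutcome]:
        """Greedy autoregressive decoding for a batch of reactants.

        Reactants whose SMILES fall outside the codec alphabet yield
        invalid outcomes with an empty generated string.
        """
        encodable = [m for m in reactants if self.codec.can_encode(m.canonical_smiles)]
        outcomes: dict[int, PredictionOutcome] = {}
        for i, m in enumerate(reactants):
            if not self.codec.can_encode(m.canonical_smiles):
                outcomes[i] = PredictionOutcome(
                    reactant=m,
                    reaction_class=self.reaction_class,
                    generated_smiles="",
                    valid=False,
                )
        if encodable:
            texts = self._greedy_decode(
                [m.canonical_smiles for m in encodable]
            )
            it = iter(zip(encodable, texts))
            for i, m in enumerate(reactants):
                if i in outcomes:
                    continue
                mol, text = next(it)
                outcomes[i] = PredictionOutcome.from_generated(
                    mol, self.reaction_class, text
                )
        return [outcomes[i] for i in range(len(reactants))]

    def predict(self, reactant: Molecule) -> PredictionOutcome:
        return self.predict_many([reactant])[0]

    def _greedy_decode(self, smiles: Sequence[str]) -> list[str]:
        codec = self.codec
        T = codec.max_length
        x_enc = np.stack([codec.encode(s) for s in smiles])
        enc_states, enc_mask = self._encode_batch(x_enc)
        enc_onehot = nn.one_hot(x_enc, codec.size)
        B = len(smiles)
        x_dec = np.zeros((B, T), dtype=np.int64)
        x_dec[:, 0] = codec.char_to_index[START]
        end_idx = codec.char_to_index[END]
        finished = np.zeros(B, dtype=bool)
        for t in range(T - 1):
            logits = self._decode_step_states(
                x_dec, enc_states, enc_mask, enc_onehot
            )
            nxt = logits[:, t].argmax(axis=-1)
            nxt = np.where(finished, 0, nxt)
            x_dec[:, t + 1] = nxt
            finished |= nxt == end_idx
            if finished.all():
                break
        return [codec.decode(row[1:]) for row in x_dec]

    # -- serialization ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write a model bundle: weights.npz + codec.json + config.json."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savez(path / "weights.npz", **self.params)
        (path / "codec.json").write_text(
            json.dumps(self.codec.to_dict()), encoding="utf-8"
        )
        meta = {
            "format_version": _FORMAT_VERSION,
            "reaction_class": self.reaction_class.value,
            "config": asdict(self.config),
            "loss_history": self.loss_history,
        }
        (path / "config.json").write_text(json.dumps(meta), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "TranslationModel":
        path = Path(path)
        try:
            meta = json.loads((path / "config.json").read_text(encoding="utf-8"))
            codec = SequenceCodec.from_dict(
                json.loads((path / "codec.json").read_text(encoding="utf-8"))
            )
            with np.load(path / "weights.npz") as npz:
                params = {k: npz[k].astype(nn.F32) for k in npz.files}
        except Exception as exc:
            raise IncompatibleModelError(
                f"cannot load model bundle at {path}: {exc}"
            ) from exc
        if meta.get("format_version") != _FORMAT_VERSION:
            raise IncompatibleModelError(
                f"unsupported model format {meta.get('format_version')!r}"
            )
        cfg_dict = dict(meta["config"])
        if "dilations" in cfg_dict:
            cfg_dict["dilations"] = tuple(cfg_dict["dilations"])
        config = ModelConfig(**cfg_dict)
        expected = set(cls._init_params(
            np.random.default_rng(0), codec.size, config
        ))
        if set(params) != expected:
            raise IncompatibleModelError("weight file does not match architecture")
        return cls(
            ReactionClass.from_name(meta["reaction_class"]),
            codec,
            config,
            params,
            loss_history=list(meta.get("loss_history", [])),
        )


def save_model(model: TranslationModel, path: str | Path) -> None:
    model.save(path)


def load_model(path: str | Path) -> TranslationModel:
    return TranslationModel.load(path)


def train(
    pairs: Sequence[ReactionPair],
    config: ModelConfig,
    codec: SequenceCodec | None = None,
    verbose: bool = False,
) -> TranslationModel:
    """Module-level convenience wrapper around :meth:`TranslationModel.train`."""
    return TranslationModel.train(pairs, config, codec=codec, verbose=verbose)


def predict(model: TranslationModel, reactant: Molecule) -> PredictionOutcome:
    return model.predict(reactant)
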