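"""GRU sequence-to-sequence autoencoders for channel pretraining.

Each sequence channel (compound SMILES, protein SPS, optionally amino acid)
is pretrained on unlabeled sequences by reconstructing its own input: an
embedding + stacked-GRU encoder maps the token sequence to per-position
outputs and a fixed-dimension "thought vector", and a GRU decoder with
additive attention over the encoder outputs reproduces the sequence under
teacher forcing.  The trained embedding and encoder weights then warm-start
the unified regression model.

Defaults follow the channel conventions used throughout the package: 2 GRU
layers, latent and embedding dimension 128 for compounds and 256 for
proteins, dropout 0.2 between layers, batch size 64.  Pretraining defaults
to Adam at 1e-3; a plain-SGD scheme with initial rate 0.5 decayed by 0.99
per epoch is selectable instead.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .vocab import TokenSequence, Vocabulary


@dataclass(frozen=True)
class EncoderConfig:
    vocab_size: int
    dim: int = 128              # latent == embedding dimension
    layers: int = 2
    dropout: float = 0.2
    bidirectional: bool = False
    attention_dim: int = 64

    @property
    def out_dim(self) -> int:
        return self.dim * (2 if self.bidirectional else 1)


@dataclass(frozen=True)
class PretrainConfig:
    epochs: int = 100
    batch_size: int = 64
    learning_rate: float = 1e-3
    scheme: str = "adam"        # "adam" | "sgd-decay"
    sgd_decay: float = 0.99
    grad_clip: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.scheme not in ("adam", "sgd-decay"):
            raise ValueError(f"unknown optimization scheme {self.scheme!r}")


def sequences_to_ids(seqs: Sequence[TokenSequence]) -> np.ndarray:
    return np.array([s.indices for s in seqs], dtype=np.intp)


def trim_to_longest(ids: np.ndarray, pad_id: int) -> np.ndarray:
    """Drop all-pad tail columns (padding never carries information)."""
    real = ids != pad_id
    longest = int(real.sum(axis=1).max())
    return ids[:, :longest]


# ---------------------------------------------------------------------------
# encoder
# ---------------------------------------------------------------------------

def init_encoder(params: nn.Params, prefix: str, cfg: EncoderConfig,
                 rng: np.random.Generator) -> None:
    nn.init_embedding(params, f"{prefix}.emb", rng, cfg.vocab_size, cfg.dim)
    nn.init_stacked_gru(params, f"{prefix}.enc", rng, cfg.dim, cfg.dim,
                        cfg.layers, cfg.bidirectional)
    nn.init_linear(params, f"{prefix}.thought", rng,
                   cfg.layers * cfg.out_dim, cfg.dim)


def encode(params: nn.Params, prefix: str, cfg: EncoderConfig, ids: np.ndarray,
           pad_id: int, train: bool = False,
           rng: np.random.Generator | None = None) -> tuple[list[Tensor], Tensor, np.ndarray]:
    """Run the channel encoder over a (batch, T) id matrix.

    Returns (per-position outputs, thought vector, 0/1 mask).  Outputs at
    padded positions are zero and the thought vector is read at each
    sequence's own last real token, so padding never changes the result.
    """
    batch, length = ids.shape
    mask = (ids != pad_id).astype(np.float64)
    flat = nn.embedding(params, f"{prefix}.emb", ids.ravel())
    xs = [ad.take_rows(flat, np.arange(batch) * length + t) for t in range(length)]
    dropout = cfg.dropout if train else 0.0
    outputs, finals = nn.stacked_gru(params, f"{prefix}.enc", xs, mask, cfg.dim,
                                     cfg.layers, cfg.bidirectional,
                                     dropout=dropout, rng=rng)
    thought = nn.linear(params, f"{prefix}.thought", ad.concat(finals, axis=1))
    return outputs, thought, mask


# ---------------------------------------------------------------------------
# decoder (pretraining only)
# ---------------------------------------------------------------------------

def init_decoder(params: nn.Params, prefix: str, cfg: EncoderConfig,
                 rng: np.random.Generator) -> None:
    nn.init_embedding(params, f"{prefix}.dec_emb", rng, cfg.vocab_size, cfg.dim)
    nn.init_stacked_gru(params, f"{prefix}.dec", rng, cfg.dim + cfg.out_dim,
                        cfg.dim, cfg.layers)
    nn.init_linear(params, f"{prefix}.dec_init", rng, cfg.dim, cfg.layers * cfg.dim)
    # additive cross-attention: score = v . tanh(Wq q + Wk k)
    a = cfg.attention_dim
    nn.init_linear(params, f"{prefix}.att_q", rng, cfg.dim, a)
    nn.init_linear(params, f"{prefix}.att_k", rng, cfg.out_dim, a, bias=False)
    params[f"{prefix}.att_v"] = Tensor(nn.glorot(rng, a, 1).ravel(), requires_grad=True)
    nn.init_linear(params, f"{prefix}.out", rng, cfg.dim + cfg.out_dim, cfg.vocab_size)


def _cross_attention(params: nn.Params, prefix: str, query: Tensor,
                     keys3: Tensor, kproj3: Tensor, mask: np.ndarray) -> Tensor:
    """Additive attention of one decoder state over all encoder outputs."""
    batch, length, _ = keys3.shape
    q = nn.linear(params, f"{prefix}.att_q", query)              # (B, A)
    q3 = ad.reshape(q, (batch, 1, -1))
    scored = ad.tanh(ad.add(kproj3, q3))                         # (B, T, A)
    v = ad.reshape(params[f"{prefix}.att_v"], (1, 1, -1))
    scores = ad.sum_(ad.mul(scored, v), axis=2)                  # (B, T)
    alpha = ad.softmax(scores, axis=1, mask=mask)
    alpha3 = ad.reshape(alpha, (batch, length, 1))
    return ad.sum_(ad.mul(alpha3, keys3), axis=1)                # (B, out_dim)


def decode_teacher_forced(params: nn.Params, prefix: str, cfg: EncoderConfig,
                          enc_outputs: list[Tensor], thought: Tensor,
                          enc_mask: np.ndarray, target_ids: np.ndarray,
                          pad_id: int) -> Tensor:
    """Teacher-forced decoding; returns logits of shape (B*(T-1), vocab).

    Position t's logits predict ``target_ids[:, t+1]`` from the gold prefix
    ``target_ids[:, :t+1]`` (row pattern: start, tokens..., end, pad...).
    """
    batch, length = target_ids.shape
    keys3 = ad.reshape(ad.concat(enc_outputs, axis=1), (batch, length, cfg.out_dim))
    kproj3 = ad.reshape(
        nn.linear(params, f"{prefix}.att_k",
                  ad.reshape(keys3, (batch * length, cfg.out_dim))),
        (batch, length, cfg.attention_dim))
    init = nn.linear(params, f"{prefix}.dec_init", thought)
    hidden = [ad.take_rows(ad.reshape(init, (batch * cfg.layers, cfg.dim)),
                           np.arange(batch) * cfg.layers + layer)
              for layer in range(cfg.layers)]
    flat_emb = nn.embedding(params, f"{prefix}.dec_emb", target_ids.ravel())
    step_logits: list[Tensor] = []
    for t in range(length - 1):
        x = ad.take_rows(flat_emb, np.arange(batch) * length + t)
        context = _cross_attention(params, prefix, hidden[-1], keys3, kproj3, enc_mask)
        x = ad.concat([x, context], axis=1)
        for layer in range(cfg.layers):
            hidden[layer] = nn.gru_cell(params, f"{prefix}.dec.l{layer}.fwd",
                                        x if layer == 0 else hidden[layer - 1],
                                        hidden[layer])
        out_in = ad.concat([hidden[-1], context], axis=1)
        step_logits.append(nn.linear(params, f"{prefix}.out", out_in))
    return ad.concat(step_logits, axis=0)  # (B*(T-1), vocab), time-major blocks


def _target_layout(target_ids: np.ndarray, pad_id: int) -> tuple[np.ndarray, np.ndarray]:
    """Flatten targets to match decoder logits (time-major blocks of batch)."""
    targets = target_ids[:, 1:].T.ravel()          # predict from position 1 on
    real = (targets != pad_id)
    return targets, real


def reconstruction_loss(params: nn.Params, prefix: str, cfg: EncoderConfig,
                        ids: np.ndarray, pad_id: int, train: bool = False,
                        rng: np.random.Generator | None = None) -> tuple[Tensor, float]:
    """Masked cross-entropy of teacher-forced self-reconstruction.

    Returns (loss tensor, token accuracy) for one batch.
    """
    enc_out, thought, mask = encode(params, prefix, cfg, ids, pad_id, train, rng)
    logits = decode_teacher_forced(params, prefix, cfg, enc_out, thought, mask,
                                   ids, pad_id)
    targets, real = _target_layout(ids, pad_id)
    n_real = int(real.sum())
    logp = ad.log_softmax(logits, axis=1)
    onehot = np.zeros(logits.shape)
    onehot[np.arange(targets.size), targets] = 1.0
    onehot *= real[:, None]
    loss = ad.mul(ad.sum_(ad.mul(logp, Tensor(onehot))), -1.0 / max(n_real, 1))
    predicted = logits.data.argmax(axis=1)
    accuracy = float((predicted[real] == targets[real]).mean()) if n_real else 0.0
    return loss, accuracy


def reconstruction_accuracy(params: nn.Params, prefix: str, cfg: EncoderConfig,
                            corpus: Sequence[TokenSequence], pad_id: int,
                            batch_size: int = 64) -> float:
    """Fraction of real tokens greedily reconstructed under teacher forcing."""
    if len(corpus) == 0:
        raise ValueError("empty corpus")
    ids_all = sequences_to_ids(corpus)
    correct = total = 0
    for lo in range(0, len(corpus), batch_size):
        ids = trim_to_longest(ids_all[lo:lo + batch_size], pad_id)
        enc_out, thought, mask = encode(params, prefix, cfg, ids, pad_id)
        logits = decode_teacher_forced(params, prefix, cfg, enc_out, thought,
                                       mask, ids, pad_id)
        targets, real = _target_layout(ids, pad_id)
        predicted = logits.data.argmax(axis=1)
        correct += int((predicted[real] == targets[real]).sum())
        total += int(real.sum())
    return correct / max(total, 1)


# ---------------------------------------------------------------------------
# pretraining loop
# ---------------------------------------------------------------------------

def init_autoencoder(cfg: EncoderConfig, seed: int, prefix: str = "ae") -> nn.Params:
    rng = np.random.default_rng(seed)
    params: nn.Params = {}
    init_encoder(params, prefix, cfg, rng)
    init_decoder(params, prefix, cfg, rng)
    return params


def pretrain(corpus: Sequence[TokenSequence], vocab: Vocabulary,
             enc_cfg: EncoderConfig, cfg: PretrainConfig,
             prefix: str = "ae",
             params: nn.Params | None = None) -> tuple[nn.Params, list[dict]]:
    """Train the channel autoencoder on an unlabeled corpus.

    Returns the trained parameters and a per-epoch history of mean
    reconstruction loss and token accuracy.  Fully deterministic under
    ``cfg.seed``.
    """
    if len(corpus) == 0:
        raise ValueError("empty corpus")
    if enc_cfg.vocab_size != vocab.size:
        raise ValueError("encoder config does not match vocabulary size")
    if params is None:
        params = init_autoencoder(enc_cfg, cfg.seed, prefix)
    rng = np.random.default_rng(cfg.seed + 1)
    if cfg.scheme == "adam":
        opt: nn.Adam | nn.DecayedSGD = nn.Adam(params, lr=cfg.learning_rate)
    else:
        opt = nn.DecayedSGD(params, lr=cfg.learning_rate, decay=cfg.sgd_decay)
    ids_all = sequences_to_ids(corpus)
    history: list[dict] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(corpus))
        losses: list[float] = []
        accs: list[float] = []
        for lo in range(0, len(corpus), cfg.batch_size):
            ids = trim_to_longest(ids_all[order[lo:lo + cfg.batch_size]], vocab.pad_id)
            loss, acc = reconstruction_loss(params, prefix, enc_cfg, ids,
                                            vocab.pad_id, train=True, rng=rng)
            opt.zero_grad()
            loss.backward()
            nn.clip_gradients(params, cfg.grad_clip)
            opt.step()
            losses.append(float(loss.data))
            accs.append(acc)
        if isinstance(opt, nn.DecayedSGD):
            opt.end_epoch()
        history.append({"epoch": epoch + 1, "loss": float(np.mean(losses)),
                        "token_accuracy": float(np.mean(accs))})
    return params, history


def pretrain_manifest(vocab: Vocabulary, enc_cfg: EncoderConfig,
                      cfg: PretrainConfig, prefix: str) -> dict:
    import hashlib
    vocab_hash = hashlib.sha256("\n".join(vocab.symbols).encode()).hexdigest()[:16]
    return {"kind": vocab.kind, "vocab_hash": vocab_hash, "prefix": prefix,
            "encoder": asdict(enc_cfg), "pretrain": asdict(cfg)}
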