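"""The unified three-channel affinity regressor.

Architecture (per enabled channel):

* ``smiles`` — embedding + 2-layer GRU encoder over SMILES tokens, additive
  attention weights over positions, a 1-D convolution with global max
  pooling over the attention-weighted outputs.
* ``sps``    — the same stack over protein structural-property words.
* ``amino``  — optional bidirectional-GRU stack over raw residues (the
  four-channel model variant).
* ``graph``  — degree-filtered graph convolution over the 2-D molecular
  graph followed by additive attention pooling of atom states.

The compound vector is the concatenation of the SMILES and graph channel
vectors, the protein vector the concatenation of SPS (and amino) vectors;
a fully connected head maps their concatenation to a single affinity on the
log10-IC50 scale.  Training minimises mean squared error end to end, with
the sequence channels optionally warm-started from pretrained autoencoders.

Channel subsets are first-class: ``{"sps", "graph"}`` reproduces a
two-channel ablation, ``{"smiles", "sps", "graph"}`` is the standard
three-channel model and adding ``"amino"`` gives the four-channel variant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .dataset import CPIDataset, CPISample
from .molgraph import (ATOM_FEATURE_DIM, N_DEGREE_FILTERS, MolecularGraph,
                       clamp_degree, parse_smiles)
from .seq2seq import EncoderConfig, encode, sequences_to_ids, trim_to_longest
from .vocab import Vocabulary, tokenize

COMPOUND_CHANNELS = ("smiles", "graph")
PROTEIN_CHANNELS = ("sps", "amino")
ALL_CHANNELS = ("smiles", "sps", "graph", "amino")


@dataclass(frozen=True)
class ModelConfig:
    """Channel selection plus every width/kernel knob of the unified model."""

    channels: tuple[str, ...] = ("smiles", "sps", "graph")
    smiles_dim: int = 128
    sps_dim: int = 256
    amino_dim: int = 256
    graph_hidden: int = 128
    graph_radius: int = 3
    layers: int = 2
    dropout: float = 0.2
    conv_filters: int = 64
    conv_kernel: int = 4
    attention_dim: int = 64
    head_hidden: int = 512
    max_smiles_len: int = 100
    max_sps_len: int = 152
    max_amino_len: int = 512

    def __post_init__(self):
        for ch in self.channels:
            if ch not in ALL_CHANNELS:
                raise ValueError(f"unknown channel {ch!r}")
        # canonical order keeps fusion layout (sequence part first) stable
        object.__setattr__(self, "channels",
                           tuple(ch for ch in ALL_CHANNELS if ch in self.channels))
        if not any(ch in self.channels for ch in COMPOUND_CHANNELS):
            raise ValueError("at least one compound channel required")
        if not any(ch in self.channels for ch in PROTEIN_CHANNELS):
            raise ValueError("at least one protein channel required")

    def encoder_config(self, channel: str, vocab_size: int) -> EncoderConfig:
        dim = {"smiles": self.smiles_dim, "sps": self.sps_dim,
               "amino": self.amino_dim}[channel]
        return EncoderConfig(vocab_size=vocab_size, dim=dim, layers=self.layers,
                             dropout=self.dropout,
                             bidirectional=(channel == "amino"),
                             attention_dim=self.attention_dim)

    def max_len(self, channel: str) -> int:
        return {"smiles": self.max_smiles_len, "sps": self.max_sps_len,
                "amino": self.max_amino_len}[channel]


@dataclass
class UnifiedModel:
    """Parameters + configuration + vocabularies of the unified regressor."""

    config: ModelConfig
    vocabs: dict[str, Vocabulary]
    params: nn.Params

    # -- construction ----------------------------------------------------
    @classmethod
    def initialize(cls, config: ModelConfig, vocabs: dict[str, Vocabulary],
                   seed: int, warm: nn.Params | None = None,
                   warm_prefixes: dict[str, str] | None = None) -> "UnifiedModel":
        """Create a model; ``warm`` optionally carries pretrained autoencoder
        parameters whose embedding/encoder weights seed the sequence channels.

        ``warm_prefixes`` maps channel name -> prefix of that channel's
        parameters inside ``warm`` (e.g. ``{"smiles": "ae_smiles"}``).
        """
        rng = np.random.default_rng(seed)
        params: nn.Params = {}
        cfg = config
        for channel in cfg.channels:
            if channel == "graph":
                continue
            enc_cfg = cfg.encoder_config(channel, vocabs[channel].size)
            from .seq2seq import init_encoder
            init_encoder(params, channel, enc_cfg, rng)
            nn.init_additive_attention(params, f"{channel}.att", rng,
                                       enc_cfg.out_dim, cfg.attention_dim)
            nn.init_conv1d(params, f"{channel}.conv", rng, enc_cfg.out_dim,
                           cfg.conv_filters, cfg.conv_kernel)
        if "graph" in cfg.channels:
            nn.init_linear(params, "graph.proj", rng, ATOM_FEATURE_DIM, cfg.graph_hidden)
            scale = 1.0 / np.sqrt(cfg.graph_hidden)
            for layer in range(cfg.graph_radius):
                for n in range(N_DEGREE_FILTERS):
                    params[f"graph.H{layer}_{n}"] = Tensor(
                        rng.normal(0.0, scale, size=(cfg.graph_hidden, cfg.graph_hidden)),
                        requires_grad=True)
            nn.init_additive_attention(params, "graph.att", rng,
                                       cfg.graph_hidden, cfg.attention_dim)
        head_in = 0
        for channel in cfg.channels:
            head_in += cfg.graph_hidden if channel == "graph" else cfg.conv_filters
        nn.init_linear(params, "head.fc1", rng, head_in, cfg.head_hidden)
        nn.init_linear(params, "head.fc2", rng, cfg.head_hidden, 1)
        model = cls(config=cfg, vocabs=dict(vocabs), params=params)
        if warm:
            model.load_warm(warm, warm_prefixes or {})
        return model

    def load_warm(self, warm: nn.Params, prefixes: dict[str, str]) -> list[str]:
        """Copy pretrained embedding/encoder weights into matching channels.

        Only keys that exist in this model (``<channel>.emb.*`` and
        ``<channel>.enc.*``) are copied; decoder-side parameters are ignored.
        Returns the list of copied keys.
        """
        copied: list[str] = []
        for channel, src_prefix in prefixes.items():
            if channel not in self.config.channels:
                continue
            for key, value in warm.items():
                if not key.startswith(src_prefix + "."):
                    continue
                suffix = key[len(src_prefix) + 1:]
                if not (suffix.startswith("emb.") or suffix.startswith("enc.")):
                    continue
                dest = f"{channel}.{suffix}"
                if dest in self.params:
                    if self.params[dest].data.shape != value.data.shape:
                        raise ValueError(f"warm-start shape mismatch at {dest}")
                    self.params[dest] = Tensor(value.data.copy(), requires_grad=True)
                    copied.append(dest)
        return copied

    # -- feature preparation --------------------------------------------
    def prepare(self, samples: Sequence[CPISample]) -> "PreparedBatchSource":
        """Tokenize/parse every sample once; reused across epochs."""
        cfg = self.config
        data: dict[str, np.ndarray] = {}
        for channel in cfg.channels:
            if channel == "graph":
                continue
            vocab = self.vocabs[channel]
            seqs = []
            for s in samples:
                s.require_channels([channel])
                raw = {"smiles": s.smiles, "sps": list(s.sps), "amino": s.amino}[channel]
                seqs.append(tokenize(raw, vocab, cfg.max_len(channel)))
            data[channel] = sequences_to_ids(seqs)
        graphs: list[MolecularGraph] | None = None
        if "graph" in cfg.channels:
            graphs = []
            for s in samples:
                s.require_channels(["graph"])
                graphs.append(parse_smiles(s.smiles))
        labels = np.array([s.label for s in samples], dtype=float)
        return PreparedBatchSource(ids=data, graphs=graphs, labels=labels,
                                  pad_ids={ch: self.vocabs[ch].pad_id
                                           for ch in data})

    # -- forward ---------------------------------------------------------
    def _sequence_channel(self, channel: str, ids: np.ndarray, train: bool,
                          rng: np.random.Generator | None) -> Tensor:
        cfg = self.config
        vocab = self.vocabs[channel]
        enc_cfg = cfg.encoder_config(channel, vocab.size)
        ids = trim_to_longest(ids, vocab.pad_id)
        if ids.shape[1] < cfg.conv_kernel:
            # very short sequences: pad so one (zero-tailed) conv window exists
            extra = np.full((ids.shape[0], cfg.conv_kernel - ids.shape[1]),
                            vocab.pad_id, dtype=ids.dtype)
            ids = np.concatenate([ids, extra], axis=1)
        batch, length = ids.shape
        outputs, _, mask = encode(self.params, channel, enc_cfg, ids,
                                  vocab.pad_id, train=train, rng=rng)
        flat = ad.concat(outputs, axis=0)  # (T*B, H), time-major blocks
        # additive attention over positions (mask excludes padding)
        scores = nn.attention_scores(self.params, f"{channel}.att", flat)
        scores_bt = ad.reshape(scores, (length, batch))  # time-major
        alpha = ad.softmax(scores_bt, axis=0, mask=mask.T)
        weighted = ad.mul(flat, ad.reshape(alpha, (length * batch, 1)))
        # back to batch-major (B*T, H) for convolution
        order = (np.arange(batch)[:, None] + np.arange(length)[None, :] * batch).ravel()
        weighted_bm = ad.take_rows(weighted, order)
        conv_out, out_len = nn.conv1d(self.params, f"{channel}.conv", weighted_bm,
                                      batch, length, cfg.conv_kernel)
        conv_out = ad.relu(conv_out)
        # mask conv windows that extend past each sequence's real length
        lengths = mask.sum(axis=1).astype(int)  # includes start/end
        # windows fully inside the real tokens; sequences shorter than the
        # kernel keep their first (zero-tailed) window so pooling stays finite
        last_ok = np.maximum(lengths - cfg.conv_kernel, 0)
        window_ok = (np.arange(out_len)[None, :] <= last_ok[:, None])
        penalty = (window_ok.astype(float) - 1.0)[:, :, None] * 1e9
        conv3 = ad.reshape(conv_out, (batch, out_len, cfg.conv_filters))
        return ad.max_(ad.add(conv3, Tensor(penalty)), axis=1)  # (B, filters)

    def _graph_channel(self, graphs: Sequence[MolecularGraph]) -> Tensor:
        cfg = self.config
        counts = [g.atom_count for g in graphs]
        total = int(sum(counts))
        offsets = np.concatenate([[0], np.cumsum(counts)])
        adj = np.zeros((total, total))
        membership = np.zeros((len(graphs), total))
        degree_mask = np.zeros((N_DEGREE_FILTERS, total, 1))
        features = np.concatenate([g.atom_features for g in graphs], axis=0)
        for gi, g in enumerate(graphs):
            off = offsets[gi]
            membership[gi, off:off + counts[gi]] = 1.0
            for a, nbrs in enumerate(g.neighbors):
                degree_mask[clamp_degree(len(nbrs)) - 1, off + a, 0] = 1.0
                for u in nbrs:
                    adj[off + a, off + u] = 1.0
        r = nn.linear(self.params, "graph.proj", Tensor(features))
        adj_t = Tensor(adj)
        for layer in range(cfg.graph_radius):
            v = ad.add(r, ad.matmul(adj_t, r))
            mixed: Tensor | None = None
            for n in range(N_DEGREE_FILTERS):
                if not degree_mask[n].any():
                    continue
                term = ad.mul(ad.matmul(v, self.params[f"graph.H{layer}_{n}"]),
                              Tensor(degree_mask[n]))
                mixed = term if mixed is None else ad.add(mixed, term)
            r = ad.relu(mixed)
        # attention pooling per molecule (segment softmax over own atoms)
        scores = nn.attention_scores(self.params, "graph.att", r)  # (total, 1)
        shift = np.array([scores.data[offsets[i]:offsets[i + 1]].max()
                          for i in range(len(graphs))])
        shift_per_atom = np.repeat(shift, counts)[:, None]
        z = ad.exp(ad.add(scores, Tensor(-shift_per_atom)))
        memb = Tensor(membership)
        denom_atom = ad.matmul(Tensor(membership.T), ad.matmul(memb, z))
        alpha = ad.mul(z, ad.power(denom_atom, -1.0))
        return ad.matmul(memb, ad.mul(alpha, r))  # (B, hidden)

    def forward_batch(self, ids: dict[str, np.ndarray],
                      graphs: Sequence[MolecularGraph] | None,
                      train: bool = False,
                      rng: np.random.Generator | None = None) -> Tensor:
        """Predict affinities for a prepared batch; returns a (B, 1) tensor."""
        cfg = self.config
        compound_parts: list[Tensor] = []
        protein_parts: list[Tensor] = []
        for channel in cfg.channels:  # fixed order: smiles, sps, graph, amino
            if channel == "graph":
                compound_parts.append(self._graph_channel(graphs))
            else:
                vec = self._sequence_channel(channel, ids[channel], train, rng)
                (compound_parts if channel in COMPOUND_CHANNELS
                 else protein_parts).append(vec)
        fused = ad.concat(compound_parts + protein_parts, axis=1)
        h = ad.relu(nn.linear(self.params, "head.fc1", fused))
        if train and rng is not None and cfg.dropout > 0:
            h = nn.dropout_apply(h, cfg.dropout, rng)
        return nn.linear(self.params, "head.fc2", h)

    def predict(self, samples: Sequence[CPISample],
                batch_size: int = 64) -> np.ndarray:
        """Deterministic (evaluation-mode) predictions for a list of samples."""
        source = self.prepare(samples)
        out: list[np.ndarray] = []
        for batch in source.batches(batch_size):
            pred = self.forward_batch(batch.ids, batch.graphs, train=False)
            out.append(pred.data.ravel())
        return np.concatenate(out)

    def predict_one(self, sample: CPISample) -> float:
        return float(self.predict([sample])[0])

    def screening_predictor(self, protein_sps: Sequence[str],
                            amino: str | None = None):
        """Bind one protein; returns a SMILES -> predicted-affinity callable."""
        def predict(smiles: str) -> float:
            sample = CPISample(smiles=smiles, sps=tuple(protein_sps),
                               amino=amino, label=0.0)
            return self.predict_one(sample)
        return predict

    # -- persistence -----------------------------------------------------
    def save(self, directory: str | Path) -> None:
        manifest = {
            "config": asdict(self.config),
            "vocabs": {ch: {"kind": v.kind, "symbols": list(v.non_special())}
                       for ch, v in self.vocabs.items()},
        }
        nn.save_params(self.params, directory, manifest)

    @classmethod
    def load(cls, directory: str | Path) -> "UnifiedModel":
        params, manifest = nn.load_params(directory)
        cfg_dict = dict(manifest["config"])
        cfg_dict["channels"] = tuple(cfg_dict["channels"])
        config = ModelConfig(**cfg_dict)
        vocabs = {ch: Vocabulary.from_symbols(spec["symbols"], spec["kind"])
                  for ch, spec in manifest["vocabs"].items()}
        return cls(config=config, vocabs=vocabs, params=params)


@dataclass
class PreparedBatch:
    ids: dict[str, np.ndarray]
    graphs: list[MolecularGraph] | None
    labels: np.ndarray


@dataclass
class PreparedBatchSource:
    """Pre-tokenized dataset; slices into mini-batches by index."""

    ids: dict[str, np.ndarray]
    graphs: list[MolecularGraph] | None
    labels: np.ndarray
    pad_ids: dict[str, int]

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, index: np.ndarray) -> PreparedBatch:
        return PreparedBatch(
            ids={ch: arr[index] for ch, arr in self.ids.items()},
            graphs=[self.graphs[i] for i in index] if self.graphs is not None else None,
            labels=self.labels[index])

    def batches(self, batch_size: int, order: np.ndarray | None = None):
        if order is None:
            order = np.arange(len(self))
        for lo in range(0, len(order), batch_size):
            yield self.subset(order[lo:lo + batch_size])


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    batch_size: int = 64
    learning_rate: float = 1e-4
    grad_clip: float = 5.0
    seed: int = 0


def train_unified(model: UnifiedModel, train: CPIDataset, val: CPIDataset | None,
                  cfg: TrainConfig) -> tuple[nn.Params, list[dict]]:
    """End-to-end MSE training; returns (best parameters, per-epoch history).

    "Best" means lowest validation RMSE (training RMSE when no validation
    set is given); the returned parameters are a copy, and ``model.params``
    is left at the best state as well.  Seeded and reproducible.
    """
    if len(train) == 0:
        raise ValueError("empty training set")
    source = model.prepare(train.samples)
    val_samples = val.samples if val is not None and len(val) > 0 else None
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(model.params, lr=cfg.learning_rate)
    history: list[dict] = []
    best_rmse = np.inf
    best_params = nn.copy_params(model.params)
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(source))
        sq_err_sum = 0.0
        for batch in source.batches(cfg.batch_size, order):
            pred = model.forward_batch(batch.ids, batch.graphs, train=True, rng=rng)
            err = ad.add(pred, Tensor(-batch.labels[:, None]))
            loss = ad.mean(ad.mul(err, err))
            opt.zero_grad()
            loss.backward()
            nn.clip_gradients(model.params, cfg.grad_clip)
            opt.step()
            sq_err_sum += float(loss.data) * len(batch.labels)
        train_rmse = float(np.sqrt(sq_err_sum / len(source)))
        record = {"epoch": epoch + 1, "train_loss": train_rmse ** 2,
                  "train_rmse": train_rmse}
        if val_samples is not None:
            val_pred = model.predict(val_samples, cfg.batch_size)
            val_rmse = float(np.sqrt(np.mean((val_pred - np.array(
                [s.label for s in val_samples])) ** 2)))
            record["val_loss"] = val_rmse ** 2
            record["val_rmse"] = val_rmse
            monitor = val_rmse
        else:
            monitor = train_rmse
        if monitor < best_rmse:
            best_rmse = monitor
            best_params = nn.copy_params(model.params)
        history.append(record)
    model.params = best_params
    return best_params, history


def history_to_csv(history: list[dict], path: str | Path) -> None:
    import csv
    keys = sorted({k for row in history for k in row}, key=lambda k: (k != "epoch", k))
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=keys)
        writer.writeheader()
        writer.writerows(history)
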