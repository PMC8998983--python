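"""Neural-network building blocks: linear/embedding layers, stacked (bi)GRUs,
additive attention, 1-D convolution, dropout, and the Adam / decayed-SGD
optimizers, all on the :mod:`cpinet.autodiff` tape.

Parameters live in a flat ``dict[str, Tensor]`` so a whole model can be
checkpointed, diffed and warm-started by key.  Every initializer draws from an
explicit :class:`numpy.random.Generator`; there is no hidden global state.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

Params = dict[str, Tensor]
Array = np.ndarray


# ---------------------------------------------------------------------------
# initialisation
# ---------------------------------------------------------------------------

def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> Array:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=(fan_in, fan_out))


def init_linear(params: Params, name: str, rng: np.random.Generator,
                fan_in: int, fan_out: int, bias: bool = True) -> None:
    params[f"{name}.W"] = Tensor(glorot(rng, fan_in, fan_out), requires_grad=True)
    if bias:
        params[f"{name}.b"] = Tensor(np.zeros(fan_out), requires_grad=True)


def linear(params: Params, name: str, x: Tensor) -> Tensor:
    y = ad.matmul(x, params[f"{name}.W"])
    b = params.get(f"{name}.b")
    return ad.add(y, b) if b is not None else y


def init_embedding(params: Params, name: str, rng: np.random.Generator,
                   vocab_size: int, dim: int) -> None:
    params[f"{name}.E"] = Tensor(rng.normal(0.0, 0.1, size=(vocab_size, dim)),
                                 requires_grad=True)


def embedding(params: Params, name: str, token_ids: Array) -> Tensor:
    """Look up rows for a flat int array of token ids -> (len(ids), dim)."""
    return ad.take_rows(params[f"{name}.E"], np.asarray(token_ids, dtype=np.intp))


# ---------------------------------------------------------------------------
# GRU
# ---------------------------------------------------------------------------

def init_gru_cell(params: Params, name: str, rng: np.random.Generator,
                  in_dim: int, hidden: int) -> None:
    for gate in ("z", "r", "n"):
        params[f"{name}.W{gate}"] = Tensor(glorot(rng, in_dim, hidden), requires_grad=True)
        params[f"{name}.U{gate}"] = Tensor(glorot(rng, hidden, hidden), requires_grad=True)
        params[f"{name}.b{gate}"] = Tensor(np.zeros(hidden), requires_grad=True)


def gru_cell(params: Params, name: str, x: Tensor, h: Tensor) -> Tensor:
    z = ad.sigmoid(ad.add(ad.add(ad.matmul(x, params[f"{name}.Wz"]),
                                 ad.matmul(h, params[f"{name}.Uz"])),
                          params[f"{name}.bz"]))
    r = ad.sigmoid(ad.add(ad.add(ad.matmul(x, params[f"{name}.Wr"]),
                                 ad.matmul(h, params[f"{name}.Ur"])),
                          params[f"{name}.br"]))
    n = ad.tanh(ad.add(ad.add(ad.matmul(x, params[f"{name}.Wn"]),
                              ad.mul(r, ad.matmul(h, params[f"{name}.Un"]))),
                       params[f"{name}.bn"]))
    one_minus_z = ad.add(ad.mul(z, -1.0), 1.0)
    return ad.add(ad.mul(one_minus_z, n), ad.mul(z, h))


def gru_layer(params: Params, name: str, xs: Sequence[Tensor], mask: Array,
              hidden: int, reverse: bool = False) -> tuple[list[Tensor], Tensor]:
    """Run one GRU direction over a padded batch.

    ``xs`` is a length-T list of (B, D) tensors, ``mask`` a constant (B, T)
    0/1 array marking real positions.  Masked steps carry the previous hidden
    state forward, so the returned final state is the state at each sequence's
    own last real token and is unaffected by the amount of padding.
    """
    batch = xs[0].shape[0]
    h = Tensor(np.zeros((batch, hidden)))
    outputs: list[Tensor | None] = [None] * len(xs)
    order = range(len(xs) - 1, -1, -1) if reverse else range(len(xs))
    for t in order:
        h_new = gru_cell(params, name, xs[t], h)
        m = Tensor(mask[:, t:t + 1])
        keep = Tensor(1.0 - mask[:, t:t + 1])
        h = ad.add(ad.mul(m, h_new), ad.mul(keep, h))
        outputs[t] = ad.mul(h, m)  # zero padded slots in per-position outputs
    return outputs, h  # final h = state at last (first, if reverse) real token


def init_stacked_gru(params: Params, name: str, rng: np.random.Generator,
                     in_dim: int, hidden: int, layers: int,
                     bidirectional: bool = False) -> None:
    for layer in range(layers):
        d_in = in_dim if layer == 0 else hidden * (2 if bidirectional else 1)
        init_gru_cell(params, f"{name}.l{layer}.fwd", rng, d_in, hidden)
        if bidirectional:
            init_gru_cell(params, f"{name}.l{layer}.bwd", rng, d_in, hidden)


def stacked_gru(params: Params, name: str, xs: Sequence[Tensor], mask: Array,
                hidden: int, layers: int, bidirectional: bool = False,
                dropout: float = 0.0,
                rng: np.random.Generator | None = None) -> tuple[list[Tensor], list[Tensor]]:
    """Stacked (optionally bidirectional) GRU.

    Returns (top-layer per-position outputs, list of per-layer final states).
    For a bidirectional stack the final state of a layer is the concatenation
    of the forward and backward final states.
    """
    current: Sequence[Tensor] = xs
    finals: list[Tensor] = []
    for layer in range(layers):
        if dropout > 0.0 and layer > 0 and rng is not None:
            current = [dropout_apply(x, dropout, rng) for x in current]
        fwd_out, fwd_h = gru_layer(params, f"{name}.l{layer}.fwd", current, mask, hidden)
        if bidirectional:
            bwd_out, bwd_h = gru_layer(params, f"{name}.l{layer}.bwd", current, mask,
                                       hidden, reverse=True)
            current = [ad.concat([f, b], axis=1) for f, b in zip(fwd_out, bwd_out)]
            finals.append(ad.concat([fwd_h, bwd_h], axis=1))
        else:
            current = fwd_out
            finals.append(fwd_h)
    return list(current), finals


# ---------------------------------------------------------------------------
# attention, convolution, dropout
# ---------------------------------------------------------------------------

def init_additive_attention(params: Params, name: str, rng: np.random.Generator,
                            dim: int, hidden: int) -> None:
    init_linear(params, f"{name}.proj", rng, dim, hidden)
    params[f"{name}.v"] = Tensor(glorot(rng, hidden, 1), requires_grad=True)


def attention_scores(params: Params, name: str, flat: Tensor) -> Tensor:
    """Additive scoring: v . tanh(W x + b), for a (N, dim) stack of vectors."""
    return ad.matmul(ad.tanh(linear(params, f"{name}.proj", flat)), params[f"{name}.v"])


def init_conv1d(params: Params, name: str, rng: np.random.Generator,
                in_dim: int, filters: int, kernel: int) -> None:
    for k in range(kernel):
        params[f"{name}.K{k}"] = Tensor(glorot(rng, in_dim, filters) / kernel,
                                        requires_grad=True)
    params[f"{name}.b"] = Tensor(np.zeros(filters), requires_grad=True)


def conv1d(params: Params, name: str, x_flat: Tensor, batch: int, length: int,
           kernel: int) -> tuple[Tensor, int]:
    """Valid 1-D convolution over a (batch*length, in_dim) flattened sequence.

    Returns a (batch*out_len, filters) flattened output and out_len.
    """
    out_len = length - kernel + 1
    if out_len < 1:
        raise ValueError(f"sequence of length {length} shorter than kernel {kernel}")
    base = (np.arange(batch)[:, None] * length + np.arange(out_len)[None, :]).ravel()
    y: Tensor | None = None
    for k in range(kernel):
        term = ad.matmul(ad.take_rows(x_flat, base + k), params[f"{name}.K{k}"])
        y = term if y is None else ad.add(y, term)
    return ad.add(y, params[f"{name}.b"]), out_len


def dropout_apply(x: Tensor, rate: float, rng: np.random.Generator) -> Tensor:
    if rate <= 0.0:
        return x
    mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return ad.mul(x, Tensor(mask))


# ---------------------------------------------------------------------------
# optimizers
# ---------------------------------------------------------------------------

class Adam:
    """Adam with bias correction; operates in-place on a parameter dict."""

    def __init__(self, params: Params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for key, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[key] = b1 * self.m[key] + (1 - b1) * g
            self.v[key] = b2 * self.v[key] + (1 - b2) * g * g
            m_hat = self.m[key] / (1 - b1 ** self.t)
            v_hat = self.v[key] / (1 - b2 ** self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


class DecayedSGD:
    """Plain SGD with a multiplicative per-epoch learning-rate decay."""

    def __init__(self, params: Params, lr: float = 0.5, decay: float = 0.99):
        self.params = params
        self.lr = lr
        self.decay = decay

    def step(self) -> None:
        for p in self.params.values():
            if p.grad is not None:
                p.data -= self.lr * p.grad

    def end_epoch(self) -> None:
        self.lr *= self.decay

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


def clip_gradients(params: Params, max_norm: float) -> float:
    """Global-norm gradient clipping; returns the pre-clip norm."""
    total = 0.0
    for p in params.values():
        if p.grad is not None:
            total += float((p.grad * p.grad).sum())
    norm = float(np.sqrt(total))
    if norm > max_norm and norm > 0.0:
        scale = max_norm / norm
        for p in params.values():
            if p.grad is not None:
                p.grad = p.grad * scale
    return norm


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_params(params: Params, directory: str | Path, manifest: dict) -> None:
    """Write parameters (one .npy per key) plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(directory / "params.npz", **{k: v.data for k, v in params.items()})
    manifest = dict(manifest)
    manifest["param_keys"] = sorted(params.keys())
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def load_params(directory: str | Path) -> tuple[Params, dict]:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    with np.load(directory / "params.npz") as archive:
        params = {k: Tensor(archive[k].copy(), requires_grad=True) for k in archive.files}
    return params, manifest


def copy_params(params: Params) -> Params:
    return {k: Tensor(v.data.copy(), requires_grad=True) for k, v in params.items()}
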