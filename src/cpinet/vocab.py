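"""Vocabularies and tokenization for the three sequence channels.

Three kinds of vocabulary are used:

``smiles``
    Symbol-level tokens over SMILES strings.  Splitting is greedy
    longest-match against the symbol table, so two-character tokens such as
    ``Cl``, ``Br`` or ``@@`` are matched before single characters.  The
    default 64-symbol base table (68 with specials) ships as package data; it
    is a reconstruction, since the published alphabet was never enumerated.
``sps``
    One token per 4-letter structural-property word (72 words, 76 with
    specials; see :mod:`cpinet.sps`).
``amino``
    One token per one-letter amino-acid code.

Every vocabulary reserves the same four special tokens at indices 0-3:
start, end, pad and an unused/unknown slot.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

START, END, PAD, UNUSED = "<start>", "<end>", "<pad>", "<unused>"
SPECIALS = (START, END, PAD, UNUSED)
KINDS = ("smiles", "sps", "amino")

DEFAULT_MAX_SMILES = 100
DEFAULT_MAX_SPS = 152


def default_smiles_symbols() -> list[str]:
    """The shipped 64-symbol SMILES base table (a documented reconstruction)."""
    text = resources.files("cpinet.data").joinpath("smiles_base64.json").read_text()
    return list(json.loads(text)["symbols"])


@dataclass(frozen=True)
class Vocabulary:
    """Ordered symbol set with the four reserved specials at the front."""

    symbols: tuple[str, ...]
    kind: str
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown vocabulary kind {self.kind!r}")
        if tuple(self.symbols[:4]) != SPECIALS:
            raise ValueError("first four symbols must be the reserved specials")
        index = {s: i for i, s in enumerate(self.symbols)}
        if len(index) != len(self.symbols):
            raise ValueError("duplicate symbols in vocabulary")
        object.__setattr__(self, "_index", index)

    @property
    def size(self) -> int:
        return len(self.symbols)

    @property
    def start_id(self) -> int:
        return 0

    @property
    def end_id(self) -> int:
        return 1

    @property
    def pad_id(self) -> int:
        return 2

    @property
    def unused_id(self) -> int:
        return 3

    def index(self, symbol: str) -> int:
        return self._index[symbol]

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._index

    def non_special(self) -> tuple[str, ...]:
        return self.symbols[4:]

    # -- persistence -----------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"kind": self.kind, "symbols": list(self.non_special())}, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "Vocabulary":
        payload = json.loads(Path(path).read_text())
        return cls.from_symbols(payload["symbols"], payload["kind"])

    @classmethod
    def from_symbols(cls, symbols: Iterable[str], kind: str) -> "Vocabulary":
        ordered = tuple(SPECIALS) + tuple(symbols)
        return cls(symbols=ordered, kind=kind)


@dataclass(frozen=True)
class TokenSequence:
    """A fixed-capacity index sequence: start, tokens..., end, pad..."""

    indices: tuple[int, ...]
    true_length: int
    max_length: int

    def __post_init__(self):
        if len(self.indices) != self.max_length:
            raise ValueError("indices must have exactly max_length entries")
        if self.true_length > self.max_length - 2:
            raise ValueError("true_length exceeds capacity")


def smiles_split(s: str, symbols: Sequence[str]) -> list[str]:
    """Greedy longest-match split of a SMILES string against a symbol table."""
    by_len = sorted({sym for sym in symbols}, key=len, reverse=True)
    tokens: list[str] = []
    i = 0
    while i < len(s):
        for sym in by_len:
            if s.startswith(sym, i):
                tokens.append(sym)
                i += len(sym)
                break
        else:
            # unknown single character; let the caller's policy decide
            tokens.append(s[i])
            i += 1
    return tokens


def split_sequence(s: str | Sequence[str], kind: str,
                   symbols: Sequence[str] | None = None) -> list[str]:
    """Split raw input into vocabulary tokens according to the channel kind."""
    if not isinstance(s, str):
        return list(s)
    if kind == "smiles":
        table = symbols if symbols is not None else default_smiles_symbols()
        return smiles_split(s, table)
    if kind == "amino":
        return list(s)
    # an SPS string given as text is whitespace-separated 4-letter words
    return s.split()


def build_vocabulary(corpus: Sequence[str | Sequence[str]], kind: str,
                     base_symbols: Sequence[str] | None = None) -> Vocabulary:
    """Build a vocabulary from a corpus: specials first, then sorted tokens.

    ``base_symbols`` seeds the symbol set (e.g. the shipped 64-symbol SMILES
    table); corpus tokens outside the base set are added as well, so the
    result always covers the corpus.  Ordering is deterministic and
    independent of corpus order.
    """
    if len(corpus) == 0:
        raise ValueError("empty corpus")
    if kind not in KINDS:
        raise ValueError(f"unknown vocabulary kind {kind!r}")
    seen: set[str] = set(base_symbols or ())
    split_table = list(base_symbols) if base_symbols else None
    for entry in corpus:
        seen.update(split_sequence(entry, kind, split_table))
    return Vocabulary.from_symbols(sorted(seen), kind)


def default_smiles_vocabulary() -> Vocabulary:
    """The 68-token vocabulary over the shipped 64-symbol base table."""
    return Vocabulary.from_symbols(sorted(default_smiles_symbols()), "smiles")


def tokenize(s: str | Sequence[str], vocab: Vocabulary, max_length: int,
             unknown: str = "strict") -> TokenSequence:
    """Tokenize, frame with start/end and pad to ``max_length``.

    Over-length sequences are rejected rather than truncated.  ``unknown``
    is either ``"strict"`` (raise on out-of-vocabulary tokens) or
    ``"unused"`` (map them to the reserved unused slot).
    """
    symbols = vocab.non_special() if vocab.kind == "smiles" else None
    tokens = split_sequence(s, vocab.kind, symbols)
    if len(tokens) > max_length - 2:
        raise ValueError(
            f"sequence exceeds max length ({len(tokens)} tokens > {max_length - 2})")
    indices = [vocab.start_id]
    for tok in tokens:
        if tok in vocab:
            indices.append(vocab.index(tok))
        elif unknown == "unused":
            indices.append(vocab.unused_id)
        else:
            raise ValueError(f"unknown token {tok!r} for {vocab.kind} vocabulary")
    indices.append(vocab.end_id)
    indices.extend([vocab.pad_id] * (max_length - len(indices)))
    return TokenSequence(indices=tuple(indices), true_length=len(tokens),
                         max_length=max_length)


def detokenize(t: TokenSequence, vocab: Vocabulary) -> str | list[str]:
    """Invert :func:`tokenize`; returns a string for smiles/amino, word list for sps."""
    tokens: list[str] = []
    for idx in t.indices[1:1 + t.true_length]:
        if not 0 <= idx < vocab.size:
            raise ValueError(f"index {idx} outside vocabulary of size {vocab.size}")
        tokens.append(vocab.symbols[idx])
    if vocab.kind == "sps":
        return tokens
    return "".join(tokens)
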