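"""Labeled compound-protein interaction samples and collections."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import math

import numpy as np


@dataclass(frozen=True)
class CPISample:
    """One labeled pair: compound SMILES, protein SPS words, optional amino
    sequence, and a real-valued affinity on the model scale (log10 IC50)."""

    smiles: str
    sps: tuple[str, ...]
    label: float
    amino: str | None = None
    compound_id: str = ""
    protein_id: str = ""

    def __post_init__(self):
        if not math.isfinite(self.label):
            raise ValueError("label must be finite")

    def require_channels(self, channels: Iterable[str]) -> None:
        for ch in channels:
            if ch in ("smiles", "graph") and not self.smiles:
                raise ValueError(f"sample missing compound data for channel {ch!r}")
            if ch == "sps" and not self.sps:
                raise ValueError("sample missing SPS data for channel 'sps'")
            if ch == "amino" and not self.amino:
                raise ValueError("sample missing amino sequence for channel 'amino'")


@dataclass
class CPIDataset:
    samples: list[CPISample]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.samples], dtype=float)

    def check_unique_pairs(self) -> None:
        seen: set[tuple[str, str]] = set()
        for s in self.samples:
            key = (s.compound_id or s.smiles, s.protein_id or " ".join(s.sps))
            if key in seen:
                raise ValueError(f"duplicate compound-protein pair {key}")
            seen.add(key)


def split_dataset(ds: CPIDataset, val_fraction: float = 0.1,
                  seed: int = 0) -> tuple[CPIDataset, CPIDataset]:
    """Disjoint, exhaustive, seeded random split into (train, val)."""
    if len(ds) == 0:
        raise ValueError("cannot split an empty dataset")
    if not 0.0 < val_fraction < 1.0:
        raise ValueError("val_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ds))
    n_val = int(round(len(ds) * val_fraction))
    val_idx = set(order[:n_val].tolist())
    train = [s for i, s in enumerate(ds.samples) if i not in val_idx]
    val = [s for i, s in enumerate(ds.samples) if i in val_idx]
    meta = dict(ds.provenance)
    return (CPIDataset(train, {**meta, "split": "train", "seed": seed}),
            CPIDataset(val, {**meta, "split": "val", "seed": seed}))


def from_synthetic(synth_samples: Sequence) -> CPIDataset:
    """Adapt synthetic-generator samples to a CPIDataset."""
    return CPIDataset([
        CPISample(smiles=s.smiles, sps=tuple(s.sps_words), amino=s.amino,
                  label=s.label, compound_id=s.compound_id, protein_id=s.protein_id)
        for s in synth_samples
    ], provenance={"source": "synthetic"})
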