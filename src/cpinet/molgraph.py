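"""2-D molecular graphs and the degree-filtered graph convolution.

A SMILES string is parsed (via RDKit) into a heavy-atom graph with initial
per-atom features.  The graph channel then runs R rounds of a
neural-fingerprint-style update in which every atom state is replaced by

    r_a  <-  sigma( (r_a + sum of neighbour states) @ H[L, n] )

where the filter matrix H[L, n] is selected by the atom's neighbour count n
(n is clamped to 1..5, so isolated atoms use the first filter with an empty
neighbour sum and hubs beyond degree 5 share the fifth).  All atoms update
synchronously from the previous round's states, which keeps the result
invariant under atom relabelling; the literal one-atom-at-a-time in-place
variant is available behind a flag for comparison, but it is order-dependent
and not used by the model.

This module is pure NumPy and stateless; the trainable batched version used
during model fitting lives in :mod:`cpinet.model` and is tested to agree
with the functions here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")  # rdkit parse errors are reported via exceptions

ELEMENT_PALETTE = ("C", "N", "O", "S", "F", "Cl", "Br", "I", "P", "B")
N_DEGREE_FILTERS = 5
ATOM_FEATURE_DIM = len(ELEMENT_PALETTE) + 1 + 6 + 1 + 1  # element, degree 0-5, aromatic, charge


@dataclass(frozen=True)
class MolecularGraph:
    """Undirected heavy-atom graph with initial features."""

    atom_features: np.ndarray          # (n_atoms, ATOM_FEATURE_DIM)
    neighbors: tuple[tuple[int, ...], ...]
    smiles: str = ""

    def __post_init__(self):
        if self.atom_count < 1:
            raise ValueError("molecular graph needs at least one atom")
        for a, nbrs in enumerate(self.neighbors):
            for u in nbrs:
                if a == u:
                    raise ValueError("self-loop in molecular graph")
                if a not in self.neighbors[u]:
                    raise ValueError("adjacency is not symmetric")

    @property
    def atom_count(self) -> int:
        return len(self.neighbors)

    @property
    def degrees(self) -> np.ndarray:
        return np.array([len(n) for n in self.neighbors], dtype=np.intp)

    @property
    def bond_count(self) -> int:
        return int(self.degrees.sum()) // 2

    def edge_list(self) -> list[tuple[int, int]]:
        return [(a, u) for a, nbrs in enumerate(self.neighbors) for u in nbrs if a < u]


def atom_feature_vector(symbol: str, degree: int, aromatic: bool, charge: int) -> np.ndarray:
    vec = np.zeros(ATOM_FEATURE_DIM)
    try:
        vec[ELEMENT_PALETTE.index(symbol)] = 1.0
    except ValueError:
        vec[len(ELEMENT_PALETTE)] = 1.0  # "other" element slot
    vec[len(ELEMENT_PALETTE) + 1 + min(degree, 5)] = 1.0
    vec[len(ELEMENT_PALETTE) + 7] = float(aromatic)
    vec[len(ELEMENT_PALETTE) + 8] = float(charge)
    return vec


def parse_smiles(smiles: str) -> MolecularGraph:
    """Parse a SMILES string into a heavy-atom graph with initial features."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    if mol.GetNumAtoms() == 0:
        raise ValueError(f"SMILES has no heavy atoms: {smiles!r}")
    neighbors = tuple(
        tuple(n.GetIdx() for n in atom.GetNeighbors()) for atom in mol.GetAtoms()
    )
    features = np.stack([
        atom_feature_vector(atom.GetSymbol(), atom.GetDegree(),
                            atom.GetIsAromatic(), atom.GetFormalCharge())
        for atom in mol.GetAtoms()
    ])
    return MolecularGraph(atom_features=features, neighbors=neighbors, smiles=smiles)


def _activation(name: str):
    if name == "relu":
        return lambda x: np.maximum(x, 0.0)
    if name == "tanh":
        return np.tanh
    if name == "sigmoid":
        return lambda x: 1.0 / (1.0 + np.exp(-x))
    if name == "identity":
        return lambda x: x
    raise ValueError(f"unknown activation {name!r}")


@dataclass
class GraphConvWeights:
    """Filter bank for the degree-filtered graph convolution.

    ``filters[L][n]`` is the hidden x hidden matrix applied at round L
    (0-based) to atoms whose clamped neighbour count is n+1.
    """

    radius: int
    filters: list[list[np.ndarray]]
    input_weight: np.ndarray          # (ATOM_FEATURE_DIM, hidden)
    input_bias: np.ndarray            # (hidden,)
    activation: str = "relu"
    hidden_dim: int = field(init=False)

    def __post_init__(self):
        if len(self.filters) != self.radius:
            raise ValueError("need exactly radius filter rows")
        dims = set()
        for row in self.filters:
            if len(row) != N_DEGREE_FILTERS:
                raise ValueError(f"need exactly {N_DEGREE_FILTERS} filters per round")
            for H in row:
                if H.ndim != 2 or H.shape[0] != H.shape[1]:
                    raise ValueError("filters must be square")
                dims.add(H.shape[0])
        if len(dims) != 1:
            raise ValueError("all filters must share one hidden dimension")
        self.hidden_dim = dims.pop()
        if self.input_weight.shape[1] != self.hidden_dim:
            raise ValueError("input projection dimension mismatch")

    @classmethod
    def random(cls, rng: np.random.Generator, hidden_dim: int = 128,
               radius: int = 3, activation: str = "relu",
               scale: float | None = None) -> "GraphConvWeights":
        s = scale if scale is not None else 1.0 / np.sqrt(hidden_dim)
        filters = [[rng.normal(0.0, s, size=(hidden_dim, hidden_dim))
                    for _ in range(N_DEGREE_FILTERS)] for _ in range(radius)]
        return cls(radius=radius, filters=filters,
                   input_weight=rng.normal(0.0, s, size=(ATOM_FEATURE_DIM, hidden_dim)),
                   input_bias=np.zeros(hidden_dim), activation=activation)


def initial_atom_states(g: MolecularGraph, w: GraphConvWeights) -> np.ndarray:
    """Project raw atom features to the hidden dimension."""
    return g.atom_features @ w.input_weight + w.input_bias


def clamp_degree(degree: int) -> int:
    """Filter index (1-based neighbour count clamped to the filter bank)."""
    return min(max(degree, 1), N_DEGREE_FILTERS)


def graph_conv_forward(g: MolecularGraph, w: GraphConvWeights,
                       in_place: bool = False) -> np.ndarray:
    """Run the R-round degree-filtered convolution; returns final atom states.

    ``in_place=True`` selects the literal sequential variant in which each
    atom's state is overwritten inside the node loop; it depends on atom
    ordering and exists only for comparison.
    """
    sigma = _activation(w.activation)
    states = initial_atom_states(g, w)
    if g.atom_features.shape[0] != g.atom_count:
        raise ValueError("feature/adjacency size mismatch")
    for layer in range(w.radius):
        source = states if in_place else states.copy()
        target = source if in_place else np.empty_like(states)
        for a in range(g.atom_count):
            nbrs = g.neighbors[a]
            v = source[a] + (source[list(nbrs)].sum(axis=0) if nbrs else 0.0)
            target[a] = sigma(v @ w.filters[layer][clamp_degree(len(nbrs)) - 1])
        states = target
    return states


def attention_pool(atom_states: np.ndarray, proj_w: np.ndarray, proj_b: np.ndarray,
                   score_v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Additive-attention pooling of per-atom states into one molecule vector.

    score_a = v . tanh(W r_a + b); weights = softmax over atoms; the pooled
    vector is the weighted sum.  Returns (molecule_vector, weights).
    """
    if atom_states.shape[0] == 0:
        raise ValueError("cannot pool an empty atom set")
    scores = np.tanh(atom_states @ proj_w + proj_b) @ score_v
    scores = scores.reshape(-1)
    scores = scores - scores.max()
    weights = np.exp(scores)
    weights /= weights.sum()
    return weights @ atom_states, weights
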