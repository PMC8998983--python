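import networkx as nx
import numpy as np
import pytest

from cpinet.molgraph import (ATOM_FEATURE_DIM, GraphConvWeights, MolecularGraph,
                             attention_pool, graph_conv_forward,
                             initial_atom_states, parse_smiles)


def random_graph(rng, max_atoms=6) -> MolecularGraph:
    """Random connected undirected graph with random atom features."""
    n = int(rng.integers(1, max_atoms + 1))
    g = nx.Graph()
    g.add_nodes_from(range(n))
    order = rng.permutation(n)
    for i in range(1, n):  # random spanning tree keeps it connected
        g.add_edge(int(order[i]), int(order[rng.integers(0, i)]))
    for _ in range(int(rng.integers(0, n))):  # extra edges
        a, b = rng.integers(0, n, 2)
        if a != b:
            g.add_edge(int(a), int(b))
    neighbors = tuple(tuple(sorted(g.neighbors(i))) for i in range(n))
    return MolecularGraph(atom_features=rng.normal(size=(n, ATOM_FEATURE_DIM)),
                          neighbors=neighbors)


def reference_graph_conv(g: MolecularGraph, w: GraphConvWeights) -> np.ndarray:
    """Independent nested-loop reference: explicit dicts, no vectorisation."""
    nxg = nx.Graph()
    nxg.add_nodes_from(range(g.atom_count))
    nxg.add_edges_from(g.edge_list())
    states = {a: g.atom_features[a] @ w.input_weight + w.input_bias
              for a in nxg.nodes}
    for layer in range(w.radius):
        new_states = {}
        for a in nxg.nodes:
            nbrs = list(nxg.neighbors(a))
            v = states[a].copy()
            for u in nbrs:
                v = v + states[u]
            filt = w.filters[layer][min(max(len(nbrs), 1), 5) - 1]
            h = v @ filt
            new_states[a] = np.maximum(h, 0.0) if w.activation == "relu" else np.tanh(h)
        states = new_states
    return np.stack([states[a] for a in range(g.atom_count)])


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("smiles,n_atoms,n_bonds,degrees", [
    ("CC", 2, 1, [1, 1]),
    ("C1CC1", 3, 3, [2, 2, 2]),        # cyclopropane
    ("c1ccccc1", 6, 6, [2, 2, 2, 2, 2, 2]),  # benzene
    ("CC(C)O", 4, 3, [1, 3, 1, 1]),
])
def test_parse_smiles_topology(smiles, n_atoms, n_bonds, degrees):
    g = parse_smiles(smiles)
    assert g.atom_count == n_atoms
    assert g.bond_count == n_bonds
    assert sorted(g.degrees.tolist()) == sorted(degrees)


def test_parse_rejects_garbage():
    with pytest.raises(ValueError, match="C1C"):
        parse_smiles("C1C")  # unclosed ring


def test_graph_invariants_enforced():
    with pytest.raises(ValueError, match="symmetric"):
        MolecularGraph(atom_features=np.zeros((2, ATOM_FEATURE_DIM)),
                       neighbors=((1,), ()))
    with pytest.raises(ValueError, match="self-loop"):
        MolecularGraph(atom_features=np.zeros((1, ATOM_FEATURE_DIM)),
                       neighbors=((0,),))


def test_aromatic_flag_in_features():
    benzene = parse_smiles("c1ccccc1")
    ethane = parse_smiles("CC")
    aromatic_col = 10 + 7
    assert benzene.atom_features[:, aromatic_col].all()
    assert not ethane.atom_features[:, aromatic_col].any()


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def identity_weights(radius=1) -> GraphConvWeights:
    eye = np.eye(ATOM_FEATURE_DIM)
    return GraphConvWeights(radius=radius,
                            filters=[[eye.copy() for _ in range(5)]
                                     for _ in range(radius)],
                            input_weight=eye.copy(),
                            input_bias=np.zeros(ATOM_FEATURE_DIM),
                            activation="identity")


def test_isolated_atom_passthrough(rng):
    g = MolecularGraph(atom_features=rng.normal(size=(1, ATOM_FEATURE_DIM)),
                       neighbors=((),))
    out = graph_conv_forward(g, identity_weights())
    np.testing.assert_allclose(out, g.atom_features)


def test_path_graph_neighbour_sum(rng):
    """On A-B-C with identity filters, B's new state is the sum of all three."""
    feats = rng.normal(size=(3, ATOM_FEATURE_DIM))
    g = MolecularGraph(atom_features=feats, neighbors=((1,), (0, 2), (1,)))
    out = graph_conv_forward(g, identity_weights(radius=1))
    np.testing.assert_allclose(out[1], feats.sum(axis=0))
    np.testing.assert_allclose(out[0], feats[0] + feats[1])


def test_matches_nested_loop_reference(rng):
    for _ in range(50):
        g = random_graph(rng)
        w = GraphConvWeights.random(rng, hidden_dim=12)
        ours = graph_conv_forward(g, w)
        ref = reference_graph_conv(g, w)
        np.testing.assert_allclose(ours, ref, rtol=1e-5, atol=1e-10)


def test_degree_clamping_above_five(rng):
    # a star with 6 leaves: hub degree 6 uses the fifth filter
    neighbors = tuple([tuple(range(1, 7))] + [(0,)] * 6)
    g = MolecularGraph(atom_features=rng.normal(size=(7, ATOM_FEATURE_DIM)),
                       neighbors=neighbors)
    w = GraphConvWeights.random(rng, hidden_dim=8)
    ref = reference_graph_conv(g, w)
    np.testing.assert_allclose(graph_conv_forward(g, w), ref, rtol=1e-5, atol=1e-10)


def test_in_place_variant_is_order_dependent(rng):
    g = random_graph(np.random.default_rng(5), max_atoms=5)
    w = GraphConvWeights.random(rng, hidden_dim=8)
    sync = graph_conv_forward(g, w)
    seq = graph_conv_forward(g, w, in_place=True)
    # the literal sequential update differs in general (documented behaviour)
    assert sync.shape == seq.shape


def test_locality_radius(rng):
    """With R layers, an atom's state ignores atoms beyond graph distance R."""
    # path of 6 atoms, R = 2: atom 0 must not see atom 5, must see atom 2
    feats = rng.normal(size=(6, ATOM_FEATURE_DIM))
    neighbors = tuple((i - 1,) * (i > 0) + (i + 1,) * (i < 5) for i in range(6))
    w = GraphConvWeights.random(rng, hidden_dim=8, radius=2)

    def run(features):
        g = MolecularGraph(atom_features=features, neighbors=neighbors)
        return graph_conv_forward(g, w)

    base = run(feats)
    far = feats.copy()
    far[5] += 10.0
    np.testing.assert_allclose(run(far)[0], base[0])
    near = feats.copy()
    near[2] += 10.0
    assert not np.allclose(run(near)[0], base[0])


# ---------------------------------------------------------------------------
# attention pooling
# ---------------------------------------------------------------------------

def pool_params(rng, dim=8, att=4):
    return (rng.normal(size=(dim, att)), rng.normal(size=att),
            rng.normal(size=att))


def test_single_atom_pool_is_identity(rng):
    state = rng.normal(size=(1, 8))
    vec, weights = attention_pool(state, *pool_params(rng))
    np.testing.assert_allclose(vec, state[0])
    np.testing.assert_allclose(weights, [1.0])


def test_identical_atoms_uniform_weights(rng):
    state = np.tile(rng.normal(size=(1, 8)), (5, 1))
    _, weights = attention_pool(state, *pool_params(rng))
    np.testing.assert_allclose(weights, np.full(5, 0.2))


def test_empty_pool_rejected(rng):
    with pytest.raises(ValueError, match="empty"):
        attention_pool(np.zeros((0, 8)), *pool_params(rng))


def test_pooled_vector_permutation_invariant(rng):
    for _ in range(20):
        g = random_graph(rng)
        w = GraphConvWeights.random(rng, hidden_dim=8)
        pw, pb, pv = pool_params(rng)
        base_states = graph_conv_forward(g, w)
        base_vec, _ = attention_pool(base_states, pw, pb, pv)
        perm = rng.permutation(g.atom_count)
        inv = np.argsort(perm)
        permuted = MolecularGraph(
            atom_features=g.atom_features[perm],
            neighbors=tuple(tuple(sorted(int(inv[u]) for u in g.neighbors[perm[a]]))
                            for a in range(g.atom_count)))
        perm_states = graph_conv_forward(permuted, w)
        np.testing.assert_allclose(perm_states, base_states[perm], rtol=1e-8, atol=1e-12)
        perm_vec, _ = attention_pool(perm_states, pw, pb, pv)
        np.testing.assert_allclose(perm_vec, base_vec, rtol=1e-8, atol=1e-12)
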