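"""Atom features, disjoint batching and the message-passing network."""

import numpy as np
import pytest

from p31shift import chem, gnn
from p31shift.gnn import (
    DisjointBatch,
    GnnConfig,
    GnnRegressor,
    atom_features,
    build_gnn,
    heavy_edges,
    hyperparameter_search,
    make_batches,
    train_gnn,
)


def g(smiles):
    return chem.parse_structure(smiles)


def test_atom_features_shape_and_content():
    graph = g("c1ccccc1P")  # phenylphosphine
    X = atom_features(graph)
    assert X.shape == (7, 8)
    mol_symbols = [a.symbol for a in graph.atoms if a.symbol != "H"]
    p_row = X[mol_symbols.index("P")]
    assert p_row[0] == 15  # atomic number
    assert p_row[4] == 2  # attached hydrogens
    carbons = X[[i for i, s in enumerate(mol_symbols) if s == "C"]]
    assert (carbons[:, 7] == 1).all()  # aromatic flags
    ch_carbons = carbons[carbons[:, 4] == 1]
    assert (ch_carbons[:, 1] == 2).all()  # two heavy neighbors


def test_ph3_features():
    X = atom_features(g("P"))
    assert X.shape == (1, 8)
    assert X[0, 0] == 15 and X[0, 4] == 3


def test_make_batches_membership_and_offsets():
    graphs = [g("CP"), g("CCOPC")]  # 2 and 5 heavy atoms
    batches = make_batches(graphs, [1.0, 2.0], batch_size=2, shuffle=False)
    b = batches[0]
    assert b.X.shape == (7, 8)
    assert b.membership.tolist() == [0, 0, 1, 1, 1, 1, 1]
    assert b.adjacency.shape == (7, 7)
    # no edges may cross graph boundaries
    rows, cols = b.adjacency.nonzero()
    assert all(b.membership[i] == b.membership[j] for i, j in zip(rows, cols))


def test_make_batches_sizes_and_determinism():
    graphs = [g("CP")] * 70
    y = np.arange(70.0)
    batches = make_batches(graphs, y, batch_size=32, seed=5)
    assert [b.n_graphs for b in batches] == [32, 32, 6]
    again = make_batches(graphs, y, batch_size=32, seed=5)
    for a, b in zip(batches, again):
        assert np.array_equal(a.y, b.y)


def test_invalid_config_lists_allowed_values():
    with pytest.raises(ValueError, match="4, 6, 8"):
        GnnConfig(n_mpl=5)
    with pytest.raises(ValueError, match="n_pre"):
        GnnConfig(n_pre=3)


def test_forward_output_shapes():
    net = build_gnn(GnnConfig(hidden=16), seed=0)
    graphs = [g("CP(C)C")] * 32 + [g("P")]
    y = np.zeros(33)
    batches = make_batches(graphs, y, batch_size=32, shuffle=False)
    net.fit_scalers(batches)
    assert net.forward(batches[0]).shape == (32,)
    assert net.forward(batches[1]).shape == (1,)


def test_permutation_invariance():
    net = build_gnn(GnnConfig(hidden=32), seed=1)
    graph = g("CCOP(=S)(Oc1ccccc1)N(C)C")
    batches = make_batches([graph], [0.0], shuffle=False)
    net.fit_scalers(batches)
    ref = net.forward(batches[0])[0]
    rng = np.random.default_rng(2)
    for _ in range(5):
        perm = chem.renumbered(graph, rng.permutation(graph.n_atoms))
        out = net.forward(make_batches([perm], [0.0], shuffle=False)[0])[0]
        assert abs(out - ref) < 1e-5


def test_batch_composition_invariance():
    net = build_gnn(GnnConfig(hidden=16), seed=0)
    graphs = [g("CP(C)C"), g("OP(O)O"), g("P")]
    alone = make_batches(graphs, [0.0] * 3, batch_size=1, shuffle=False)
    net.fit_scalers(alone)
    together = make_batches(graphs, [0.0] * 3, batch_size=3, shuffle=False)
    joint = net.forward(together[0])
    single = np.array([net.forward(b)[0] for b in alone])
    assert np.allclose(joint, single, atol=1e-8)


def test_bond_orders_do_not_enter_the_model():
    # same connectivity, different bond orders: the edge list is identical
    # and edges carry no weights, so any output difference can come only
    # from node features
    single = g("C1CCCCC1P")
    double = g("C1=CCCCC1P")
    assert sorted(heavy_edges(single)) == sorted(heavy_edges(double))
    b = make_batches([single], [0.0], shuffle=False)[0]
    assert set(b.adjacency.data) == {1.0}
    # swap in the other molecule's connectivity: prediction unchanged
    net = build_gnn(GnnConfig(hidden=16), seed=0)
    net.fit_scalers([b])
    b_swapped = DisjointBatch(
        X=b.X,
        adjacency=make_batches([double], [0.0], shuffle=False)[0].adjacency,
        membership=b.membership,
        y=b.y,
        n_graphs=1,
    )
    assert net.forward(b) == pytest.approx(net.forward(b_swapped))


def test_backprop_matches_numerical_gradients():
    """Analytic gradients agree with central finite differences for every
    parameter tensor of a small network."""
    net = build_gnn(GnnConfig(n_pre=2, n_mpl=4, n_post=2, hidden=5), seed=0)
    graphs = [g(s) for s in ["CP(C)C", "OP(O)O", "P(=O)(C)(C)C", "FP(F)F"]]
    y = np.array([1.0, -2.0, 0.5, 3.0])
    batch = make_batches(graphs, y, batch_size=4, shuffle=False)[0]
    net.fit_scalers([batch])

    def loss():
        pred, _ = net.forward(batch, need_cache=True)
        return float(np.mean(((pred - batch.y) / net.y_std) ** 2))

    pred, cache = net.forward(batch, need_cache=True)
    dpred = 2.0 * (pred - batch.y) / net.y_std / batch.n_graphs
    grads = net.backward(batch, cache, dpred)
    eps = 1e-6
    for name, tensor in net.params.items():
        flat = tensor.reshape(-1)
        for i in range(min(3, flat.size)):
            orig = flat[i]
            flat[i] = orig + eps
            up = loss()
            flat[i] = orig - eps
            down = loss()
            flat[i] = orig
            numeric = (up - down) / (2 * eps)
            analytic = grads[name].reshape(-1)[i]
            assert analytic == pytest.approx(numeric, abs=1e-5, rel=1e-4), name


def test_training_reduces_loss_and_is_deterministic(noisy_records):
    graphs = [r.graph for r in noisy_records[:100]]
    y = np.array([r.shift_ppm for r in noisy_records[:100]])

    def run():
        net = build_gnn(GnnConfig(hidden=24), seed=4)
        return train_gnn(net, graphs, y, epochs=50, seed=4)

    _, h1 = run()
    assert h1["train_mse"].iloc[-1] < h1["train_mse"].iloc[0]
    _, h2 = run()
    assert np.allclose(h1["train_mse"], h2["train_mse"])


def test_constant_target_converges(noisy_records):
    graphs = [r.graph for r in noisy_records[:60]]
    y = np.full(60, 12.0)
    reg = GnnRegressor(hidden=24, epochs=100, learning_rate=0.01, seed=0)
    reg.fit(graphs, y)
    assert np.abs(reg.predict(graphs[:20]) - 12.0).mean() < 1.0


def test_divergence_aborts_with_diagnostic(noisy_records):
    graphs = [r.graph for r in noisy_records[:40]]
    y = np.array([r.shift_ppm for r in noisy_records[:40]])
    net = build_gnn(GnnConfig(hidden=8, learning_rate=0.001), seed=0)
    net.params["out_w"] += np.inf
    with np.errstate(invalid="ignore"):
        with pytest.raises(RuntimeError, match="non-finite"):
            train_gnn(net, graphs, y, epochs=2, seed=0)


def test_hyperparameter_grid_enumeration(noisy_records):
    graphs = [r.graph for r in noisy_records[:40]]
    y = [r.shift_ppm for r in noisy_records[:40]]
    space = {
        "n_pre": [1],
        "n_mpl": [4],
        "n_post": [1, 2],
        "learning_rate": [0.01],
    }
    best, ranking = hyperparameter_search(
        graphs, y, space=space, epochs=3, seed=0, hidden=8
    )
    assert len(ranking) == 2
    assert best.n_mpl == 4 and best.learning_rate == 0.01
    _, ranking2 = hyperparameter_search(
        graphs, y, space=space, epochs=3, seed=0, hidden=8
    )
    assert ranking["valid_mse"].tolist() == ranking2["valid_mse"].tolist()


def test_default_search_space_has_24_configs():
    import itertools

    space = {
        "n_pre": [1, 2],
        "n_mpl": [4, 6, 8],
        "n_post": [1, 2],
        "learning_rate": [0.001, 0.01],
    }
    assert len(list(itertools.product(*space.values()))) == 24
    for combo in itertools.product(*space.values()):
        GnnConfig(hidden=8, **dict(zip(space, combo)))  # all valid
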