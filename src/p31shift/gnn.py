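"""Graph neural network for per-molecule ³¹P shift regression.

The network operates on the heavy-atom graph with eight node features
(atomic number, heavy-atom degree, formal charge, chirality code, attached
hydrogen count, hybridization code, atomic mass, aromatic flag) and no edge
features — bond orders do not enter the model, only connectivity.  The
architecture is: input standardization → ``n_pre`` dense layers →
``n_mpl`` message-passing layers (sum aggregation over neighbors, skip
connection by concatenating a node's own state with the aggregated
messages before the linear transform) → ``n_post`` dense layers → global
sum pooling → linear read-out to one scalar per graph.  All activations
are PReLU with a learnable slope per layer.  Training minimizes MSE with
Adam on disjoint-union batches of 32 graphs.

The implementation is pure NumPy/SciPy with hand-written backpropagation;
sum aggregation and sum pooling make the output exactly invariant under
node permutation and batch composition.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from rdkit import Chem
from sklearn.base import BaseEstimator, RegressorMixin

from . import chem
from .chem import MolecularGraph

N_FEATURES = 8
FEATURE_NAMES = [
    "atomic_number",
    "degree",
    "formal_charge",
    "chirality",
    "n_hydrogens",
    "hybridization",
    "atomic_mass",
    "is_aromatic",
]

_ALLOWED = {"n_pre": (1, 2), "n_mpl": (4, 6, 8), "n_post": (1, 2)}


@dataclass(frozen=True)
class GnnConfig:
    """Hyperparameters; defaults are the selected optimum of the search
    space (1 preprocessing layer, 6 message-passing layers, 2
    post-processing layers, 256 hidden channels, sum aggregation)."""

    n_pre: int = 1
    n_mpl: int = 6
    n_post: int = 2
    hidden: int = 256
    learning_rate: float = 0.001
    batch_size: int = 32

    def __post_init__(self):
        for name, allowed in _ALLOWED.items():
            if getattr(self, name) not in allowed:
                raise ValueError(
                    f"{name}={getattr(self, name)} invalid; allowed: {allowed}"
                )
        if self.hidden < 1 or self.learning_rate <= 0 or self.batch_size < 1:
            raise ValueError("hidden, learning_rate, batch_size must be positive")


@dataclass
class DisjointBatch:
    """Several molecular graphs stacked into one block-diagonal graph."""

    X: np.ndarray  # (n_nodes, 8) raw node features
    adjacency: sp.csr_matrix  # (n_nodes, n_nodes), symmetric, unweighted
    membership: np.ndarray  # (n_nodes,) graph index per node
    y: np.ndarray  # (n_graphs,) targets
    n_graphs: int


def atom_features(graph: MolecularGraph) -> np.ndarray:
    """(n_heavy_atoms, 8) feature matrix in :data:`FEATURE_NAMES` order.

    Computed on the hydrogen-collapsed graph: degree counts heavy
    neighbors only and attached hydrogens are a feature of their own.
    Hydrogen caps introduced by truncation count as attached hydrogens.
    """
    mol = Chem.RemoveHs(Chem.Mol(graph.mol))
    rows = []
    for a in mol.GetAtoms():
        rows.append(
            [
                a.GetAtomicNum(),
                a.GetDegree(),
                a.GetFormalCharge(),
                int(a.GetChiralTag()),
                a.GetTotalNumHs(),
                int(a.GetHybridization()),
                a.GetMass(),
                int(a.GetIsAromatic()),
            ]
        )
    return np.asarray(rows, dtype=float)


def heavy_edges(graph: MolecularGraph) -> list[tuple[int, int]]:
    """Heavy-atom bond list (no orders — the model ignores them)."""
    mol = Chem.RemoveHs(Chem.Mol(graph.mol))
    return [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()
    ]


def _as_graphs(X: Iterable) -> list[MolecularGraph]:
    return [
        x if isinstance(x, MolecularGraph) else chem.parse_structure(x)
        for x in X
    ]


def make_batches(
    graphs: Sequence[MolecularGraph],
    targets: Sequence[float],
    batch_size: int = 32,
    seed: int = 0,
    shuffle: bool = True,
) -> list[DisjointBatch]:
    """Seeded shuffled disjoint-union batches; the last may be smaller."""
    if len(graphs) != len(targets):
        raise ValueError("graphs and targets length mismatch")
    y = np.asarray(targets, dtype=float)
    order = np.arange(len(graphs))
    if shuffle:
        np.random.default_rng(seed).shuffle(order)
    batches = []
    for start in range(0, len(order), batch_size):
        idx = order[start : start + batch_size]
        feats, members, rows, cols = [], [], [], []
        offset = 0
        for gi, k in enumerate(idx):
            f = atom_features(graphs[k])
            feats.append(f)
            members.extend([gi] * len(f))
            for i, j in heavy_edges(graphs[k]):
                rows.extend([i + offset, j + offset])
                cols.extend([j + offset, i + offset])
            offset += len(f)
        X = np.vstack(feats)
        A = sp.csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(offset, offset)
        )
        batches.append(
            DisjointBatch(
                X=X,
                adjacency=A,
                membership=np.asarray(members, dtype=int),
                y=y[idx],
                n_graphs=len(idx),
            )
        )
    return batches


def _prelu(s: np.ndarray, a: float) -> np.ndarray:
    return np.where(s > 0, s, a * s)


_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9


class GnnNetwork:
    """The parameterized network with forward pass and backpropagation.

    Every dense and message-passing layer is linear → batch norm → PReLU;
    batch statistics are taken over the node axis (permutation invariant)
    during training, running statistics at inference.
    """

    def __init__(self, config: GnnConfig, n_features: int = N_FEATURES, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        h = config.hidden
        self.params: dict[str, np.ndarray] = {}
        self.bn_stats: dict[str, np.ndarray] = {}
        self.layer_names: list[tuple[str, str]] = []

        def dense(kind, name, n_in, n_out):
            scale = np.sqrt(2.0 / n_in)
            self.params[f"{name}_W"] = rng.normal(0, scale, (n_in, n_out))
            self.params[f"{name}_gamma"] = np.ones(n_out)
            self.params[f"{name}_beta"] = np.zeros(n_out)
            self.params[f"{name}_a"] = np.array(0.25)
            self.bn_stats[f"{name}_mu"] = np.zeros(n_out)
            self.bn_stats[f"{name}_var"] = np.ones(n_out)
            self.layer_names.append((kind, name))

        n_in = n_features
        for i in range(config.n_pre):
            dense("dense", f"pre{i}", n_in, h)
            n_in = h
        for j in range(config.n_mpl):
            dense("mpl", f"mpl{j}", 2 * h, h)
        for i in range(config.n_post):
            dense("dense", f"post{i}", h, h)
        self.params["out_w"] = rng.normal(0, np.sqrt(1.0 / h), h)
        self.params["out_c"] = np.array(0.0)
        # input/target standardization, fit on the training data
        self.x_mean = np.zeros(n_features)
        self.x_std = np.ones(n_features)
        self.y_mean = 0.0
        self.y_std = 1.0

    def fit_scalers(self, batches: Sequence[DisjointBatch]) -> None:
        X = np.vstack([b.X for b in batches])
        y = np.concatenate([b.y for b in batches])
        self.x_mean = X.mean(axis=0)
        self.x_std = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
        self.y_mean = float(y.mean())
        self.y_std = float(y.std()) or 1.0

    def state(self) -> dict:
        return {
            "params": {k: v.copy() for k, v in self.params.items()},
            "bn_stats": {k: v.copy() for k, v in self.bn_stats.items()},
        }

    def load_state(self, state: dict) -> None:
        self.params = {k: v.copy() for k, v in state["params"].items()}
        self.bn_stats = {k: v.copy() for k, v in state["bn_stats"].items()}

    # -- forward -----------------------------------------------------------
    def forward(self, batch: DisjointBatch, need_cache: bool = False):
        """Forward pass; ``need_cache=True`` is the training mode (batch-norm
        batch statistics, running stats updated, cache returned)."""
        p = self.params
        cfg = self.config
        A = batch.adjacency
        h = (batch.X - self.x_mean) / self.x_std
        cache = []

        def through(kind, name, x_in):
            s = x_in @ p[f"{name}_W"]
            if need_cache:
                mu = s.mean(axis=0)
                var = s.var(axis=0)
                self.bn_stats[f"{name}_mu"] = (
                    _BN_MOMENTUM * self.bn_stats[f"{name}_mu"]
                    + (1 - _BN_MOMENTUM) * mu
                )
                self.bn_stats[f"{name}_var"] = (
                    _BN_MOMENTUM * self.bn_stats[f"{name}_var"]
                    + (1 - _BN_MOMENTUM) * var
                )
            else:
                mu = self.bn_stats[f"{name}_mu"]
                var = self.bn_stats[f"{name}_var"]
            inv_std = 1.0 / np.sqrt(var + _BN_EPS)
            shat = (s - mu) * inv_std
            lin = p[f"{name}_gamma"] * shat + p[f"{name}_beta"]
            out = _prelu(lin, p[f"{name}_a"])
            if need_cache:
                cache.append((kind, name, x_in, shat, inv_std, lin))
            return out

        for i in range(cfg.n_pre):
            h = through("dense", f"pre{i}", h)
        for j in range(cfg.n_mpl):
            m = A @ h
            z = np.hstack([h, m])
            h = through("mpl", f"mpl{j}", z)
        for i in range(cfg.n_post):
            h = through("dense", f"post{i}", h)

        G = np.zeros((batch.n_graphs, cfg.hidden))
        np.add.at(G, batch.membership, h)
        pred_std = G @ p["out_w"] + p["out_c"]
        if need_cache:
            cache.append(("pool", G))
        pred = pred_std * self.y_std + self.y_mean
        return (pred, cache) if need_cache else pred

    # -- backward ----------------------------------------------------------
    def backward(
        self, batch: DisjointBatch, cache: list, dpred_std: np.ndarray
    ) -> dict[str, np.ndarray]:
        p = self.params
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        kind, G = cache[-1][0], cache[-1][1]
        assert kind == "pool"
        grads["out_w"] = G.T @ dpred_std
        grads["out_c"] = np.array(dpred_std.sum())
        dG = np.outer(dpred_std, p["out_w"])
        dh = dG[batch.membership]
        A = batch.adjacency
        hdim = self.config.hidden
        for kind, name, x_in, shat, inv_std, lin in reversed(cache[:-1]):
            a = p[f"{name}_a"]
            dlin = dh * np.where(lin > 0, 1.0, a)
            grads[f"{name}_a"] = np.array(
                np.sum(dh * np.where(lin > 0, 0.0, lin))
            )
            grads[f"{name}_gamma"] = (dlin * shat).sum(axis=0)
            grads[f"{name}_beta"] = dlin.sum(axis=0)
            dshat = dlin * p[f"{name}_gamma"]
            n = shat.shape[0]
            ds = (
                inv_std
                / n
                * (
                    n * dshat
                    - dshat.sum(axis=0)
                    - shat * (dshat * shat).sum(axis=0)
                )
            )
            grads[f"{name}_W"] = x_in.T @ ds
            dz = ds @ p[f"{name}_W"].T
            if kind == "mpl":
                dh = dz[:, :hdim] + A @ dz[:, hdim:]  # A is symmetric
            else:
                dh = dz
        return grads


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads, b1=0.9, b2=0.999, eps=1e-8):
        self.t += 1
        for k in params:
            self.m[k] = b1 * self.m[k] + (1 - b1) * grads[k]
            self.v[k] = b2 * self.v[k] + (1 - b2) * grads[k] ** 2
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] = params[k] - self.lr * mhat / (np.sqrt(vhat) + eps)


def build_gnn(config: GnnConfig, seed: int = 0) -> GnnNetwork:
    """Instantiate the network for a configuration (validated on creation)."""
    return GnnNetwork(config, seed=seed)


def train_gnn(
    model: GnnNetwork,
    train_graphs: Sequence[MolecularGraph],
    train_y: Sequence[float],
    valid_graphs: Sequence[MolecularGraph] | None = None,
    valid_y: Sequence[float] | None = None,
    epochs: int = 500,
    seed: int = 0,
) -> tuple[GnnNetwork, pd.DataFrame]:
    """Minimize MSE with Adam; returns the model (best-validation-epoch
    parameters restored when a validation set is given) and the per-epoch
    loss history.  Aborts with a diagnostic on non-finite loss."""
    cfg = model.config
    base_batches = make_batches(
        train_graphs, train_y, cfg.batch_size, seed=seed, shuffle=False
    )
    model.fit_scalers(base_batches)
    valid_batches = (
        make_batches(valid_graphs, valid_y, cfg.batch_size, shuffle=False)
        if valid_graphs is not None
        else None
    )
    opt = _Adam(model.params, cfg.learning_rate)
    history = {"epoch": [], "train_mse": [], "valid_mse": []}
    best_val = np.inf
    best_params = None
    for epoch in range(epochs):
        batches = make_batches(
            train_graphs, train_y, cfg.batch_size, seed=seed + epoch + 1
        )
        sq_sum, n_seen = 0.0, 0
        for batch in batches:
            pred, cache = model.forward(batch, need_cache=True)
            resid_std = (pred - batch.y) / model.y_std
            if not np.all(np.isfinite(resid_std)):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: non-finite loss"
                )
            dpred_std = 2.0 * resid_std / batch.n_graphs
            grads = model.backward(batch, cache, dpred_std)
            opt.step(model.params, grads)
            sq_sum += float(np.sum((pred - batch.y) ** 2))
            n_seen += batch.n_graphs
        train_mse = sq_sum / n_seen
        valid_mse = np.nan
        if valid_batches is not None:
            vp = np.concatenate([model.forward(b) for b in valid_batches])
            vy = np.concatenate([b.y for b in valid_batches])
            valid_mse = float(np.mean((vp - vy) ** 2))
            if valid_mse < best_val:
                best_val = valid_mse
                best_params = model.state()
        history["epoch"].append(epoch)
        history["train_mse"].append(train_mse)
        history["valid_mse"].append(valid_mse)
    if best_params is not None:
        model.load_state(best_params)
    return model, pd.DataFrame(history)


def hyperparameter_search(
    graphs: Sequence[MolecularGraph],
    targets: Sequence[float],
    space: dict | None = None,
    epochs: int = 1000,
    seed: int = 0,
    hidden: int = 256,
    batch_size: int = 32,
) -> tuple[GnnConfig, pd.DataFrame]:
    """Exhaustive grid over the architecture search space, ranked by
    validation MSE on a 60/20 split of the given subset."""
    from .evaluation import random_split

    space = space or {
        "n_pre": [1, 2],
        "n_mpl": [4, 6, 8],
        "n_post": [1, 2],
        "learning_rate": [0.001, 0.01],
    }
    ids = [str(i) for i in range(len(graphs))]
    split = random_split(ids, (0.6, 0.2, 0.2), seed=seed)
    tr = split.mask(ids, "train")
    va = split.mask(ids, "valid")
    g = np.asarray(graphs, dtype=object)
    y = np.asarray(targets, dtype=float)
    rows = []
    keys = list(space)
    for combo in itertools.product(*(space[k] for k in keys)):
        kw = dict(zip(keys, combo))
        config = GnnConfig(hidden=hidden, batch_size=batch_size, **kw)
        model = build_gnn(config, seed=seed)
        _, hist = train_gnn(
            model,
            list(g[tr]),
            y[tr],
            list(g[va]),
            y[va],
            epochs=epochs,
            seed=seed,
        )
        rows.append({**kw, "valid_mse": float(np.nanmin(hist["valid_mse"]))})
    ranking = pd.DataFrame(rows).sort_values("valid_mse").reset_index(drop=True)
    best = ranking.iloc[0]
    best_config = GnnConfig(
        hidden=hidden,
        batch_size=batch_size,
        **{k: best[k] for k in keys if k != "learning_rate"},
        learning_rate=float(best["learning_rate"]),
    )
    return best_config, ranking


class GnnRegressor(BaseEstimator, RegressorMixin):
    """scikit-learn wrapper around the NumPy message-passing network.

    ``X`` is a sequence of SMILES strings or :class:`MolecularGraph`
    objects.  A ``validation_fraction`` > 0 holds out a seeded slice of the
    training data for best-epoch checkpointing.
    """

    def __init__(
        self,
        n_pre: int = 1,
        n_mpl: int = 6,
        n_post: int = 2,
        hidden: int = 256,
        learning_rate: float = 0.001,
        batch_size: int = 32,
        epochs: int = 500,
        validation_fraction: float = 0.0,
        seed: int = 0,
    ):
        self.n_pre = n_pre
        self.n_mpl = n_mpl
        self.n_post = n_post
        self.hidden = hidden
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.validation_fraction = validation_fraction
        self.seed = seed

    def _config(self) -> GnnConfig:
        return GnnConfig(
            n_pre=self.n_pre,
            n_mpl=self.n_mpl,
            n_post=self.n_post,
            hidden=self.hidden,
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
        )

    def fit(self, X, y) -> "GnnRegressor":
        graphs = _as_graphs(X)
        y = np.asarray(y, dtype=float)
        net = build_gnn(self._config(), seed=self.seed)
        vg, vy = None, None
        if self.validation_fraction > 0:
            rng = np.random.default_rng(self.seed)
            order = rng.permutation(len(graphs))
            n_val = max(1, int(round(self.validation_fraction * len(graphs))))
            val_idx, tr_idx = order[:n_val], order[n_val:]
            vg = [graphs[i] for i in val_idx]
            vy = y[val_idx]
            graphs = [graphs[i] for i in tr_idx]
            y = y[tr_idx]
        self.network_, self.history_ = train_gnn(
            net, graphs, y, vg, vy, epochs=self.epochs, seed=self.seed
        )
        return self

    def predict(self, X) -> np.ndarray:
        graphs = _as_graphs(X)
        if not graphs:
            return np.array([])
        batches = make_batches(
            graphs, np.zeros(len(graphs)), self.batch_size, shuffle=False
        )
        return np.concatenate([self.network_.forward(b) for b in batches])
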