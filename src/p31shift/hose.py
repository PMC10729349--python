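"""HOSE-code shift prediction with hierarchical depth fallback.

A HOSE (Hierarchically Ordered Spherical Environment) code is a canonical
string describing the spheres of neighbors around an atom out to a given
depth.  Prediction is a lookup: a query molecule's depth-5 code is searched
in the training index; if absent the model falls back to depth 4, then 3,
and so on down to depth 1, returning the arithmetic mean of the training
shifts stored under the first matching code.  If even the depth-1 code is
unknown the model abstains — the caller sees an explicit no-prediction
outcome, never an imputed number.

The sphere serialization here is a canonical recursive scheme of our own:
atoms are tokenized as element symbol plus charge mark, children are ordered
by their (recursively canonical) subtree strings, kekulized bond orders
prefix each child, and same-sphere ring closures are marked with ``&``.
It is deterministic and invariant under atom renumbering, which is all the
lookup table requires; it does not aim for byte-equality with other HOSE
implementations.  Stereochemistry is not encoded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from . import chem
from .chem import MolecularGraph

_BOND_SYM = {1: "", 2: "=", 3: "#"}


@dataclass(frozen=True)
class HoseCodeSet:
    """Spherical environment strings for one center, depths 1..max_depth."""

    codes: dict[int, str]

    def __getitem__(self, depth: int) -> str:
        return self.codes[depth]


@dataclass
class HosePrediction:
    shift_ppm: float
    depth_used: int
    n_matches: int


@dataclass
class HoseIndex:
    """Per-depth map from HOSE code to the list of training shifts."""

    by_depth: dict[int, dict[str, list[float]]] = field(default_factory=dict)
    max_depth: int = 5

    def n_stored(self, depth: int) -> int:
        return sum(len(v) for v in self.by_depth.get(depth, {}).values())


def _atom_token(graph: MolecularGraph, idx: int) -> str:
    a = graph.mol.GetAtomWithIdx(idx)
    tok = a.GetSymbol()
    q = a.GetFormalCharge()
    if q > 0:
        tok += "+" * q
    elif q < 0:
        tok += "-" * (-q)
    return tok


def hose_codes(
    graph: MolecularGraph, center: int, max_depth: int = 5
) -> HoseCodeSet:
    """Canonical sphere codes for ``center`` at every depth 1..max_depth."""
    dist = chem.shortest_path_distances(graph, center)

    def serialize(u: int, remaining: int) -> str:
        tok = _atom_token(graph, u)
        # ring closure within the same sphere
        n_closures = sum(
            1 for v in graph.neighbors(u) if dist.get(v, -1) == dist[u] and v != u
        )
        tok += "&" * n_closures
        if remaining == 0:
            return tok
        kids = [v for v in graph.neighbors(u) if dist.get(v, -1) == dist[u] + 1]
        if not kids:
            return tok
        parts = sorted(
            _BOND_SYM[graph.bond_order(u, v)] + serialize(v, remaining - 1)
            for v in kids
        )
        return tok + "(" + ",".join(parts) + ")"

    return HoseCodeSet(
        codes={d: serialize(center, d) for d in range(1, max_depth + 1)}
    )


def hose_codes_for_phosphorus(
    graph: MolecularGraph, max_depth: int = 5
) -> HoseCodeSet:
    return hose_codes(graph, chem.find_phosphorus(graph), max_depth)


def build_index(
    graphs: Sequence[MolecularGraph],
    shifts: Sequence[float],
    max_depth: int = 5,
) -> HoseIndex:
    """Index training molecules by their P-centered codes at every depth."""
    index = HoseIndex(
        by_depth={d: {} for d in range(1, max_depth + 1)}, max_depth=max_depth
    )
    for g, y in zip(graphs, shifts):
        codes = hose_codes_for_phosphorus(g, max_depth)
        for d in range(1, max_depth + 1):
            index.by_depth[d].setdefault(codes[d], []).append(float(y))
    return index


def predict_one(index: HoseIndex, graph: MolecularGraph) -> HosePrediction | None:
    """Deepest-first code lookup; ``None`` means the model abstains."""
    codes = hose_codes_for_phosphorus(graph, index.max_depth)
    for d in range(index.max_depth, 0, -1):
        matches = index.by_depth.get(d, {}).get(codes[d])
        if matches:
            return HosePrediction(
                shift_ppm=float(np.mean(matches)),
                depth_used=d,
                n_matches=len(matches),
            )
    return None


class HoseRegressor:
    """Lookup-table shift predictor over hierarchical environment codes.

    scikit-learn-style estimator.  ``X`` is a sequence of
    :class:`MolecularGraph` or SMILES strings, one phosphorus atom each.
    ``predict`` returns NaN where the model abstains; ``predict_detail``
    exposes depth used and match counts.
    """

    def __init__(self, max_depth: int = 5):
        self.max_depth = max_depth

    def get_params(self, deep: bool = True) -> dict:
        return {"max_depth": self.max_depth}

    def set_params(self, **params) -> "HoseRegressor":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    @staticmethod
    def _as_graphs(X: Iterable) -> list[MolecularGraph]:
        return [
            x if isinstance(x, MolecularGraph) else chem.parse_structure(x)
            for x in X
        ]

    def fit(self, X, y) -> "HoseRegressor":
        graphs = self._as_graphs(X)
        y = np.asarray(y, dtype=float)
        if len(graphs) != len(y):
            raise ValueError("X and y length mismatch")
        self.index_ = build_index(graphs, y, self.max_depth)
        self.n_training_ = len(graphs)
        return self

    def predict_detail(self, X) -> list[HosePrediction | None]:
        return [predict_one(self.index_, g) for g in self._as_graphs(X)]

    def predict(self, X) -> np.ndarray:
        return np.array(
            [
                p.shift_ppm if p is not None else np.nan
                for p in self.predict_detail(X)
            ]
        )


def evaluate_hose(
    model: HoseRegressor,
    graphs: Sequence[MolecularGraph],
    shifts: Sequence[float],
):
    """Metrics over covered test molecules, coverage and depth-usage histogram.

    Abstentions count as non-coverage and are excluded from the error
    metrics — never imputed.
    """
    from .evaluation import metrics

    details = model.predict_detail(graphs)
    y = np.asarray(shifts, dtype=float)
    covered = np.array([p is not None for p in details])
    depth_hist = {d: 0 for d in range(1, model.max_depth + 1)}
    for p in details:
        if p is not None:
            depth_hist[p.depth_used] += 1
    coverage = float(covered.mean()) if len(covered) else 0.0
    if covered.any():
        y_pred = np.array([p.shift_ppm for p in details if p is not None])
        report = metrics(y[covered], y_pred)
        report.coverage = coverage
    else:
        from .evaluation import MetricsReport

        report = MetricsReport(
            mae=np.nan, rmse=np.nan, r2=np.nan, n=0, coverage=0.0
        )
    return report, coverage, depth_hist
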