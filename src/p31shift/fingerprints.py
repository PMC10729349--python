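"""ECFP6 circular fingerprints and whole-molecule shift regressors.

Each molecule is folded into a 1024-bit Morgan fingerprint of radius 3
(ECFP6) computed from its canonical SMILES; five regressor families are
available on top: multiple linear regression (``mlr``), elastic-net ridge
(``lrr``), k-nearest neighbors with Jaccard distance (``knn``), random
forest / extremely-randomized trees (``rf``) and gradient tree boosting
(``xgb``).  Hyperparameters are tuned by repeated 4-fold cross-validation
on validation RMSE within fixed search ranges (mixing 1e-10..1 and penalty
0..1 for ``lrr``; k 3..60; mtry 3..1000 with variance or extra-trees split
rule and minimum node size 5; 250..1500 boosting rounds at depth 3,
learning rate 0.2..0.4, gamma 2, column subsample 0.8, row subsample 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import ExtraTreesRegressor, RandomForestRegressor
from sklearn.linear_model import ElasticNet, LinearRegression
from sklearn.model_selection import GridSearchCV, RepeatedKFold
from sklearn.neighbors import KNeighborsRegressor
from xgboost import XGBRegressor

from . import chem
from .chem import MolecularGraph
from .evaluation import CVSpec

N_BITS = 1024
RADIUS = 3

ALGOS = ("mlr", "lrr", "knn", "rf", "xgb")


@dataclass(frozen=True)
class Fingerprint:
    bits: np.ndarray  # uint8 vector of length 1024
    molecule_id: str = ""

    def __post_init__(self):
        if self.bits.shape != (N_BITS,):
            raise ValueError(f"fingerprint must have {N_BITS} bits")


_generator = rdFingerprintGenerator.GetMorganGenerator(
    radius=RADIUS, fpSize=N_BITS
)


def ecfp6(smiles_or_graph, molecule_id: str = "") -> Fingerprint:
    """1024-bit radius-3 Morgan fingerprint; canonical per molecule."""
    if isinstance(smiles_or_graph, MolecularGraph):
        mol = Chem.RemoveHs(Chem.Mol(smiles_or_graph.mol))
    else:
        mol = Chem.MolFromSmiles(str(smiles_or_graph))
        if mol is None:
            raise chem.ParseError(str(smiles_or_graph), "smiles")
    fp = _generator.GetFingerprint(mol)
    bits = np.zeros(N_BITS, dtype=np.uint8)
    bits[list(fp.GetOnBits())] = 1
    return Fingerprint(bits=bits, molecule_id=molecule_id)


class MorganFeaturizer(BaseEstimator):
    """Stateless transformer: molecules -> 1024-bit ECFP6 matrix."""

    def fit(self, X, y=None):
        return self

    def transform(self, X: Iterable) -> np.ndarray:
        return np.vstack([ecfp6(x).bits for x in X])

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.transform(X)


def _grid_for(algo: str, n_samples: int, grid_points: int) -> tuple:
    """Estimator and hyperparameter grid within the fixed search ranges."""
    gp = grid_points
    if algo == "mlr":
        return LinearRegression(), {}
    if algo == "lrr":
        penalty = np.linspace(0, 1, gp + 1)
        penalty[penalty == 0] = 1e-6
        return (
            ElasticNet(max_iter=50_000, tol=1e-6),
            {"l1_ratio": np.logspace(-10, 0, gp), "alpha": penalty},
        )
    if algo == "knn":
        ks = np.unique(np.linspace(3, 60, gp).astype(int))
        ks = ks[ks < max(n_samples, 4)]
        return (
            KNeighborsRegressor(metric="jaccard"),
            {"n_neighbors": ks},
        )
    if algo == "rf":
        mtry = np.unique(
            np.clip(
                np.logspace(np.log10(3), np.log10(1000), gp).astype(int),
                1,
                N_BITS,
            )
        )
        return (
            RandomForestRegressor(min_samples_leaf=5, n_estimators=200),
            {
                "max_features": mtry,
                "splitrule": ["variance", "extratrees"],
            },
        )
    if algo == "xgb":
        return (
            XGBRegressor(
                max_depth=3,
                gamma=2,
                colsample_bytree=0.8,
                min_child_weight=1,
                subsample=0.5,
                n_jobs=1,
                verbosity=0,
            ),
            {
                "n_estimators": np.unique(
                    np.linspace(250, 1500, gp).astype(int)
                ),
                "learning_rate": np.linspace(0.2, 0.4, max(2, gp // 3)),
            },
        )
    raise ValueError(f"unknown algo {algo!r}; choose from {ALGOS}")


class FingerprintRegressor(BaseEstimator, RegressorMixin):
    """Shift regression on ECFP6 fingerprints.

    Parameters
    ----------
    algo : {"mlr", "lrr", "knn", "rf", "xgb"}
    cv : CVSpec, cross-validation protocol for the grid search.
    grid_points : points per continuous hyperparameter range (default 10).
    seed : random seed for stochastic learners.

    ``X`` passed to ``fit``/``predict`` may be SMILES strings,
    :class:`MolecularGraph` objects, or an already-featurized
    ``(n, 1024)`` bit matrix.
    """

    def __init__(
        self,
        algo: str = "rf",
        cv: CVSpec | None = None,
        grid_points: int = 10,
        seed: int = 0,
    ):
        self.algo = algo
        self.cv = cv
        self.grid_points = grid_points
        self.seed = seed

    def _featurize(self, X) -> np.ndarray:
        if not hasattr(X, "shape") and len(list(X)) == 0:
            return np.zeros((0, N_BITS), dtype=np.uint8)
        arr = np.asarray(X)
        if arr.ndim == 2 and arr.shape[1] == N_BITS:
            return arr.astype(np.uint8)
        if arr.ndim == 2:
            raise ValueError(
                f"feature matrix must have {N_BITS} columns, got {arr.shape[1]}"
            )
        return MorganFeaturizer().transform(X)

    def fit(self, X, y) -> "FingerprintRegressor":
        Xv = self._featurize(X)
        if self.algo == "knn":
            Xv = Xv.astype(bool)  # Jaccard distance is defined on bit sets
        yv = np.asarray(y, dtype=float)
        if len(Xv) != len(yv) or len(yv) < 2:
            raise ValueError("need matching X/y with at least 2 samples")
        cv = self.cv or CVSpec(seed=self.seed)
        est, grid = _grid_for(self.algo, len(Xv), self.grid_points)

        # "splitrule" selects between variance-split forests and extra-trees
        if "splitrule" in grid:
            grid = dict(grid)
            rules = grid.pop("splitrule")
            best = None
            for rule in rules:
                base = (
                    RandomForestRegressor(min_samples_leaf=5, n_estimators=200)
                    if rule == "variance"
                    else ExtraTreesRegressor(min_samples_leaf=5, n_estimators=200)
                )
                base.set_params(random_state=self.seed)
                fitted = self._search(base, grid, Xv, yv, cv)
                if best is None or fitted.best_score_ > best.best_score_:
                    best = fitted
                    best_rule = rule
            self.model_ = best.best_estimator_
            self.cv_best_params_ = {"splitrule": best_rule, **best.best_params_}
        else:
            if hasattr(est, "random_state"):
                est.set_params(random_state=self.seed)
            if isinstance(est, XGBRegressor):
                est.set_params(random_state=self.seed)
            if grid:
                search = self._search(est, grid, Xv, yv, cv)
                self.model_ = search.best_estimator_
                self.cv_best_params_ = dict(search.best_params_)
            else:
                self.model_ = est.fit(Xv, yv)
                self.cv_best_params_ = {}
        self.n_training_ = len(Xv)
        return self

    @staticmethod
    def _search(est, grid, Xv, yv, cv: CVSpec) -> GridSearchCV:
        search = GridSearchCV(
            est,
            grid,
            scoring="neg_root_mean_squared_error",
            cv=RepeatedKFold(
                n_splits=cv.folds, n_repeats=cv.repeats, random_state=cv.seed
            ),
        )
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            search.fit(Xv, yv)
        search.best_estimator_.fit(Xv, yv)
        return search

    def predict(self, X) -> np.ndarray:
        Xv = self._featurize(X)
        if len(Xv) == 0:
            return np.array([])
        if self.algo == "knn":
            Xv = Xv.astype(bool)
        return np.asarray(self.model_.predict(Xv), dtype=float)


def fit_fp_model(
    X, y, algo: str = "rf", cv: CVSpec | None = None, **kw
) -> FingerprintRegressor:
    """Fit one of the five fingerprint regressors; thin estimator wrapper."""
    return FingerprintRegressor(algo=algo, cv=cv, **kw).fit(X, y)


def predict_fp(model: FingerprintRegressor, X) -> np.ndarray:
    return model.predict(X)
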