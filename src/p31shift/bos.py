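"""Bag-of-Substituents features and linear increment models for δ(³¹P).

An increment model assumes the shift is additive over the substituents
bound to phosphorus:

    δ = b + Σᵢ aᵢ·nᵢ

where nᵢ counts substituent i in a molecule and aᵢ is its fitted shift
contribution (ppm per occurrence).  Substituents are obtained by virtually
breaking every bond incident to the P atom; each detached fragment becomes
a canonical key.  A fragment attached through two bonds (phosphorus in a
ring) yields a single bivalent key; double-bonded partners such as the
phosphoryl oxygen (key ``*=O``) are substituents like any other.

Variants: **BoS** uses full molecules; **BoS3** first truncates each
molecule to atoms within 3 bonds of P; the rare-substituent filter drops
substituents below a minimum occurrence count together with the molecules
that use them; class-restricted fits keep only one environment label
(e.g. ``C1C1C1``, phosphines).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import ElasticNet
from sklearn.model_selection import GridSearchCV, RepeatedKFold

from . import chem
from .chem import MolecularGraph
from .evaluation import CVSpec, SplitAssignment


class CollinearityError(ValueError):
    """OLS design matrix is rank deficient; names the implicated keys."""

    def __init__(self, keys: list[str]):
        self.keys = keys
        super().__init__(
            "collinear substituent columns under MLR: " + ", ".join(keys)
        )


@dataclass
class SubstituentBag:
    """Multiset of canonical substituent keys around one P atom."""

    counts: dict[str, int]

    def arity(self, key: str) -> int:
        return key.count("*")

    def total_bonds(self) -> int:
        return sum(c * self.arity(k) for k, c in self.counts.items())


@dataclass
class BosMatrix:
    """Molecules × substituent-keys count matrix with targets."""

    X: pd.DataFrame  # index: molecule ids, columns: substituent keys
    y: pd.Series  # shift_ppm, same index
    env_labels: pd.Series | None = None

    @property
    def ids(self) -> list[str]:
        return list(self.X.index)

    @property
    def keys(self) -> list[str]:
        return list(self.X.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape


def extract_substituents(graph: MolecularGraph) -> SubstituentBag:
    """Cut every bond incident to P; canonical fragment SMILES become keys.

    Attachment points are dummy atoms (``*``) carrying the broken bond's
    order, so ``*=O`` (phosphoryl oxygen) and ``*O`` (P–O single bond)
    are distinct keys and formal charges are preserved (``*[O-]`` vs
    ``*O``).  A ring through P yields one key with two attachment points.
    """
    p = chem.find_phosphorus(graph)
    mol = Chem.Mol(graph._kekulized)
    bond_ids = [b.GetIdx() for b in mol.GetAtomWithIdx(p).GetBonds()]
    if not bond_ids:
        return SubstituentBag(counts={})
    frag_mol = Chem.FragmentOnBonds(
        mol, bond_ids, addDummies=True, dummyLabels=[(0, 0)] * len(bond_ids)
    )
    counts: dict[str, int] = {}
    for frag in Chem.GetMolFrags(frag_mol, asMols=True, sanitizeFrags=True):
        if any(a.GetSymbol() == "P" for a in frag.GetAtoms()):
            continue  # the central stub
        try:
            frag = Chem.RemoveHs(frag)
        except Exception:
            pass
        key = Chem.MolToSmiles(frag)
        counts[key] = counts.get(key, 0) + 1
    return SubstituentBag(counts=counts)


def build_bos_matrix(
    records: Sequence, radius: int | None = None
) -> BosMatrix:
    """Count matrix over all substituents found in ``records``.

    ``radius=None`` extracts from full molecules (BoS); ``radius=3``
    truncates each molecule to atoms within 3 bonds of P first (BoS3),
    capping opened valences with hydrogens before extraction.
    """
    ids, bags, shifts, envs = [], [], [], []
    for r in records:
        g = r.graph
        if radius is not None:
            g = chem.subgraph_within_bonds(g, chem.find_phosphorus(g), radius)
        ids.append(r.id)
        bags.append(extract_substituents(g))
        shifts.append(r.shift_ppm)
        envs.append(r.env_label)
    vocab = sorted({k for b in bags for k in b.counts})
    X = pd.DataFrame(
        [[b.counts.get(k, 0) for k in vocab] for b in bags],
        index=ids,
        columns=vocab,
        dtype=int,
    )
    return BosMatrix(
        X=X,
        y=pd.Series(shifts, index=ids, name="shift_ppm", dtype=float),
        env_labels=pd.Series(envs, index=ids, name="env_label"),
    )


class BosVectorizer(BaseEstimator):
    """Transformer: molecules -> substituent-count matrix.

    Learns the substituent vocabulary on ``fit``; ``transform`` maps
    molecules (SMILES, :class:`MolecularGraph` or records with a
    ``graph`` attribute) onto the learned columns, dropping substituents
    unseen at fit time (retrieve them per molecule with
    ``transform_with_unseen``).  ``radius=3`` truncates molecules around P
    before extraction (BoS3).
    """

    def __init__(self, radius: int | None = None):
        self.radius = radius

    def _bag(self, x) -> SubstituentBag:
        g = getattr(x, "graph", x)
        if not isinstance(g, MolecularGraph):
            g = chem.parse_structure(str(g))
        if self.radius is not None:
            g = chem.subgraph_within_bonds(g, chem.find_phosphorus(g), self.radius)
        return extract_substituents(g)

    def fit(self, X, y=None) -> "BosVectorizer":
        vocab = set()
        for x in X:
            vocab.update(self._bag(x).counts)
        self.vocabulary_ = sorted(vocab)
        return self

    def transform(self, X) -> pd.DataFrame:
        rows, _ = self.transform_with_unseen(X)
        return rows

    def transform_with_unseen(self, X) -> tuple[pd.DataFrame, list[list[str]]]:
        rows, unseen = [], []
        known = set(self.vocabulary_)
        for x in X:
            bag = self._bag(x)
            rows.append([bag.counts.get(k, 0) for k in self.vocabulary_])
            unseen.append(sorted(set(bag.counts) - known))
        return (
            pd.DataFrame(rows, columns=self.vocabulary_, dtype=int),
            unseen,
        )

    def fit_transform(self, X, y=None) -> pd.DataFrame:
        return self.fit(X).transform(X)


def filter_rare(matrix: BosMatrix, min_count: int = 10) -> BosMatrix:
    """Drop substituents occurring fewer than ``min_count`` times overall,
    then drop every molecule that used a dropped substituent."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    totals = matrix.X.sum(axis=0)
    keep_cols = totals[totals >= min_count].index
    drop_cols = totals[totals < min_count].index
    keep_rows = matrix.X[drop_cols].sum(axis=1) == 0
    X = matrix.X.loc[keep_rows, keep_cols]
    if X.empty:
        raise ValueError(
            f"min_count={min_count} filtered out every molecule"
        )
    return BosMatrix(
        X=X,
        y=matrix.y.loc[keep_rows],
        env_labels=(
            matrix.env_labels.loc[keep_rows]
            if matrix.env_labels is not None
            else None
        ),
    )


def subset_by_env(records: Sequence, label: str) -> list:
    """Records whose phosphorus first sphere matches ``label`` exactly."""
    return [r for r in records if r.env_label == label]


def coverage_split(
    matrix: BosMatrix,
    fractions: Mapping[str, float] | Sequence[float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> SplitAssignment:
    """Split guaranteeing every substituent appears in training at least once.

    Greedy pass over substituent columns in descending rarity: any column
    not yet covered forces one seeded-random carrier molecule into training.
    Remaining molecules are assigned randomly to reach the requested
    fractions.  This semi-random design makes increment-model training
    feasible on sparse matrices but is known to overestimate increment-model
    performance relative to fully random splits.
    """
    if not isinstance(fractions, Mapping):
        names = ["train", "valid", "test"][: len(fractions)]
        fractions = dict(zip(names, fractions))
    if "train" not in fractions:
        raise ValueError("fractions must include a 'train' part")
    rng = np.random.default_rng(seed)
    ids = matrix.ids
    n = len(ids)
    n_train_target = int(round(fractions["train"] * n))

    Xv = matrix.X.to_numpy()
    totals = Xv.sum(axis=0)
    order = np.argsort(totals, kind="stable")  # rarest first
    forced: set[int] = set()
    for col in order:
        carriers = np.nonzero(Xv[:, col] > 0)[0]
        if len(carriers) == 0:
            continue
        if not any(c in forced for c in carriers):
            forced.add(int(rng.choice(carriers)))
    if len(forced) > n_train_target:
        raise ValueError(
            f"coverage constraint needs at least {len(forced)}/{n} training "
            f"molecules (fraction >= {len(forced) / n:.3f})"
        )

    remaining = [i for i in range(n) if i not in forced]
    rng.shuffle(remaining)
    assignment = {ids[i]: "train" for i in forced}
    quota = {"train": n_train_target - len(forced)}
    cum = fractions["train"]
    prev_stop = n_train_target
    for part, frac in fractions.items():
        if part == "train":
            continue
        cum += frac
        stop = int(round(cum * n))
        quota[part] = stop - prev_stop
        prev_stop = stop
    pos = 0
    for part, q in quota.items():
        for i in remaining[pos : pos + q]:
            assignment[ids[i]] = part
        pos += q
    for i in remaining[pos:]:
        assignment[ids[i]] = "unused"
    return SplitAssignment(assignment, dict(fractions), seed, "coverage")


class IncrementRegressor(BaseEstimator, RegressorMixin):
    """Linear increment model δ = b + Σ aᵢ·nᵢ over substituent counts.

    Parameters
    ----------
    method : {"mlr", "ridge"}
        ``mlr`` is ordinary least squares and errors on exactly collinear
        designs, naming the implicated keys.  ``ridge`` is an elastic-net
        penalized fit whose mixing parameter (1e-10..1, log grid) and
        penalty strength (0..1, linear grid) are selected by repeated
        k-fold cross-validation on validation RMSE.
    cv : CVSpec
        Cross-validation protocol for the ridge search.
    grid_points : (int, int)
        Grid density for (mixing, penalty); default 20 × 21.
    """

    def __init__(
        self,
        method: str = "mlr",
        cv: CVSpec | None = None,
        grid_points: tuple[int, int] = (20, 21),
    ):
        self.method = method
        self.cv = cv
        self.grid_points = grid_points

    def _keys_from(self, X) -> list[str]:
        if isinstance(X, pd.DataFrame):
            return list(X.columns)
        return [f"x{i}" for i in range(np.asarray(X).shape[1])]

    def fit(self, X, y) -> "IncrementRegressor":
        keys = self._keys_from(X)
        Xv = np.asarray(X, dtype=float)
        yv = np.asarray(y, dtype=float)
        if Xv.shape[0] != yv.shape[0]:
            raise ValueError("X and y length mismatch")
        if (Xv.sum(axis=0) == 0).any():
            dead = [k for k, s in zip(keys, Xv.sum(axis=0)) if s == 0]
            raise ValueError(f"all-zero substituent columns: {dead}")
        if self.method == "mlr":
            A = np.column_stack([np.ones(len(Xv)), Xv])
            rank = np.linalg.matrix_rank(A)
            if rank < A.shape[1]:
                _, _, vh = np.linalg.svd(A, full_matrices=True)
                null = vh[rank:]
                implicated = sorted(
                    {
                        keys[j - 1]
                        for v in null
                        for j in np.nonzero(np.abs(v) > 1e-8)[0]
                        if j > 0
                    }
                )
                raise CollinearityError(implicated)
            coef, *_ = np.linalg.lstsq(A, yv, rcond=None)
            self.intercept_ = float(coef[0])
            coefs = coef[1:]
            self.cv_best_params_ = None
        elif self.method == "ridge":
            cv = self.cv or CVSpec()
            n_mix, n_pen = self.grid_points
            mixing = np.logspace(-10, 0, n_mix)
            penalty = np.linspace(0, 1, n_pen)
            penalty[penalty == 0] = 1e-6  # coordinate descent needs > 0
            search = GridSearchCV(
                ElasticNet(max_iter=50_000, tol=1e-6),
                {"l1_ratio": mixing, "alpha": penalty},
                scoring="neg_root_mean_squared_error",
                cv=RepeatedKFold(
                    n_splits=cv.folds,
                    n_repeats=cv.repeats,
                    random_state=cv.seed,
                ),
            )
            import warnings as _w

            with _w.catch_warnings():
                _w.simplefilter("ignore")
                search.fit(Xv, yv)
            best = search.best_estimator_
            self.intercept_ = float(best.intercept_)
            coefs = best.coef_
            self.cv_best_params_ = dict(search.best_params_)
        else:
            raise ValueError(f"unknown method {self.method!r}")
        self.keys_ = keys
        self.coef_ = np.asarray(coefs, dtype=float)
        self.increments_ = dict(zip(keys, self.coef_))
        return self

    def predict(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X.reindex(columns=self.keys_, fill_value=0)
        Xv = np.asarray(X, dtype=float)
        return self.intercept_ + Xv @ self.coef_

    def predict_bag(self, bag: SubstituentBag) -> tuple[float, list[str]]:
        """Predict from a substituent bag; unseen keys are reported and
        excluded from the sum (the prediction is flagged, not refused)."""
        unseen = sorted(k for k in bag.counts if k not in self.increments_)
        shift = self.intercept_ + sum(
            self.increments_[k] * c
            for k, c in bag.counts.items()
            if k in self.increments_
        )
        return float(shift), unseen


def fit_increment(
    matrix: BosMatrix, method: str = "mlr", cv: CVSpec | None = None, **kw
) -> IncrementRegressor:
    """Fit an increment model on a BoS matrix; returns the fitted estimator."""
    return IncrementRegressor(method=method, cv=cv, **kw).fit(matrix.X, matrix.y)


def predict_increment(
    model: IncrementRegressor, bag: SubstituentBag
) -> tuple[float, list[str]]:
    return model.predict_bag(bag)
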