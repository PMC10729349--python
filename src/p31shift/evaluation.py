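"""Splits, regression metrics and per-class breakdowns.

Model families are compared on identical random splits (train 60% /
validation 20% / test 20% by default) with MAE, RMSE and R².  R² defaults
to the traditional 1 − SS_res/SS_tot definition; the squared-Pearson
variant is available via ``r2_variant="correlation"`` since some toolchains
report that instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass
class CVSpec:
    """Repeated k-fold cross-validation protocol for hyperparameter tuning."""

    folds: int = 4
    repeats: int = 3
    train_fraction: float = 0.8
    objective: str = "rmse"
    seed: int = 0

    def __post_init__(self):
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


@dataclass
class MetricsReport:
    mae: float
    rmse: float
    r2: float
    n: int
    coverage: float = 1.0

    def as_dict(self) -> dict:
        return {
            "mae": self.mae,
            "rmse": self.rmse,
            "r2": self.r2,
            "n": self.n,
            "coverage": self.coverage,
        }


@dataclass
class SplitAssignment:
    """Exhaustive, disjoint partition of record ids into named splits."""

    assignment: dict[str, str]  # id -> train | valid | test | unused
    fractions: Mapping[str, float]
    seed: int
    strategy: str = "random"

    def ids(self, part: str) -> list[str]:
        return [i for i, p in self.assignment.items() if p == part]

    def mask(self, ids: Sequence[str], part: str) -> np.ndarray:
        return np.array([self.assignment.get(i) == part for i in ids])


def random_split(
    ids: Sequence[str],
    fractions: Mapping[str, float] | Sequence[float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> SplitAssignment:
    """Seeded uniform split honoring fractions up to rounding.

    ``fractions`` may be a mapping (part name -> fraction) or a sequence,
    interpreted as (train, valid, test).  Fractions summing to less than 1
    leave the remainder ``unused``.
    """
    if not isinstance(fractions, Mapping):
        names = ["train", "valid", "test"][: len(fractions)]
        fractions = dict(zip(names, fractions))
    if any(f < 0 for f in fractions.values()):
        raise ValueError("fractions must be non-negative")
    total = sum(fractions.values())
    if total > 1 + 1e-9:
        raise ValueError("fractions must sum to at most 1")
    rng = np.random.default_rng(seed)
    ids = list(ids)
    order = rng.permutation(len(ids))
    n = len(ids)
    assignment: dict[str, str] = {}
    start = 0
    cum = 0.0
    for part, frac in fractions.items():
        cum += frac
        stop = int(round(cum * n))
        for k in order[start:stop]:
            assignment[ids[k]] = part
        start = stop
    for k in order[start:]:
        assignment[ids[k]] = "unused"
    return SplitAssignment(assignment, dict(fractions), seed, "random")


def metrics(
    y_true: Sequence[float],
    y_pred: Sequence[float],
    r2_variant: str = "traditional",
) -> MetricsReport:
    """MAE, RMSE and R² of a prediction set.

    On zero-variance ``y_true`` with nonzero residuals the traditional R²
    is undefined and reported as NaN.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("y_true and y_pred must be equal-length and nonempty")
    err = y_pred - y_true
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    ss_res = float(np.sum(err**2))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if r2_variant == "traditional":
        if ss_tot == 0.0:
            r2 = 1.0 if ss_res == 0.0 else float("nan")
        else:
            r2 = 1.0 - ss_res / ss_tot
    elif r2_variant == "correlation":
        if np.std(y_true) == 0 or np.std(y_pred) == 0:
            r2 = float("nan")
        else:
            r2 = float(np.corrcoef(y_true, y_pred)[0, 1] ** 2)
    else:
        raise ValueError(f"unknown r2_variant {r2_variant!r}")
    return MetricsReport(mae=mae, rmse=rmse, r2=r2, n=len(y_true))


def per_class_mae(
    results: pd.DataFrame, n_groups: int = 19
) -> pd.DataFrame:
    """MAE per environment label for the most frequent labels.

    ``results`` needs columns ``y_true``, ``y_pred``, ``env_label``
    (and optionally ``model``, in which case groups are per model).
    Labels beyond the ``n_groups`` most frequent are pooled as ``"Other"``.
    """
    df = results.copy()
    top = df["env_label"].value_counts().head(n_groups).index
    df["group"] = df["env_label"].where(df["env_label"].isin(top), "Other")
    keys = ["group"] + (["model"] if "model" in df.columns else [])
    out = (
        df.assign(abs_err=(df["y_pred"] - df["y_true"]).abs())
        .groupby(keys)
        .agg(mae=("abs_err", "mean"), n=("abs_err", "size"))
        .reset_index()
    )
    return out.sort_values("n", ascending=False).reset_index(drop=True)


def parity_export(
    ids: Sequence[str],
    y_true: Sequence[float],
    y_pred: Sequence[float],
    env_labels: Sequence[str],
    model: str,
) -> pd.DataFrame:
    """Long-format parity-plot table: one row per prediction, no aggregation."""
    return pd.DataFrame(
        {
            "id": list(ids),
            "y_true": np.asarray(y_true, dtype=float),
            "y_pred": np.asarray(y_pred, dtype=float),
            "env_label": list(env_labels),
            "model": model,
        }
    )
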