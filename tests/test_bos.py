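"""Substituent extraction, BoS matrices, coverage splits, increment fits."""

import numpy as np
import pandas as pd
import pytest

from p31shift import bos, chem, synthetic
from p31shift.bos import (
    CollinearityError,
    IncrementRegressor,
    build_bos_matrix,
    coverage_split,
    extract_substituents,
    filter_rare,
    fit_increment,
    subset_by_env,
    SubstituentBag,
)


def g(smiles):
    return chem.parse_structure(smiles)


def test_extract_triphenylphosphine():
    bag = extract_substituents(g("c1ccccc1P(c1ccccc1)c1ccccc1"))
    assert bag.counts == {"*c1ccccc1": 3}
    assert bag.total_bonds() == 3


def test_extract_ph3():
    bag = extract_substituents(g("P"))
    assert bag.counts == {"*[H]": 3}


def test_extract_phospholane_ring_gives_bivalent_key():
    # 1H-phosphacyclopentane: the ring contributes one bivalent substituent
    bag = extract_substituents(g("C1CCPC1"))
    assert bag.counts == {"*CCCC*": 1, "*[H]": 1}
    assert bag.arity("*CCCC*") == 2
    assert bag.total_bonds() == 3


def test_extract_oxo_and_charge_are_distinct_keys():
    bag = extract_substituents(g("COP(=O)(OC)[O-]"))
    assert bag.counts == {"*OC": 2, "*=O": 1, "*[O-]": 1}


def test_bag_invariant_bond_conservation(noiseless_records):
    for r in noiseless_records[:50]:
        bag = extract_substituents(r.graph)
        p = chem.find_phosphorus(r.graph)
        assert bag.total_bonds() == len(r.graph.neighbors(p))


def test_vectorizer_pipeline_composability(noiseless_records):
    """BosVectorizer + IncrementRegressor chain in an sklearn Pipeline."""
    from sklearn.pipeline import Pipeline

    records = noiseless_records
    y = np.array([r.shift_ppm for r in records])
    pipe = Pipeline(
        [("bos", bos.BosVectorizer()), ("inc", IncrementRegressor("mlr"))]
    )
    pipe.fit(records, y)
    assert np.allclose(pipe.predict(records), y, atol=1e-8)
    # unseen substituents are reported per molecule
    vec = bos.BosVectorizer().fit(records[:5])
    _, unseen = vec.transform_with_unseen(records)
    assert any(unseen) or vec.vocabulary_  # list aligned with input
    assert len(unseen) == len(records)


def test_build_matrix_shape_and_radius_vocabulary(noiseless_records):
    m_full = build_bos_matrix(noiseless_records)
    m_r3 = build_bos_matrix(noiseless_records, radius=3)
    assert m_full.shape[0] == m_r3.shape[0] == len(noiseless_records)
    assert m_r3.shape[1] <= m_full.shape[1]
    assert (m_full.X.to_numpy() >= 0).all()


def test_filter_rare_identity_and_drop():
    records = synthetic.generate(
        synthetic.GeneratorConfig(n_molecules=150, seed=5, noise_sd=0)
    )
    m = build_bos_matrix(records)
    assert filter_rare(m, min_count=1).shape == m.shape
    filtered = filter_rare(m, min_count=10)
    assert filtered.shape[1] <= m.shape[1]
    assert filtered.shape[0] <= m.shape[0]
    # rarity is measured on the original dataset (single pass): dropped
    # columns were rare there, and no surviving molecule used any of them
    totals = m.X.sum(axis=0)
    assert all(totals[k] < 10 for k in set(m.keys) - set(filtered.keys))
    assert all(totals[k] >= 10 for k in filtered.keys)
    dropped = set(m.keys) - set(filtered.keys)
    assert (m.X.loc[filtered.ids, sorted(dropped)].sum(axis=1) == 0).all()


def test_filter_rare_everything_gone_errors():
    records = synthetic.generate(
        synthetic.GeneratorConfig(n_molecules=5, seed=6, noise_sd=0)
    )
    m = build_bos_matrix(records)
    with pytest.raises(ValueError, match="filtered out"):
        filter_rare(m, min_count=1000)


def test_subset_by_env(noiseless_records):
    phosphines = subset_by_env(noiseless_records, "C1C1C1")
    assert all(r.env_label == "C1C1C1" for r in phosphines)
    assert subset_by_env(noiseless_records, "Xx9") == []
    assert subset_by_env(phosphines, "C1C1C1") == phosphines


def test_coverage_split_forces_unique_carrier_into_training():
    ids = ["m1", "m2", "m3", "m4"]
    X = pd.DataFrame(
        {"a": [1, 1, 1, 0], "b": [0, 0, 0, 2]},
        index=ids,
    )
    m = bos.BosMatrix(X=X, y=pd.Series([1.0, 2.0, 3.0, 4.0], index=ids))
    split = coverage_split(m, (0.5, 0.25, 0.25), seed=0)
    assert split.assignment["m4"] == "train"  # only carrier of b


def test_coverage_split_deterministic_and_covering():
    records = synthetic.generate(
        synthetic.GeneratorConfig(n_molecules=1000, seed=7, noise_sd=0)
    )
    m = build_bos_matrix(records)
    s1 = coverage_split(m, (0.8, 0.0, 0.2), seed=4)
    s2 = coverage_split(m, (0.8, 0.0, 0.2), seed=4)
    assert s1.assignment == s2.assignment
    n_train = len(s1.ids("train"))
    assert abs(n_train - 800) <= 1
    train_mask = m.X.index.isin(s1.ids("train"))
    assert (m.X.loc[train_mask].sum(axis=0) > 0).all()  # every column covered


def test_coverage_split_infeasible_fraction_errors():
    records = synthetic.generate(
        synthetic.GeneratorConfig(n_molecules=60, seed=8, noise_sd=0)
    )
    m = build_bos_matrix(records)
    with pytest.raises(ValueError, match="fraction"):
        coverage_split(m, (0.01, 0.5, 0.49), seed=0)


def test_mlr_exact_recovery_on_noiseless_data(noiseless_records, library):
    m = build_bos_matrix(noiseless_records)
    model = fit_increment(m, method="mlr")
    truth = library.increments_by_key()
    for key, a in model.increments_.items():
        assert a == pytest.approx(truth[key], abs=1e-6)
    assert model.intercept_ == pytest.approx(library.intercept, abs=1e-6)


def test_mlr_collinearity_error_names_keys_ridge_survives():
    X = pd.DataFrame(
        {"dup1": [1, 2, 0, 3, 1, 2], "dup2": [1, 2, 0, 3, 1, 2],
         "other": [0, 1, 2, 0, 1, 1]}
    )
    y = pd.Series([1.0, 2.0, 0.5, 3.0, 1.2, 2.2])
    with pytest.raises(CollinearityError) as exc:
        IncrementRegressor(method="mlr").fit(X, y)
    assert {"dup1", "dup2"} <= set(exc.value.keys)
    from p31shift.evaluation import CVSpec

    ridge = IncrementRegressor(
        method="ridge", cv=CVSpec(folds=3, repeats=1), grid_points=(3, 3)
    ).fit(X, y)
    assert np.isfinite(ridge.predict(X)).all()


def test_predict_bag_unseen_keys_flagged(noiseless_records, library):
    m = build_bos_matrix(noiseless_records[:100])
    model = fit_increment(m, method="mlr")
    empty = SubstituentBag(counts={})
    assert model.predict_bag(empty) == (model.intercept_, [])
    shift, unseen = model.predict_bag(
        SubstituentBag(counts={"*C": 1, "*[Ge]": 1})
    )
    assert unseen == ["*[Ge]"]
    assert shift == pytest.approx(model.intercept_ + model.increments_["*C"])


def test_matrix_prediction_matches_bag_prediction(noiseless_records):
    m = build_bos_matrix(noiseless_records)
    model = fit_increment(m, method="mlr")
    row = m.X.iloc[[7]]
    bag = SubstituentBag(
        counts={k: int(v) for k, v in m.X.iloc[7].items() if v > 0}
    )
    shift, unseen = model.predict_bag(bag)
    assert not unseen
    assert shift == pytest.approx(model.predict(row)[0])


def test_increment_prediction_additivity(noiseless_records):
    m = build_bos_matrix(noiseless_records[:100])
    model = fit_increment(m, method="mlr")
    keys = model.keys_[:4]
    b1 = SubstituentBag(counts={keys[0]: 1, keys[1]: 2})
    b2 = SubstituentBag(counts={keys[2]: 1, keys[3]: 1})
    union = SubstituentBag(counts={**b1.counts, **b2.counts})
    b = model.intercept_
    lhs = model.predict_bag(union)[0] - b
    rhs = (model.predict_bag(b1)[0] - b) + (model.predict_bag(b2)[0] - b)
    assert lhs == pytest.approx(rhs)


def test_interaction_degrades_linear_fit(library):
    base = dict(n_molecules=500, seed=9, noise_sd=0.0)
    additive = synthetic.generate(synthetic.GeneratorConfig(**base))
    inter = synthetic.generate(
        synthetic.GeneratorConfig(**base, interaction_strength=0.5)
    )
    rmse = {}
    for name, recs in [("additive", additive), ("interacting", inter)]:
        m = build_bos_matrix(recs)
        model = fit_increment(m, method="mlr")
        resid = model.predict(m.X) - m.y.to_numpy()
        rmse[name] = float(np.sqrt(np.mean(resid**2)))
    assert rmse["interacting"] > rmse["additive"]
    assert rmse["additive"] < 1e-6
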