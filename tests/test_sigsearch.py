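"""LOOCV-scored signature search: AUC behaviour, enumeration, stepwise growth."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LogisticRegression

from ptxrank import exhaustive_search, loocv_auc, random_probe, stepwise_signature
from ptxrank.sigsearch import feature_matrix


def toy_data(seed=0, n=24, n_prot=8, informative=None, effect=2.0):
    """Positive 'count' data with optional label-associated proteins."""
    rng = np.random.default_rng(seed)
    y = np.array([0] * (n // 2) + [1] * (n - n // 2))
    X = rng.normal(0, 1, size=(n_prot, n))
    for i in informative or []:
        X[i] += effect * y
    pool = [f"P{i}" for i in range(n_prot)]
    data = pd.DataFrame(2.0 ** X, index=pool, columns=[f"s{i}" for i in range(n)])
    return pool, data, y


def test_perfect_separator_gives_auc_one():
    pool, data, y = toy_data(seed=1, informative=[0], effect=20.0)
    X = feature_matrix(data, ["P0"])
    assert loocv_auc(X, y) == pytest.approx(1.0)


def test_label_inversion_maps_auc():
    """Ranking symmetry: inverting labels against a fixed score vector maps
    the AUC to its complement."""
    from ptxrank.sigsearch import _auc

    rng = np.random.default_rng(2)
    scores = rng.normal(size=30)
    y = (rng.uniform(size=30) < 0.5).astype(int)
    y[0], y[1] = 0, 1  # both classes present
    a = _auc(y, scores)
    b = _auc(1 - y, scores)
    assert a + b == pytest.approx(1.0, abs=1e-12)


def test_null_feature_auc_not_optimistic():
    """A label-independent feature cannot look discriminative under LOOCV.

    Pooled leave-one-out predictions are pessimistic under the null (the
    held-out sample's class is under-represented in its training fold), so
    null AUCs centre at or below 0.5 and essentially never reach the range
    of genuinely informative subsets.
    """
    aucs = []
    for seed in range(30):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(40, 1))
        y = np.array([0] * 20 + [1] * 20)
        aucs.append(loocv_auc(X, y))
    aucs = np.array(aucs)
    assert np.median(aucs) <= 0.6
    assert (aucs >= 0.75).mean() <= 0.1


def test_single_class_errors():
    X = np.random.default_rng(0).normal(size=(10, 2))
    with pytest.raises(ValueError):
        loocv_auc(X, np.zeros(10))


def test_exhaustive_count_only_62_choose_4():
    rep = exhaustive_search([f"P{i}" for i in range(62)], 4, count_only=True)
    assert rep.n_evaluated == 557_845 == math.comb(62, 4)


def test_exhaustive_small_pool_counts():
    pool, data, y = toy_data(n_prot=5)
    rep = exhaustive_search(pool, 4, data, y)
    assert rep.n_evaluated == 5


def test_pool_smaller_than_k_errors():
    with pytest.raises(ValueError):
        exhaustive_search(["A", "B"], 4, count_only=True)


def sklearn_loocv_auc(Xs, y):
    """Independent LOOCV scorer built on scikit-learn."""
    from scipy.stats import rankdata

    n = len(y)
    preds = np.empty(n)
    for i in range(n):
        m = np.ones(n, bool)
        m[i] = False
        mu, sd = Xs[m].mean(0), Xs[m].std(0)
        sd[sd == 0] = 1.0
        clf = LogisticRegression(C=1000.0, solver="lbfgs", max_iter=2000, tol=1e-10)
        clf.fit((Xs[m] - mu) / sd, y[m])
        preds[i] = clf.predict_proba(((Xs[i] - mu) / sd).reshape(1, -1))[0, 1]
    pos = y == 1
    n1, n0 = pos.sum(), n - pos.sum()
    return (rankdata(preds)[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)


def test_exhaustive_matches_bruteforce_oracle():
    """All 70 4-subsets of an 8-protein pool rank identically to an
    independent enumeration scored with scikit-learn logistic LOOCV."""
    pool, data, y = toy_data(seed=5, informative=[0, 3], effect=0.8)
    rep = exhaustive_search(pool, 4, data, y, keep=70, top_f=70)
    X = feature_matrix(data, pool)
    col = {p: i for i, p in enumerate(pool)}
    oracle = {
        combo: sklearn_loocv_auc(X[:, [col[p] for p in combo]], y)
        for combo in itertools.combinations(pool, 4)
    }
    oracle_ranked = sorted(oracle.items(), key=lambda kv: (-kv[1], kv[0]))
    assert len(rep.ranked) == 70
    for (auc, combo), (combo_o, auc_o) in zip(rep.ranked, oracle_ranked):
        assert combo == combo_o
        assert auc == pytest.approx(auc_o, abs=1e-6)


def test_pool_order_does_not_change_results():
    pool, data, y = toy_data(seed=6, informative=[1])
    rep1 = exhaustive_search(pool, 3, data, y)
    rep2 = exhaustive_search(pool[::-1], 3, data, y)
    assert rep1.ranked == rep2.ranked


def test_random_probe_deterministic_and_saturates():
    pool, data, y = toy_data(seed=7, n_prot=7, informative=[2])
    r1 = random_probe(pool, 5, data, y, n_draws=400, seed=11)
    r2 = random_probe(pool, 5, data, y, n_draws=400, seed=11)
    assert r1.ranked == r2.ranked
    # 400 draws over C(7,5)=21 subsets covers the space: top combo matches
    ex = exhaustive_search(pool, 5, data, y, keep=25, top_f=25)
    assert r1.ranked[0] == ex.ranked[0]


def test_frequency_table_counting_bound():
    pool, data, y = toy_data(seed=8, n_prot=7)
    rep = random_probe(pool, 4, data, y, n_draws=100, seed=3, top_f=10)
    assert sum(rep.frequencies.values()) <= 4 * 10


def test_stepwise_finds_informative_protein():
    hits = 0
    for seed in range(10):
        pool, data, y = toy_data(seed=seed, n_prot=10, informative=[4], effect=2.5)
        model = stepwise_signature(pool, data, y, start="highest_auc")
        hits += "P4" in model.proteins
    assert hits >= 9


def test_stepwise_huge_epsilon_stops_immediately():
    pool, data, y = toy_data(seed=9, informative=[0])
    model = stepwise_signature(pool, data, y, start="highest_auc", epsilon=1.0)
    assert model.k == 1


def test_stepwise_combines_complementary_proteins():
    """Two additively half-informative proteins are both selected."""
    rng = np.random.default_rng(10)
    n = 40
    y = np.array([0] * 20 + [1] * 20)
    latent = 3.0 * y + rng.normal(0, 1, n)
    X = rng.normal(0, 1, size=(6, n))
    X[0] = 0.5 * latent + rng.normal(0, 1, n)
    X[1] = 0.5 * latent - X[0] + 3.0 * y  # complementary component
    pool = [f"P{i}" for i in range(6)]
    data = pd.DataFrame(2.0 ** X, index=pool, columns=[f"s{i}" for i in range(n)])
    model = stepwise_signature(pool, data, y, start="highest_auc")
    assert {"P0", "P1"} <= set(model.proteins)


def test_stepwise_explicit_start_protein():
    pool, data, y = toy_data(seed=11, informative=[0], effect=2.0)
    model = stepwise_signature(pool, data, y, start="P5")
    assert model.proteins[0] == "P5"
    assert model.trace[0][0] == "P5"
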