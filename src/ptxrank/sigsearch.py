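"""Combinatorial multi-protein signature search with LOOCV-scored logistic models.

Small protein subsets (4-mers exhaustively, 5-mers by random probing) are
scored as ridge-stabilized logistic classifiers of poor vs good response,
using the area under the ROC curve of pooled leave-one-out held-out
probabilities.  A light L2 penalty keeps the fits finite under the perfect
separation that small subsets of small cohorts routinely produce, and
features are standardized inside each training fold so no information leaks
from the held-out sample.  A forward stepwise construction yields compact
signatures starting from either the single best-AUC protein or a designated
(e.g. most robust) marker.
"""

from __future__ import annotations

import heapq
import itertools
import logging
import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RIDGE_LAMBDA = 1e-3


def fit_ridge_logistic(X: np.ndarray, y: np.ndarray, lam: float = RIDGE_LAMBDA,
                       max_iter: int = 50, tol: float = 1e-9) -> np.ndarray:
    """Newton/IRLS fit of an L2-penalized logistic model.

    ``X`` is (n, k) of already-standardized features; returns weights
    ``[intercept, w_1..w_k]``.  The intercept is not penalized.
    """
    n, k = X.shape
    Xd = np.hstack([np.ones((n, 1)), X])
    w = np.zeros(k + 1)
    pen = lam * np.eye(k + 1)
    pen[0, 0] = 0.0
    for _ in range(max_iter):
        eta = np.clip(Xd @ w, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = Xd.T @ (y - mu) - pen @ w
        wts = np.maximum(mu * (1.0 - mu), 1e-10)
        hess = (Xd * wts[:, None]).T @ Xd + pen
        step = np.linalg.solve(hess, grad)
        w = w + step
        if np.max(np.abs(step)) < tol:
            break
    return w


def _predict_proba(w: np.ndarray, X: np.ndarray) -> np.ndarray:
    eta = np.clip(w[0] + X @ w[1:], -30, 30)
    return 1.0 / (1.0 + np.exp(-eta))


def _auc(y: np.ndarray, scores: np.ndarray) -> float:
    """Rank-based AUC (Mann-Whitney), ties averaged."""
    from scipy.stats import rankdata

    pos = y == 1
    n1 = int(pos.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined for single-class labels")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def loocv_auc(features: np.ndarray, labels: np.ndarray, lam: float = RIDGE_LAMBDA) -> float:
    """Pooled leave-one-out AUC of a ridge-logistic model.

    For each sample the model is refit on the remaining samples (features
    re-standardized on the training fold) and the held-out probability
    recorded; the AUC is computed once on the n pooled held-out predictions.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ValueError("features must be (n_samples, n_proteins) aligned with labels")
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("labels must contain exactly two classes")
    y01 = (y == classes[1]).astype(float)
    if y01.sum() < 3 or (len(y01) - y01.sum()) < 3:
        raise ValueError("need at least 3 samples per class for LOOCV")

    n = len(y01)
    preds = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xtr = X[mask]
        mean = Xtr.mean(axis=0)
        sd = Xtr.std(axis=0)
        sd[sd == 0] = 1.0
        w = fit_ridge_logistic((Xtr - mean) / sd, y01[mask], lam=lam)
        preds[i] = _predict_proba(w, (X[i] - mean) / sd)
    return _auc(y01, preds)


@dataclass
class SignatureModel:
    """A protein subset with its fitted classifier and LOOCV performance."""

    proteins: tuple[str, ...]
    coefficients: np.ndarray  # [intercept, w per protein], full-data fit
    loocv_auc: float
    trace: list[tuple[str, float]] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.proteins)


@dataclass
class SearchReport:
    """Outcome of a combinatorial signature search."""

    k: int
    n_evaluated: int
    ranked: list[tuple[float, tuple[str, ...]]]  # (auc, combo), best first
    frequencies: dict[str, int]  # protein -> count among top-F combos
    top_f: int
    stepwise: list[SignatureModel] = field(default_factory=list)

    def top30(self) -> list[tuple[str, ...]]:
        return [combo for _, combo in self.ranked[:30]]

    def protein_rank(self, protein: str) -> int | None:
        """1-based rank of the best top-30 combo containing ``protein``."""
        for pos, combo in enumerate(self.top30(), start=1):
            if protein in combo:
                return pos
        return None


def feature_matrix(data: pd.DataFrame, proteins) -> np.ndarray:
    """Extract a samples × proteins feature block on the log2(x+1) scale."""
    missing = [p for p in proteins if p not in data.index]
    if missing:
        raise KeyError(f"proteins not in matrix: {missing}")
    return np.log2(data.loc[list(proteins)].to_numpy(dtype=float).T + 1.0)


def _rank_and_report(
    k: int,
    scored: dict[tuple[str, ...], float],
    n_evaluated: int,
    top_f: int,
    keep: int,
) -> SearchReport:
    # deterministic order: AUC descending, then lexicographic combo ids
    ranked_all = heapq.nsmallest(
        max(keep, top_f), scored.items(), key=lambda kv: (-kv[1], kv[0])
    )
    ranked = [(auc, combo) for combo, auc in ranked_all]
    freq: Counter[str] = Counter()
    for _, combo in ranked[:top_f]:
        freq.update(combo)
    return SearchReport(
        k=k,
        n_evaluated=n_evaluated,
        ranked=ranked[:keep],
        frequencies=dict(freq),
        top_f=top_f,
    )


def exhaustive_search(
    pool,
    k: int,
    data: pd.DataFrame | None = None,
    labels=None,
    top_f: int = 100,
    keep: int = 100,
    count_only: bool = False,
) -> SearchReport:
    """Evaluate every k-subset of ``pool`` by LOOCV AUC.

    ``data`` is a protein × sample matrix and ``labels`` the per-sample
    binary response.  With ``count_only`` the combinations are only counted
    (exactly C(|pool|, k)), which is instantaneous for any pool size.
    """
    pool = sorted(pool)
    if len(pool) < k:
        raise ValueError(f"pool of {len(pool)} proteins is smaller than k={k}")
    n_comb = math.comb(len(pool), k)
    if count_only:
        return SearchReport(k=k, n_evaluated=n_comb, ranked=[], frequencies={}, top_f=top_f)
    if data is None or labels is None:
        raise ValueError("data and labels required unless count_only")
    y = np.asarray(labels)
    scored: dict[tuple[str, ...], float] = {}
    X_all = feature_matrix(data, pool)
    col = {p: i for i, p in enumerate(pool)}
    for combo in itertools.combinations(pool, k):
        idx = [col[p] for p in combo]
        scored[combo] = loocv_auc(X_all[:, idx], y)
    assert len(scored) == n_comb
    return _rank_and_report(k, scored, n_comb, top_f, keep)


def random_probe(
    pool,
    k: int,
    data: pd.DataFrame,
    labels,
    n_draws: int = 500_000,
    seed: int = 0,
    top_f: int = 100,
    keep: int = 100,
) -> SearchReport:
    """Score ``n_draws`` uniformly random k-subsets of ``pool``.

    Draws are without replacement within a subset; repeated subsets across
    draws are allowed but scored once and deduplicated in the report.
    Deterministic for a fixed seed.
    """
    pool = sorted(pool)
    if len(pool) < k:
        raise ValueError(f"pool of {len(pool)} proteins is smaller than k={k}")
    rng = np.random.default_rng(seed)
    y = np.asarray(labels)
    X_all = feature_matrix(data, pool)
    col = {p: i for i, p in enumerate(pool)}
    scored: dict[tuple[str, ...], float] = {}
    n_pool = len(pool)
    for _ in range(n_draws):
        combo = tuple(sorted(pool[j] for j in rng.choice(n_pool, size=k, replace=False)))
        if combo not in scored:
            idx = [col[p] for p in combo]
            scored[combo] = loocv_auc(X_all[:, idx], y)
    return _rank_and_report(k, scored, n_draws, top_f, keep)


def fit_signature(data: pd.DataFrame, labels, proteins) -> SignatureModel:
    """Fit the final full-data model for a protein subset."""
    y = np.asarray(labels)
    classes = np.unique(y)
    y01 = (y == classes[1]).astype(float)
    X = feature_matrix(data, proteins)
    mean, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    w = fit_ridge_logistic((X - mean) / sd, y01)
    return SignatureModel(
        proteins=tuple(proteins),
        coefficients=w,
        loocv_auc=loocv_auc(X, y),
    )


def stepwise_signature(
    pool,
    data: pd.DataFrame,
    labels,
    start: str = "highest_auc",
    epsilon: float = 0.005,
    max_k: int = 6,
) -> SignatureModel:
    """Forward-selected logistic signature.

    Starts from ``start`` — either the literal protein id (e.g. the most
    robust marker) or ``"highest_auc"`` to seed with the best single-protein
    LOOCV AUC — and greedily adds the protein whose inclusion most improves
    the LOOCV AUC, stopping when no addition improves it by more than
    ``epsilon`` or the signature reaches ``max_k`` proteins.
    """
    pool = sorted(pool)
    if not pool:
        raise ValueError("empty pool")
    y = np.asarray(labels)
    X_all = feature_matrix(data, pool)
    col = {p: i for i, p in enumerate(pool)}

    def score(subset) -> float:
        return loocv_auc(X_all[:, [col[p] for p in subset]], y)

    if start == "highest_auc":
        singles = sorted(((score([p]), p) for p in pool), key=lambda t: (-t[0], t[1]))
        best_auc, current = singles[0][0], [singles[0][1]]
    else:
        if start not in col:
            raise KeyError(f"start protein {start!r} not in pool")
        current = [start]
        best_auc = score(current)
    trace = [(current[0], best_auc)]

    while len(current) < max_k:
        candidates = [p for p in pool if p not in current]
        if not candidates:
            break
        scored = sorted(
            ((score(current + [p]), p) for p in candidates), key=lambda t: (-t[0], t[1])
        )
        auc, prot = scored[0]
        if auc - best_auc <= epsilon:
            break
        current.append(prot)
        best_auc = auc
        trace.append((prot, auc))

    model = fit_signature(data, y, current)
    model.trace = trace
    return model
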