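"""Beta-binomial differential expression testing and significance tiers.

Spectral counts for one protein are modelled as beta-binomial: sample ``s``
contributes ``k_s`` spectra out of a library of ``n_s`` total spectra, where
the per-sample success proportion ``q_s`` is itself beta-distributed with
mean ``pi`` and overdispersion ``phi``.  Writing the beta parameters as
``alpha = pi * (1/phi - 1)`` and ``beta = (1 - pi) * (1/phi - 1)`` gives
``phi = 1 / (alpha + beta + 1)``, so ``phi -> 0`` recovers the plain binomial
and ``phi -> 1`` a maximally overdispersed mixture.

Two groups are compared with a likelihood-ratio test: the null model shares
one mean proportion across both groups (parameters ``pi``, ``phi``), the
alternative fits group-specific means with a shared ``phi`` (``pi_A``,
``pi_B``, ``phi``).  Twice the log-likelihood gain is referred to a
chi-square distribution with one degree of freedom.

Significance tiers stack three nested gates on each protein:

* T1 — p < 0.05,
* T2 — T1 and data presence >= 60% of samples in the upregulated group,
* T3 — T2 and fold-change > 1.5.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import betaln, digamma, gammaln
from scipy.stats import chi2

from .containers import NORMALIZED_SC, CountMatrix
from .preprocess import group_stats
from .survival import assign_response_groups

logger = logging.getLogger(__name__)

_PI_BOUNDS = (1e-9, 1.0 - 1e-9)
_PHI_BOUNDS = (1e-9, 0.999)


def _bb_loglik(k: np.ndarray, n: np.ndarray, pi: float, phi: float) -> float:
    """Beta-binomial log-likelihood (including the binomial coefficient)."""
    s = 1.0 / phi - 1.0
    a = pi * s
    b = (1.0 - pi) * s
    const = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return float(np.sum(const + betaln(k + a, n - k + b) - betaln(a, b)))


def _bb_grad_ab(k: np.ndarray, n: np.ndarray, pi: float, phi: float) -> tuple[float, float]:
    """Gradient of the log-likelihood w.r.t. the beta parameters (a, b)."""
    s = 1.0 / phi - 1.0
    a = pi * s
    b = (1.0 - pi) * s
    common = -digamma(n + a + b) + digamma(a + b)
    da = float(np.sum(digamma(k + a) - digamma(a) + common))
    db = float(np.sum(digamma(n - k + b) - digamma(b) + common))
    return da, db


def _grad_pi_phi(da: float, db: float, pi: float, phi: float) -> tuple[float, float]:
    s = 1.0 / phi - 1.0
    dpi = s * (da - db)
    dphi = -(pi * da + (1.0 - pi) * db) / phi**2
    return dpi, dphi


def _phi_moment(k: np.ndarray, n: np.ndarray) -> float:
    """Method-of-moments overdispersion start value."""
    p = k / n
    pbar = max(p.mean(), 1e-12)
    excess = p.var() - np.mean(pbar * (1 - pbar) / n)
    return float(np.clip(excess / max(pbar * (1 - pbar), 1e-12), 1e-4, 0.9))


def _fit_null(k: np.ndarray, n: np.ndarray) -> float:
    p0 = np.clip(k.sum() / n.sum(), *_PI_BOUNDS)

    def nll(theta):
        pi, phi = theta
        f = -_bb_loglik(k, n, pi, phi)
        da, db = _bb_grad_ab(k, n, pi, phi)
        dpi, dphi = _grad_pi_phi(da, db, pi, phi)
        return f, -np.array([dpi, dphi])

    phi_mom = _phi_moment(k, n)
    best = math.inf
    for phi0 in (phi_mom, 0.25, 0.01):
        res = minimize(
            nll,
            x0=[p0, phi0],
            jac=True,
            method="L-BFGS-B",
            bounds=[_PI_BOUNDS, _PHI_BOUNDS],
        )
        best = min(best, res.fun)
    return -best


def _fit_alt(kA: np.ndarray, nA: np.ndarray, kB: np.ndarray, nB: np.ndarray) -> float:
    pA0 = np.clip(kA.sum() / nA.sum(), *_PI_BOUNDS)
    pB0 = np.clip(kB.sum() / nB.sum(), *_PI_BOUNDS)

    def nll(theta):
        pA, pB, phi = theta
        f = -(_bb_loglik(kA, nA, pA, phi) + _bb_loglik(kB, nB, pB, phi))
        daA, dbA = _bb_grad_ab(kA, nA, pA, phi)
        daB, dbB = _bb_grad_ab(kB, nB, pB, phi)
        dpA, dphiA = _grad_pi_phi(daA, dbA, pA, phi)
        dpB, dphiB = _grad_pi_phi(daB, dbB, pB, phi)
        return f, -np.array([dpA, dpB, dphiA + dphiB])

    phi_mom = 0.5 * (
        _phi_moment(kA, nA) + _phi_moment(kB, nB)
    )
    best = math.inf
    for phi0 in (phi_mom, 0.25, 0.01):
        res = minimize(
            nll,
            x0=[pA0, pB0, phi0],
            jac=True,
            method="L-BFGS-B",
            bounds=[_PI_BOUNDS, _PI_BOUNDS, _PHI_BOUNDS],
        )
        best = min(best, res.fun)
    return -best


def _fit_alt_per_group_phi(kA, nA, kB, nB) -> float:
    return _fit_null_single(kA, nA) + _fit_null_single(kB, nB)


def _fit_null_single(k, n) -> float:
    return _fit_null(k, n)


def beta_binomial_test(
    counts_a,
    totals_a,
    counts_b,
    totals_b,
    per_group_phi: bool = False,
) -> float:
    """Two-sided beta-binomial likelihood-ratio test between two groups.

    Parameters
    ----------
    counts_a, counts_b
        Integer spectral counts per sample in each group.
    totals_a, totals_b
        Matching per-sample library sizes (total spectra).
    per_group_phi
        Fit a separate overdispersion per group in the alternative model
        (2 extra parameters, still referred to chi-square with 1 df for the
        mean difference is not exact; kept for sensitivity analysis).

    Returns
    -------
    float
        Two-sided p-value from the chi-square(1 df) reference distribution.
    """
    kA = np.asarray(counts_a, dtype=float)
    nA = np.asarray(totals_a, dtype=float)
    kB = np.asarray(counts_b, dtype=float)
    nB = np.asarray(totals_b, dtype=float)
    if kA.shape != nA.shape or kB.shape != nB.shape:
        raise ValueError("counts and totals must have matching lengths per group")
    if (kA < 0).any() or (kB < 0).any():
        raise ValueError("counts must be non-negative")
    if (kA > nA).any() or (kB > nB).any():
        raise ValueError("counts cannot exceed totals")

    keepA = nA > 0
    keepB = nB > 0
    if not keepA.all() or not keepB.all():
        logger.warning("excluding %d samples with zero totals", (~keepA).sum() + (~keepB).sum())
        kA, nA = kA[keepA], nA[keepA]
        kB, nB = kB[keepB], nB[keepB]
    if len(kA) < 2 or len(kB) < 2:
        raise ValueError("need at least 2 samples with positive totals per group")

    if kA.sum() == 0 and kB.sum() == 0:
        logger.debug("all counts zero in both groups; degenerate p = 1")
        return 1.0

    ll_null = _fit_null(np.concatenate([kA, kB]), np.concatenate([nA, nB]))
    if per_group_phi:
        ll_alt = _fit_alt_per_group_phi(kA, nA, kB, nB)
    else:
        ll_alt = _fit_alt(kA, nA, kB, nB)
    stat = max(0.0, 2.0 * (ll_alt - ll_null))
    return float(chi2.sf(stat, df=1))


def assign_tier(p_value: float, presence_up: float, fold_change: float) -> str:
    """Map (p, presence in upregulated group, fold-change) to a tier label.

    Boundary conventions: p strictly below 0.05; presence at or above 0.60;
    fold-change strictly above 1.5.
    """
    if not (0.0 <= p_value <= 1.0):
        raise ValueError("p_value outside [0, 1]")
    if not (0.0 <= presence_up <= 1.0):
        raise ValueError("presence_up outside [0, 1]")
    if fold_change < 0:
        raise ValueError("fold_change must be non-negative")
    if p_value >= 0.05:
        return "none"
    if presence_up < 0.60:
        return "T1"
    if fold_change <= 1.5:
        return "T2"
    return "T3"


TIER_ORDER = {"none": 0, "T1": 1, "T2": 2, "T3": 3}


@dataclass
class ComparisonSpec:
    """Sample selection for one differential comparison."""

    comparison: str  # LUAD | LUSC | panNSCLC
    cohort: str  # discovery | validation | untreated


def select_samples(annotation: pd.DataFrame, spec: ComparisonSpec) -> pd.DataFrame:
    """Return the annotation rows participating in a comparison.

    The *untreated* cohort is the UT arm of the validation cohort; the
    *validation* cohort means its ACT arm only.
    """
    ann = annotation
    if spec.cohort == "discovery":
        sel = (ann["cohort"] == "discovery") & (ann["treatment"] == "ACT")
    elif spec.cohort == "validation":
        sel = (ann["cohort"] == "validation") & (ann["treatment"] == "ACT")
    elif spec.cohort == "untreated":
        sel = ann["treatment"] == "UT"
    else:
        raise ValueError(f"unknown cohort {spec.cohort!r}")
    if spec.comparison in ("LUAD", "LUSC"):
        sel &= ann["subtype"] == spec.comparison
    elif spec.comparison != "panNSCLC":
        raise ValueError(f"unknown comparison {spec.comparison!r}")
    return ann.loc[sel]


class UnderpoweredComparison(ValueError):
    """Raised when a comparison has fewer than 2 samples in either group."""


def run_differential(
    norm: CountMatrix,
    annotation: pd.DataFrame,
    comparison: str = "panNSCLC",
    cohort: str = "discovery",
    intensities: CountMatrix | None = None,
    pseudocount: float = 0.5,
    per_group_phi: bool = False,
) -> pd.DataFrame:
    """Run the beta-binomial test on every protein of one comparison.

    Samples with intermediate recurrence-free survival (16 < RFS <= 24
    months) are excluded.  Per-sample totals are the normalized sample sums
    (equal across samples after normalization), and normalized counts are
    rounded to integers to retain the count support of the likelihood.

    Returns a table with one row per protein: p-value, fold-change (ratio of
    the upregulated group mean over the other, with pseudocount), direction
    (``PRG_up``/``GRG_up``), data presence in the upregulated group, tier,
    and a Benjamini-Hochberg FDR column emitted for information only.
    """
    if norm.layer != NORMALIZED_SC:
        raise ValueError("run_differential expects a normalized count matrix")
    ann = assign_response_groups(annotation)
    spec = ComparisonSpec(comparison=comparison, cohort=cohort)
    ann = select_samples(ann, spec)
    ann = ann[ann["response_group"].isin(["PRG", "GRG"])]
    prg = ann.loc[ann["response_group"] == "PRG", "sample_id"].tolist()
    grg = ann.loc[ann["response_group"] == "GRG", "sample_id"].tolist()
    if len(prg) < 2 or len(grg) < 2:
        raise UnderpoweredComparison(
            f"comparison {comparison}/{cohort} underpowered: "
            f"{len(prg)} PRG vs {len(grg)} GRG samples (need >=2 each)"
        )

    sub = norm.subset_samples(prg + grg)
    stats = group_stats(
        sub,
        intensities.subset_samples(prg + grg) if intensities is not None else None,
        group_a=prg,
        group_b=grg,
        pseudocount=pseudocount,
        group_names=("PRG", "GRG"),
    )

    counts = np.rint(sub.data.to_numpy()).astype(np.int64)
    total = int(round(sub.data.sum(axis=0).mean()))
    nA = np.full(len(prg), total)
    nB = np.full(len(grg), total)
    kmat_a = counts[:, : len(prg)]
    kmat_b = counts[:, len(prg) :]

    pvals = np.empty(counts.shape[0])
    for i in range(counts.shape[0]):
        pvals[i] = beta_binomial_test(
            np.minimum(kmat_a[i], total),
            nA,
            np.minimum(kmat_b[i], total),
            nB,
            per_group_phi=per_group_phi,
        )

    direction = np.where(stats["upregulated_group"] == "PRG", "PRG_up", "GRG_up")
    presence_up = np.where(
        stats["upregulated_group"] == "PRG",
        stats["presence_PRG"],
        stats["presence_GRG"],
    )
    tiers = [
        assign_tier(p, pres, fc)
        for p, pres, fc in zip(pvals, presence_up, stats["fold_change"])
    ]
    from statsmodels.stats.multitest import multipletests

    bh = multipletests(pvals, method="fdr_bh")[1]

    out = pd.DataFrame(
        {
            "protein_id": stats["protein_id"],
            "comparison": comparison,
            "cohort": cohort,
            "p_value": pvals,
            "fold_change": stats["fold_change"].to_numpy(),
            "direction": direction,
            "presence_up": presence_up,
            "tier": tiers,
            "bh_fdr": bh,
        }
    )
    if "sc_intensity_r" in stats.columns:
        out["sc_intensity_r"] = stats["sc_intensity_r"].to_numpy()
    out["mean_up"] = np.where(
        stats["upregulated_group"] == "PRG", stats["mean_PRG"], stats["mean_GRG"]
    )
    return out
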