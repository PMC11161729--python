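"""Beta-binomial test behaviour: exactness, symmetry, calibration, tiers."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import betaln, gammaln
from scipy.stats import chi2

from conftest import make_matrix
from ptxrank import assign_tier, beta_binomial_test, run_differential
from ptxrank.containers import CountMatrix, NORMALIZED_SC
from ptxrank.detest import UnderpoweredComparison


def grid_lrt_oracle(kA, nA, kB, nB):
    """Independent grid-search likelihood-ratio oracle over (pi_A, pi_B, phi)."""
    kA, nA, kB, nB = (np.asarray(v, float) for v in (kA, nA, kB, nB))

    def ll(k, n, pi, phi):
        s = 1 / phi - 1
        a, b = pi * s, (1 - pi) * s
        c = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
        return np.sum(c + betaln(k + a, n - k + b) - betaln(a, b))

    pis = np.geomspace(1e-6, 0.5, 120)
    phis = np.geomspace(1e-6, 0.9, 80)
    k, n = np.concatenate([kA, kB]), np.concatenate([nA, nB])
    ll_null = max(ll(k, n, pi, phi) for pi in pis for phi in phis)
    ll_alt = -np.inf
    for phi in phis:
        la = max(ll(kA, nA, pi, phi) for pi in pis)
        lb = max(ll(kB, nB, pi, phi) for pi in pis)
        ll_alt = max(ll_alt, la + lb)
    stat = max(0.0, 2 * (ll_alt - ll_null))
    return float(chi2.sf(stat, 1))


def test_identical_groups_give_p_one():
    k = [10, 12, 11]
    n = [1000, 1000, 1000]
    assert beta_binomial_test(k, n, k, n) == pytest.approx(1.0, abs=1e-6)


def test_clear_separation_significant_and_matches_grid_oracle():
    kA, kB = [10, 12, 11], [0, 1, 0]
    n = [1000, 1000, 1000]
    p = beta_binomial_test(kA, n, kB, n)
    assert p < 0.01
    p_oracle = grid_lrt_oracle(kA, n, kB, n)
    # coarse grid is slightly suboptimal; oracle p is an upper bound and close
    assert p <= p_oracle * 1.05
    assert p == pytest.approx(p_oracle, rel=0.25)


def test_group_order_symmetry():
    rng = np.random.default_rng(0)
    kA = rng.integers(0, 50, 6)
    kB = rng.integers(0, 80, 8)
    nA = np.full(6, 5000)
    nB = np.full(8, 5000)
    p1 = beta_binomial_test(kA, nA, kB, nB)
    p2 = beta_binomial_test(kB, nB, kA, nA)
    assert p1 == pytest.approx(p2, rel=1e-4)


def test_p_increases_as_groups_converge():
    """Scaling group B's counts toward group A's proportion raises p."""
    n = np.full(8, 10_000)
    kA = np.array([50, 55, 48, 52, 49, 51, 53, 50])
    ps = []
    for frac in (0.2, 0.6, 1.0):
        kB = np.rint(kA * (0.2 + 0.8 * frac)).astype(int)
        ps.append(beta_binomial_test(kA, n, kB, n))
    assert ps[0] < ps[1] < ps[2]


def test_all_zero_counts_degenerate():
    z = [0, 0, 0]
    n = [100, 100, 100]
    assert beta_binomial_test(z, n, z, n) == 1.0


def test_zero_total_samples_excluded():
    p = beta_binomial_test([5, 6, 0], [100, 100, 0], [1, 0, 2], [100, 100, 100])
    assert 0 <= p <= 1


def test_counts_exceeding_totals_rejected():
    with pytest.raises(ValueError):
        beta_binomial_test([10], [5], [1, 2], [5, 5])


@pytest.mark.parametrize(
    "p,presence,fc,expected",
    [
        (0.04, 0.70, 1.6, "T3"),
        (0.04, 0.50, 1.6, "T1"),
        (0.06, 0.90, 3.0, "none"),
        (0.04, 0.60, 1.6, "T3"),  # presence boundary inclusive
        (0.04, 0.70, 1.5, "T2"),  # fold-change boundary strict
        (0.05, 0.90, 3.0, "none"),  # p boundary strict
        (0.01, 0.80, 1.2, "T2"),
    ],
)
def test_tier_rule(p, presence, fc, expected):
    assert assign_tier(p, presence, fc) == expected


def _toy_annotation(norm, n_prg, n_grg, subtype="LUAD", cohort="discovery"):
    ids = norm.sample_ids
    rfs = [10.0] * n_prg + [30.0] * n_grg
    return pd.DataFrame(
        {
            "sample_id": ids,
            "cohort": cohort,
            "subtype": subtype,
            "treatment": "ACT",
            "rfs_months": rfs,
            "event": 1,
            "tcp": 50,
        }
    )


def test_run_differential_requires_two_per_group():
    rng = np.random.default_rng(1)
    m = make_matrix(rng.integers(1, 50, size=(5, 6)), layer=NORMALIZED_SC)
    ann = _toy_annotation(m, n_prg=1, n_grg=5)
    with pytest.raises(UnderpoweredComparison):
        run_differential(m, ann, comparison="panNSCLC", cohort="discovery")


def test_run_differential_detects_planted_effect():
    rng = np.random.default_rng(2)
    n_prg, n_grg = 8, 8
    base = rng.integers(50, 200, size=20)
    counts = rng.poisson(np.tile(base[:, None], (1, n_prg + n_grg))).astype(float)
    counts[0, :n_prg] *= 4  # strong planted effect in protein 0
    m = make_matrix(counts, layer=NORMALIZED_SC)
    ann = _toy_annotation(m, n_prg, n_grg)
    out = run_differential(m, ann, comparison="panNSCLC", cohort="discovery")
    row = out.set_index("protein_id").loc["P0"]
    assert row["p_value"] < 0.01
    assert row["direction"] == "PRG_up"
    assert row["fold_change"] > 1.5
    assert row["tier"] == "T3"


def test_run_differential_permuted_labels_calibrated():
    """Under label permutation the fraction of p<0.05 calls stays near 5%."""
    rng = np.random.default_rng(3)
    n = 20
    base = rng.integers(20, 300, size=150)
    counts = rng.poisson(np.tile(base[:, None], (1, n)) * rng.lognormal(0, 0.2, size=(150, n)))
    m = make_matrix(counts.astype(float), layer=NORMALIZED_SC)
    rates = []
    for perm_seed in range(3):
        order = np.random.default_rng(perm_seed).permutation(n)
        ann = _toy_annotation(m, 10, 10)
        ann["rfs_months"] = ann["rfs_months"].to_numpy()[order]
        out = run_differential(m, ann, comparison="panNSCLC", cohort="discovery")
        rates.append((out["p_value"] < 0.05).mean())
    # 99% binomial band around 0.05 for 450 tests is roughly [0.02, 0.08]
    assert 0.0 <= np.mean(rates) <= 0.10


def test_intermediate_samples_excluded(cohorts, norm_discovery):
    out = run_differential(norm_discovery, cohorts.samples, "panNSCLC", "discovery")
    labels = cohorts.truth.response_label
    n_prg = sum(
        1 for s in norm_discovery.sample_ids if labels[s] == "PRG"
    )
    assert len(out) == len(norm_discovery.protein_ids)
    assert set(out["direction"]) <= {"PRG_up", "GRG_up"}
    assert out["p_value"].between(0, 1).all()
    assert n_prg >= 2  # sanity of the fixture
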