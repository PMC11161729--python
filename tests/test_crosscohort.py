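"""Cross-cohort intersection, overlap significance and prognostic flagging."""

from math import comb

import pandas as pd
import pytest

from ptxrank import flag_prognostic, overlap_candidates, overlap_significance


def de_table(rows, cohort):
    return pd.DataFrame(
        [
            {
                "protein_id": pid,
                "comparison": comp,
                "cohort": cohort,
                "p_value": p,
                "fold_change": fc,
                "direction": direction,
                "presence_up": pres,
                "tier": tier,
            }
            for (pid, comp, p, fc, direction, pres, tier) in rows
        ]
    )


DISC = de_table(
    [
        ("A", "panNSCLC", 0.01, 2.0, "PRG_up", 0.9, "T3"),
        ("B", "panNSCLC", 0.02, 1.2, "PRG_up", 0.9, "T2"),
        ("C", "panNSCLC", 0.01, 2.0, "GRG_up", 0.9, "T3"),
        ("D", "panNSCLC", 0.50, 1.0, "PRG_up", 0.5, "none"),
        ("E", "panNSCLC", 0.01, 3.0, "PRG_up", 0.9, "T3"),
    ],
    "discovery",
)
VAL = de_table(
    [
        ("A", "panNSCLC", 0.03, 1.8, "PRG_up", 0.8, "T3"),
        ("B", "panNSCLC", 0.90, 1.0, "PRG_up", 0.4, "none"),
        ("C", "panNSCLC", 0.04, 1.7, "GRG_up", 0.7, "T3"),
        ("D", "panNSCLC", 0.01, 2.0, "PRG_up", 0.9, "T3"),
        ("E", "panNSCLC", 0.02, 2.0, "GRG_up", 0.9, "T3"),  # discordant with DISC
    ],
    "validation",
)


def test_intersection_with_direction_match():
    recs = overlap_candidates(DISC, VAL, "T1")
    ids = {r.protein_id: r for r in recs}
    assert set(ids) == {"A", "C"}
    assert ids["A"].direction == "PRG_up"
    assert ids["C"].direction == "GRG_up"


def test_discordant_direction_excluded():
    recs = overlap_candidates(DISC, VAL, "T1")
    assert "E" not in {r.protein_id for r in recs}


def test_tier_monotonicity():
    t1 = {r.protein_id for r in overlap_candidates(DISC, VAL, "T1")}
    t2 = {r.protein_id for r in overlap_candidates(DISC, VAL, "T2")}
    t3 = {r.protein_id for r in overlap_candidates(DISC, VAL, "T3")}
    assert t3 <= t2 <= t1


def test_empty_universe_errors():
    other = de_table([("Z", "panNSCLC", 0.01, 2.0, "PRG_up", 0.9, "T3")], "validation")
    with pytest.raises(ValueError):
        overlap_candidates(DISC, other, "T1")


def hypergeom_tail_enumeration(n_disc, n_val, n_overlap, universe):
    """Exact tail by combinatorial enumeration (valid for small universes)."""
    total = comb(universe, n_val)
    acc = 0
    for x in range(n_overlap, min(n_disc, n_val) + 1):
        acc += comb(n_disc, x) * comb(universe - n_disc, n_val - x)
    return acc / total


def test_overlap_significance_small_exact_case():
    # drawing 4 from 10 with 5 successes, all 4 hits: C(5,4)*C(5,0)/C(10,4)
    p = overlap_significance(5, 4, 4, 10)
    assert p == pytest.approx(5 / 210)


def test_overlap_zero_has_probability_one():
    assert overlap_significance(6, 5, 0, 20) == pytest.approx(1.0)


def test_overlap_at_expectation_moderate_p():
    # universe 20, 10 successes, draw 8: expectation = 4 hits
    p = overlap_significance(10, 8, 4, 20)
    assert 0.4 <= p <= 0.8
    assert p == pytest.approx(hypergeom_tail_enumeration(10, 8, 4, 20), abs=1e-12)


@pytest.mark.parametrize("n_disc,n_val,k,universe", [
    (5, 4, 2, 12), (7, 7, 3, 15), (9, 5, 5, 20), (3, 3, 0, 8),
])
def test_overlap_significance_matches_enumeration(n_disc, n_val, k, universe):
    assert overlap_significance(n_disc, n_val, k, universe) == pytest.approx(
        hypergeom_tail_enumeration(n_disc, n_val, k, universe), abs=1e-12
    )


def test_overlap_inconsistent_counts_error():
    with pytest.raises(ValueError):
        overlap_significance(5, 4, 5, 10)


def test_prognostic_flagging_rules():
    recs = overlap_candidates(DISC, VAL, "T1")
    ut = de_table(
        [
            ("A", "panNSCLC", 0.03, 1.8, "PRG_up", 0.8, "T1"),  # same direction, T1
            ("C", "panNSCLC", 0.50, 1.1, "GRG_up", 0.6, "none"),  # not significant
        ],
        "untreated",
    )
    flagged = {r.protein_id: r.prognostic_flag for r in flag_prognostic(recs, ut)}
    assert flagged["A"] is True
    assert flagged["C"] is False


def test_prognostic_flag_requires_concordant_direction():
    recs = overlap_candidates(DISC, VAL, "T1")
    ut = de_table(
        [("A", "panNSCLC", 0.01, 2.0, "GRG_up", 0.9, "T3")], "untreated"
    )
    flagged = {r.protein_id: r.prognostic_flag for r in flag_prognostic(recs, ut)}
    assert flagged["A"] is False


def test_prognostic_effects_flagged_predictive_effects_not():
    """Planted survival-associated (treatment-independent) proteins get the
    prognostic flag from the untreated arm; treatment-interaction proteins
    do not (majority over replicate cohorts at n_UT = 10)."""
    import numpy as np

    from ptxrank import generate_cohorts, normalize_counts
    from ptxrank.crosscohort import CandidateRecord
    from ptxrank.detest import UnderpoweredComparison, run_differential
    from ptxrank.simulate import GenerationConfig

    prog_rates, pred_rates = [], []
    for seed in range(10):
        cfg = GenerationConfig(
            n_proteins=60, n_planted_de=8, n_planted_prognostic=4, seed=seed
        )
        co = generate_cohorts(cfg)
        norm = normalize_counts(co.validation)
        try:
            ut = run_differential(norm, co.samples, "panNSCLC", "untreated")
        except UnderpoweredComparison:
            continue  # mirrors the study's exclusion of tiny response arms
        recs = [
            CandidateRecord(p, d, ["panNSCLC"], "T1", "T1")
            for p, d, _ in co.truth.planted_de
        ]
        recs = flag_prognostic(recs, ut)
        prog = set(co.truth.prognostic_proteins)
        fl = {r.protein_id: r.prognostic_flag for r in recs}
        prog_rates.append(np.mean([fl[p] for p in fl if p in prog]))
        pred_rates.append(np.mean([fl[p] for p in fl if p not in prog]))
    assert len(prog_rates) >= 5
    wins = sum(p > q for p, q in zip(prog_rates, pred_rates))
    assert wins > len(prog_rates) / 2
    assert np.mean(prog_rates) >= 0.5
    assert np.mean(pred_rates) <= 0.3


def test_cross_cohort_replication_controls_false_discoveries(cohorts):
    """Replication across cohorts is the pipeline's error control: among
    proteins carrying no planted structure, the fraction entering the
    candidate set is far below their single-cohort T1 call rate, while most
    planted proteins survive the intersection."""
    import numpy as np

    from ptxrank import normalize_counts
    from ptxrank.detest import run_differential

    planted = {p for p, _, _ in cohorts.truth.planted_de}
    signal = planted | set(cohorts.truth.stromal_proteins)
    tables = {}
    for cohort, mat in (("discovery", cohorts.discovery), ("validation", cohorts.validation)):
        norm = normalize_counts(mat)
        tables[cohort] = run_differential(norm, cohorts.samples, "panNSCLC", cohort)
    recs = overlap_candidates(tables["discovery"], tables["validation"], "T1")
    candidates = {r.protein_id for r in recs}

    null_proteins = set(tables["discovery"]["protein_id"]) - signal
    single_false = np.mean(
        tables["discovery"].set_index("protein_id").loc[sorted(null_proteins), "p_value"] < 0.05
    )
    candidate_false = len(candidates & null_proteins) / len(null_proteins)
    assert len(candidates & planted) / len(planted) >= 0.7
    assert candidate_false < single_false / 2
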