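"""Cross-cohort intersection of differential proteins into candidates.

A biomarker candidate is a protein that is significantly differential
(at a chosen tier) with the same direction in *both* the discovery and the
validation ACT cohorts, in the LUAD and/or pan-NSCLC comparison.  Overlap
significance is assessed with an upper-tail hypergeometric test, and the
untreated (surgery-only) arm is used to flag candidates whose differential
expression is prognostic rather than treatment-predictive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import hypergeom

from .detest import TIER_ORDER

logger = logging.getLogger(__name__)


@dataclass
class CandidateRecord:
    protein_id: str
    direction: str  # PRG_up | GRG_up
    comparisons: list[str] = field(default_factory=list)  # subset of {LUAD, panNSCLC}
    tier_discovery: str = "none"
    tier_validation: str = "none"
    prognostic_flag: bool = False


def _meets(row, min_tier: str) -> bool:
    return TIER_ORDER[row["tier"]] >= TIER_ORDER[min_tier]


def overlap_candidates(
    disc: pd.DataFrame, val: pd.DataFrame, min_tier: str = "T1"
) -> list[CandidateRecord]:
    """Intersect discovery and validation DE tables into candidates.

    Both tables may stack several comparisons (LUAD, panNSCLC).  A protein
    qualifies if, in at least one comparison, it meets ``min_tier`` in both
    cohorts with a concordant direction; discordant-direction proteins are
    excluded and logged.  For the recorded tier pair the best (highest)
    qualifying tier per cohort across supporting comparisons is kept.
    """
    if min_tier not in TIER_ORDER or min_tier == "none":
        raise ValueError(f"invalid tier {min_tier!r}")
    universe = set(disc["protein_id"]) & set(val["protein_id"])
    if not universe:
        raise ValueError("discovery and validation tables share no proteins")

    records: dict[str, CandidateRecord] = {}
    discordant: set[str] = set()
    comparisons = sorted(
        set(disc["comparison"]) & set(val["comparison"]),
        key=lambda c: ("LUAD", "panNSCLC", "LUSC").index(c) if c in ("LUAD", "panNSCLC", "LUSC") else 99,
    )
    for comp in comparisons:
        d = disc[(disc["comparison"] == comp)].set_index("protein_id")
        v = val[(val["comparison"] == comp)].set_index("protein_id")
        for pid in d.index.intersection(v.index):
            drow, vrow = d.loc[pid], v.loc[pid]
            if not (_meets(drow, min_tier) and _meets(vrow, min_tier)):
                continue
            if drow["direction"] != vrow["direction"]:
                discordant.add(pid)
                continue
            rec = records.get(pid)
            if rec is None:
                rec = CandidateRecord(
                    protein_id=pid,
                    direction=drow["direction"],
                    tier_discovery=drow["tier"],
                    tier_validation=vrow["tier"],
                )
                records[pid] = rec
            rec.comparisons.append(comp)
            if TIER_ORDER[drow["tier"]] > TIER_ORDER[rec.tier_discovery]:
                rec.tier_discovery = drow["tier"]
            if TIER_ORDER[vrow["tier"]] > TIER_ORDER[rec.tier_validation]:
                rec.tier_validation = vrow["tier"]
    if discordant:
        logger.info("excluded %d discordant-direction proteins: %s", len(discordant), sorted(discordant))
    return sorted(records.values(), key=lambda r: r.protein_id)


def overlap_significance(n_disc: int, n_val: int, n_overlap: int, universe: int) -> float:
    """Upper-tail hypergeometric probability of the observed overlap.

    P(X >= n_overlap) when ``n_val`` proteins are drawn without replacement
    from a universe containing ``n_disc`` successes.
    """
    if min(n_disc, n_val, n_overlap, universe) < 0:
        raise ValueError("counts must be non-negative")
    if n_overlap > min(n_disc, n_val) or max(n_disc, n_val) > universe:
        raise ValueError("inconsistent overlap counts")
    return float(hypergeom.sf(n_overlap - 1, universe, n_disc, n_val))


def flag_prognostic(
    candidates: list[CandidateRecord], ut_results: pd.DataFrame
) -> list[CandidateRecord]:
    """Flag candidates that replicate (T1, same direction) in the untreated arm.

    Differential expression between response groups in patients who received
    no adjuvant treatment indicates a prognostic rather than a
    treatment-predictive marker.
    """
    ut = ut_results.set_index("protein_id")
    for rec in candidates:
        rec.prognostic_flag = False
        if rec.protein_id in ut.index:
            row = ut.loc[rec.protein_id]
            if isinstance(row, pd.DataFrame):  # several comparisons stacked
                row = row.iloc[0]
            if TIER_ORDER[row["tier"]] >= 1 and row["direction"] == rec.direction:
                rec.prognostic_flag = True
    return candidates


def candidates_to_frame(candidates: list[CandidateRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "protein_id": [r.protein_id for r in candidates],
            "direction": [r.direction for r in candidates],
            "comparisons": ["+".join(r.comparisons) for r in candidates],
            "tier_discovery": [r.tier_discovery for r in candidates],
            "tier_validation": [r.tier_validation for r in candidates],
            "prognostic_flag": [r.prognostic_flag for r in candidates],
        }
    )
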