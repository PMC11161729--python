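"""Robustness rubric, signature score and composite candidate ranking.

Each cross-cohort candidate receives a cumulative robustness score (0-11)
built from four technical components, each assessed in both cohorts:

(a) spectral-count:intensity correlation, binned on the weaker cohort:
    < 0.75 -> 0; [0.75, 0.85) -> 1; [0.85, 0.95) -> 2; >= 0.95 -> 3.
(b) average abundance in the upregulated group:
    >= 30 counts in both cohorts -> 3; >= 15 in both -> 2;
    <= 5 in both -> 0; otherwise -> 1.
(c) significance tier pair: T3:T3 -> 3; T2:T3 or T3:T2 -> 2; T2:T2 -> 1;
    any weaker pairing -> 0.
(d) unique peptides per kDa of molecular weight:
    > 0.2 in both cohorts -> 2; >= 0.1 in both -> 1; < 0.1 in either -> 0.

Bins that touch are resolved half-open from below with the top bin closed;
overlapping abundance phrases are resolved by first match from the highest
score downward.  A missing correlation scores 0 on (a) and is logged.

The signature score (0-4) adds the candidate's standing in the signature
search: best position across the top-30 lists of 4- and 5-protein
combinations (top 10 -> 3, top 20 -> 2, top 30 -> 1, absent -> 0) plus one
point for membership in any stepwise signature.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detest import TIER_ORDER
from .sigsearch import SearchReport, SignatureModel

logger = logging.getLogger(__name__)

ROBUSTNESS_THRESHOLD = 7


@dataclass
class RobustnessRecord:
    protein_id: str
    comp_a: int
    comp_b: int
    comp_c: int
    comp_d: int
    signature_score: int = 0

    @property
    def robustness_total(self) -> int:
        return self.comp_a + self.comp_b + self.comp_c + self.comp_d

    @property
    def composite(self) -> int:
        return self.robustness_total + self.signature_score


def _bin_correlation(corr_d: float | None, corr_v: float | None) -> int:
    vals = []
    for v in (corr_d, corr_v):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            logger.info("missing SC:intensity correlation; component (a) scored 0")
            return 0
        if not -1.0 <= v <= 1.0:
            raise ValueError(f"correlation {v} outside [-1, 1]")
        vals.append(v)
    m = min(vals)
    if m >= 0.95:
        return 3
    if m >= 0.85:
        return 2
    if m >= 0.75:
        return 1
    return 0


def _bin_abundance(abund_d: float, abund_v: float) -> int:
    if abund_d < 0 or abund_v < 0:
        raise ValueError("abundances must be non-negative")
    if abund_d >= 30 and abund_v >= 30:
        return 3
    if abund_d >= 15 and abund_v >= 15:
        return 2
    if abund_d <= 5 and abund_v <= 5:
        return 0
    return 1


def _bin_tiers(tier_d: str, tier_v: str) -> int:
    for t in (tier_d, tier_v):
        if t not in TIER_ORDER:
            raise ValueError(f"invalid tier {t!r}")
    a, b = TIER_ORDER[tier_d], TIER_ORDER[tier_v]
    if a == 3 and b == 3:
        return 3
    if {a, b} == {2, 3}:
        return 2
    if a == 2 and b == 2:
        return 1
    return 0


def _bin_peptide_ratio(ratio_d: float, ratio_v: float) -> int:
    if ratio_d < 0 or ratio_v < 0:
        raise ValueError("peptide ratios must be non-negative")
    if ratio_d > 0.2 and ratio_v > 0.2:
        return 2
    if ratio_d >= 0.1 and ratio_v >= 0.1:
        return 1
    return 0


def robustness_components(
    protein_id: str,
    corr_d: float | None,
    corr_v: float | None,
    abund_d: float,
    abund_v: float,
    tier_d: str,
    tier_v: str,
    pepratio_d: float,
    pepratio_v: float,
) -> RobustnessRecord:
    """Score the four robustness components for one candidate.

    Suffixes ``_d``/``_v`` are the discovery and validation cohort values:
    SC:intensity Pearson correlation, mean normalized abundance in the
    upregulated group, significance tier, and unique peptides per kDa.
    """
    return RobustnessRecord(
        protein_id=protein_id,
        comp_a=_bin_correlation(corr_d, corr_v),
        comp_b=_bin_abundance(abund_d, abund_v),
        comp_c=_bin_tiers(tier_d, tier_v),
        comp_d=_bin_peptide_ratio(pepratio_d, pepratio_v),
    )


def signature_score(
    protein: str,
    reports: list[SearchReport],
    stepwise: list[SignatureModel] | None = None,
) -> int:
    """Positional score from the top-30 combination lists plus stepwise bonus.

    The best (smallest) rank of a combination containing the protein across
    all reports maps to {1-10: 3, 11-20: 2, 21-30: 1, absent: 0}; membership
    in any stepwise signature adds 1.
    """
    best: int | None = None
    all_stepwise = list(stepwise or [])
    for rep in reports:
        r = rep.protein_rank(protein)
        if r is not None and (best is None or r < best):
            best = r
        all_stepwise.extend(rep.stepwise)
    if best is None:
        positional = 0
    elif best <= 10:
        positional = 3
    elif best <= 20:
        positional = 2
    else:
        positional = 1
    member = any(protein in m.proteins for m in all_stepwise)
    return positional + int(member)


def composite_rank(
    records: list[RobustnessRecord],
    p_products: dict[str, float] | None = None,
    threshold: int = ROBUSTNESS_THRESHOLD,
) -> pd.DataFrame:
    """Rank scored candidates by composite score.

    Sorted by composite descending, ties broken by robustness total, then by
    the product of the two cohorts' p-values ascending, then protein id.
    Returns the full ordered table with a ``passes_threshold`` flag for
    robustness_total >= ``threshold``.
    """
    pp = p_products or {}
    ordered = sorted(
        records,
        key=lambda r: (
            -r.composite,
            -r.robustness_total,
            pp.get(r.protein_id, 1.0),
            r.protein_id,
        ),
    )
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(ordered) + 1),
            "protein_id": [r.protein_id for r in ordered],
            "comp_a": [r.comp_a for r in ordered],
            "comp_b": [r.comp_b for r in ordered],
            "comp_c": [r.comp_c for r in ordered],
            "comp_d": [r.comp_d for r in ordered],
            "robustness_total": [r.robustness_total for r in ordered],
            "signature_score": [r.signature_score for r in ordered],
            "composite": [r.composite for r in ordered],
            "passes_threshold": [r.robustness_total >= threshold for r in ordered],
        }
    )
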