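"""Spectral-count normalization, protein filtering and group summaries.

Raw spectral counts are normalized on the sum of counts of all identified
proteins in a sample, relative to the average sample sum: every sample is
scaled so its total equals the cohort-average total.  This removes run-depth
differences while keeping values on the count scale.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import INTENSITY, NORMALIZED_SC, RAW_SC, CountMatrix

logger = logging.getLogger(__name__)


def normalize_counts(raw: CountMatrix) -> CountMatrix:
    """Scale every sample by (average sample total / its own total).

    After normalization all sample totals equal the original average total.
    Idempotent: renormalizing a normalized matrix is a no-op.
    """
    if raw.layer == INTENSITY:
        raise ValueError("normalize_counts operates on spectral counts, not intensities")
    totals = raw.data.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero) > 0:
        raise ValueError(f"samples with zero total counts: {list(zero.index)}")
    factors = totals.mean() / totals
    data = raw.data * factors
    return CountMatrix(data=data, layer=NORMALIZED_SC)


def _presence_by_group(
    matrix: CountMatrix, groups: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    out = {}
    for name, samples in groups.items():
        sub = matrix.data.loc[:, list(samples)]
        out[name] = (sub > 0).mean(axis=1)
    return pd.DataFrame(out)


def filter_proteins(
    matrix: CountMatrix,
    min_presence: float,
    groups: Mapping[str, Sequence[str]] | None = None,
) -> tuple[CountMatrix, list[str]]:
    """Keep proteins whose data presence reaches ``min_presence`` in at
    least one sample group.

    Parameters
    ----------
    matrix
        Any layer; presence is the fraction of samples with value > 0.
    min_presence
        Threshold in [0, 1].
    groups
        Mapping of group name to sample ids (e.g. subtype × cohort strata).
        When omitted, all samples form a single group.

    Returns
    -------
    (filtered matrix, list of removed protein ids)
    """
    if not 0.0 <= min_presence <= 1.0:
        raise ValueError("min_presence must be in [0, 1]")
    if groups is None:
        groups = {"all": matrix.sample_ids}
    presence = _presence_by_group(matrix, groups)
    keep = (presence >= min_presence).any(axis=1)
    removed = list(presence.index[~keep])
    if removed:
        logger.info("filter_proteins removed %d proteins", len(removed))
    return replace(matrix, data=matrix.data.loc[keep]), removed


def annotation_groups(annotation: pd.DataFrame) -> dict[str, list[str]]:
    """Subtype × cohort strata used as the default filtering groups."""
    groups: dict[str, list[str]] = {}
    for (cohort, subtype), sub in annotation.groupby(["cohort", "subtype"]):
        groups[f"{cohort}:{subtype}"] = sub["sample_id"].tolist()
    return groups


def group_stats(
    norm: CountMatrix,
    intensities: CountMatrix | None,
    group_a: Sequence[str],
    group_b: Sequence[str],
    pseudocount: float = 0.5,
    group_names: tuple[str, str] = ("A", "B"),
) -> pd.DataFrame:
    """Per-protein two-group summary statistics.

    For each protein: group means of normalized counts, data presence per
    group, the upregulated group (larger mean; ties go to the first group
    and are logged), a fold-change ``(mean_up + pc) / (mean_other + pc)``
    reported as a ratio >= 1 with the direction carried by
    ``upregulated_group``, and — when an intensity layer is supplied — the
    Pearson correlation of counts vs intensities across all samples of the
    matrix (NaN when either vector is constant).
    """
    ga, gb = list(group_a), list(group_b)
    if not ga or not gb:
        raise ValueError("groups must be non-empty")
    if set(ga) & set(gb):
        raise ValueError("groups must be disjoint")
    unknown = [s for s in ga + gb if s not in norm.data.columns]
    if unknown:
        raise KeyError(f"unknown sample ids: {unknown}")

    sub_a = norm.data.loc[:, ga]
    sub_b = norm.data.loc[:, gb]
    mean_a = sub_a.mean(axis=1)
    mean_b = sub_b.mean(axis=1)
    presence_a = (sub_a > 0).mean(axis=1)
    presence_b = (sub_b > 0).mean(axis=1)

    a_up = mean_a.to_numpy() >= mean_b.to_numpy()
    n_ties = int((mean_a.to_numpy() == mean_b.to_numpy()).sum())
    if n_ties:
        logger.debug("%d proteins with tied group means; assigned to %s", n_ties, group_names[0])
    mean_up = np.where(a_up, mean_a, mean_b)
    mean_other = np.where(a_up, mean_b, mean_a)
    fold_change = (mean_up + pseudocount) / (mean_other + pseudocount)

    na, nb = group_names
    out = pd.DataFrame(
        {
            "protein_id": norm.data.index,
            f"mean_{na}": mean_a.to_numpy(),
            f"mean_{nb}": mean_b.to_numpy(),
            f"presence_{na}": presence_a.to_numpy(),
            f"presence_{nb}": presence_b.to_numpy(),
            "upregulated_group": np.where(a_up, na, nb),
            "fold_change": fold_change,
        }
    )
    if intensities is not None:
        out["sc_intensity_r"] = sc_intensity_correlation(norm, intensities)
    return out


def sc_intensity_correlation(
    counts: CountMatrix, intensities: CountMatrix
) -> np.ndarray:
    """Per-protein Pearson correlation between counts and intensities.

    Computed across all shared samples; NaN where either vector is constant.
    """
    shared = [s for s in counts.sample_ids if s in intensities.data.columns]
    if not shared:
        raise ValueError("no shared samples between counts and intensities")
    x = counts.data.loc[:, shared].to_numpy(dtype=float)
    y = intensities.data.loc[counts.data.index, shared].to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc * yc).sum(axis=1) / (sx * sy)
    r[(sx == 0) | (sy == 0)] = np.nan
    return np.clip(r, -1.0, 1.0)
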