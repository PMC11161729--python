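"""End-to-end orchestration: simulate/load -> preprocess -> DE -> candidates
-> signature search -> scoring -> survival -> clustering.

Every stage consumes only earlier-stage outputs; all randomness derives from
the single global seed via named substreams, so a configuration reproduces
its outputs exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering as clus
from . import crosscohort as cc
from . import detest, preprocess, scoring, sigsearch
from . import survival as surv
from .containers import CountMatrix, INTENSITY, RAW_SC
from .simulate import GenerationConfig, SyntheticCohorts, generate_cohorts

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Parameters of a full pipeline run.

    Either ``generation`` (simulate a cohort pair) or the four input paths
    must be provided.
    """

    generation: GenerationConfig | None = None
    counts_discovery: str | None = None
    counts_validation: str | None = None
    intensities_discovery: str | None = None
    intensities_validation: str | None = None
    samples: str | None = None
    proteins: str | None = None

    min_presence: float = 0.5
    pseudocount: float = 0.5
    tier: str = "T1"
    corr_gate: float = 0.75
    top_f: int = 100
    epsilon: float = 0.005
    robustness_threshold: int = 7
    quantile: float = 0.75
    n_draws: int = 2000
    exhaustive_max_combos: int = 5000
    run_signature_search: bool = True
    run_clustering: bool = True
    comparisons: tuple[tuple[str, str], ...] | None = None  # None = full plan
    seed: int = 0
    out_dir: str | None = None

    def validate(self) -> None:
        if self.generation is None and self.counts_discovery is None:
            raise ValueError("either a generation config or input paths are required")
        if not 0 <= self.min_presence <= 1:
            raise ValueError("min_presence must be in [0, 1]")
        if self.tier not in ("T1", "T2", "T3"):
            raise ValueError("tier must be T1, T2 or T3")


@dataclass
class PipelineResult:
    config: PipelineConfig
    cohorts: SyntheticCohorts | None
    norm_discovery: CountMatrix
    norm_validation: CountMatrix
    de_tables: dict[tuple[str, str], pd.DataFrame]
    skipped_comparisons: list[tuple[str, str, str]]
    candidates: list[cc.CandidateRecord]
    overlap_p: float | None
    pool: list[str]
    reports: list[sigsearch.SearchReport] = field(default_factory=list)
    stepwise: list[sigsearch.SignatureModel] = field(default_factory=list)
    ranked: pd.DataFrame | None = None
    clusterings: dict[str, tuple[clus.ClusteringResult, clus.OutcomeAssociation]] = field(
        default_factory=dict
    )
    survival_split: dict | None = None
    manifest: dict = field(default_factory=dict)


def _load_inputs(config: PipelineConfig):
    if config.generation is not None:
        cohorts = generate_cohorts(config.generation)
        return cohorts, cohorts.discovery, cohorts.validation, cohorts.discovery_intensity, cohorts.validation_intensity, cohorts.samples, cohorts.proteins
    from .containers import read_proteins, read_samples

    disc = CountMatrix.from_tsv(config.counts_discovery, layer=RAW_SC)
    val = CountMatrix.from_tsv(config.counts_validation, layer=RAW_SC)
    disc_i = CountMatrix.from_tsv(config.intensities_discovery, layer=INTENSITY)
    val_i = CountMatrix.from_tsv(config.intensities_validation, layer=INTENSITY)
    samples = read_samples(config.samples)
    proteins = read_proteins(config.proteins)
    return None, disc, val, disc_i, val_i, samples, proteins


COMPARISON_PLAN = [
    ("LUAD", "discovery"),
    ("LUSC", "discovery"),
    ("panNSCLC", "discovery"),
    ("LUAD", "validation"),
    ("LUSC", "validation"),
    ("panNSCLC", "validation"),
    ("panNSCLC", "untreated"),
]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full discovery pipeline for one configuration."""
    config.validate()
    cohorts, disc_raw, val_raw, disc_int, val_int, samples, proteins = _load_inputs(config)

    # --- preprocess: normalize and filter per cohort -----------------------
    ann = surv.assign_response_groups(samples)
    norm_d = preprocess.normalize_counts(disc_raw)
    norm_v = preprocess.normalize_counts(val_raw)
    groups_d = preprocess.annotation_groups(ann[ann["cohort"] == "discovery"])
    groups_v = preprocess.annotation_groups(ann[ann["cohort"] == "validation"])
    norm_d, removed_d = preprocess.filter_proteins(norm_d, config.min_presence, groups_d)
    norm_v, removed_v = preprocess.filter_proteins(norm_v, config.min_presence, groups_v)

    # --- differential testing ---------------------------------------------
    de_tables: dict[tuple[str, str], pd.DataFrame] = {}
    skipped: list[tuple[str, str, str]] = []
    plan = list(config.comparisons) if config.comparisons is not None else COMPARISON_PLAN
    for comparison, cohort in plan:
        norm = norm_d if cohort == "discovery" else norm_v
        intens = disc_int if cohort == "discovery" else val_int
        try:
            de_tables[(comparison, cohort)] = detest.run_differential(
                norm,
                ann,
                comparison=comparison,
                cohort=cohort,
                intensities=intens.subset_proteins(norm.protein_ids),
                pseudocount=config.pseudocount,
            )
        except detest.UnderpoweredComparison as exc:
            logger.warning("skipping %s/%s: %s", comparison, cohort, exc)
            skipped.append((comparison, cohort, str(exc)))

    # --- cross-cohort candidates -------------------------------------------
    disc_parts = [de_tables[k] for k in de_tables if k[1] == "discovery" and k[0] != "LUSC"]
    val_parts = [de_tables[k] for k in de_tables if k[1] == "validation" and k[0] != "LUSC"]
    if disc_parts and val_parts:
        disc_de = pd.concat(disc_parts, ignore_index=True)
        val_de = pd.concat(val_parts, ignore_index=True)
        candidates = cc.overlap_candidates(disc_de, val_de, min_tier=config.tier)
    else:
        logger.warning("no testable discovery/validation comparison pair; no candidates")
        candidates = []

    overlap_p = None
    key_d, key_v = ("panNSCLC", "discovery"), ("panNSCLC", "validation")
    if key_d in de_tables and key_v in de_tables:
        d, v = de_tables[key_d], de_tables[key_v]
        shared = set(d["protein_id"]) & set(v["protein_id"])
        sig_d = set(d.loc[d["p_value"] < 0.05, "protein_id"]) & shared
        sig_v = set(v.loc[v["p_value"] < 0.05, "protein_id"]) & shared
        overlap_p = cc.overlap_significance(
            len(sig_d), len(sig_v), len(sig_d & sig_v), len(shared)
        )

    ut_key = ("panNSCLC", "untreated")
    if ut_key in de_tables:
        candidates = cc.flag_prognostic(candidates, de_tables[ut_key])

    # --- signature search on the correlation-gated pan-NSCLC pool ----------
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))
    pan_candidates = [r for r in candidates if "panNSCLC" in r.comparisons]
    combined_r = _combined_correlation(norm_d, norm_v, disc_int, val_int)
    pool = sorted(
        r.protein_id
        for r in pan_candidates
        if combined_r.get(r.protein_id, np.nan) > config.corr_gate
    )

    reports: list[sigsearch.SearchReport] = []
    stepwise: list[sigsearch.SignatureModel] = []
    act = ann[(ann["treatment"] == "ACT") & ann["response_group"].isin(["PRG", "GRG"])]
    data, labels = _combined_features(norm_d, norm_v, act)
    if config.run_signature_search and len(pool) >= 4 and len(set(labels)) == 2:
        n4 = math.comb(len(pool), 4)
        if n4 <= config.exhaustive_max_combos:
            rep4 = sigsearch.exhaustive_search(pool, 4, data, labels, top_f=config.top_f)
        else:
            logger.info(
                "pool of %d gives %d 4-mers; probing %d random draws instead",
                len(pool), n4, config.exhaustive_max_combos,
            )
            rep4 = sigsearch.random_probe(
                pool, 4, data, labels,
                n_draws=config.exhaustive_max_combos,
                seed=int(rng.integers(2**31)),
                top_f=config.top_f,
            )
        reports.append(rep4)
        if len(pool) >= 5:
            reports.append(
                sigsearch.random_probe(
                    pool, 5, data, labels,
                    n_draws=config.n_draws,
                    seed=int(rng.integers(2**31)),
                    top_f=config.top_f,
                )
            )
        stepwise.append(
            sigsearch.stepwise_signature(pool, data, labels, start="highest_auc", epsilon=config.epsilon)
        )

    # --- robustness + signature scoring ------------------------------------
    ranked, records = _score_candidates(
        config, pan_candidates, de_tables, norm_d, norm_v, disc_int, val_int, proteins,
        reports, stepwise,
    )

    # stepwise from the most robust marker, then rescore signature bonus
    if config.run_signature_search and len(pool) >= 4 and ranked is not None and len(ranked):
        in_pool = ranked[ranked["protein_id"].isin(pool)]
        if len(in_pool):
            most_robust = in_pool.iloc[0]["protein_id"]
            stepwise.append(
                sigsearch.stepwise_signature(pool, data, labels, start=most_robust, epsilon=config.epsilon)
            )
            ranked, records = _score_candidates(
                config, pan_candidates, de_tables, norm_d, norm_v, disc_int, val_int,
                proteins, reports, stepwise,
            )

    # --- survival: top-quartile split of the top-ranked candidate ----------
    survival_split = None
    if ranked is not None and len(ranked):
        top_protein = ranked.iloc[0]["protein_id"]
        val_act = ann[(ann["cohort"] == "validation") & (ann["treatment"] == "ACT")]
        try:
            sub = norm_v.subset_samples(val_act["sample_id"].tolist())
            high, low = surv.abundance_split(sub, top_protein, config.quantile)
            idx = val_act.set_index("sample_id")
            lr = surv.logrank_test(
                (idx.loc[high, "rfs_months"].to_numpy(), idx.loc[high, "event"].astype(bool).to_numpy()),
                (idx.loc[low, "rfs_months"].to_numpy(), idx.loc[low, "event"].astype(bool).to_numpy()),
                labels=("high", "low"),
            )
            survival_split = {
                "protein": top_protein,
                "n_high": len(high),
                "n_low": len(low),
                "logrank_p": lr.p_value,
                "chi2": lr.chi2,
            }
        except (ValueError, KeyError) as exc:
            logger.warning("abundance split skipped: %s", exc)

    # --- clustering ---------------------------------------------------------
    clusterings = {}
    if config.run_clustering:
        for cohort, norm in (("discovery", norm_d), ("validation", norm_v)):
            res = clus.cluster_samples(norm, k=3)
            assoc = clus.cluster_outcome_association(res, ann)
            clusterings[cohort] = (res, assoc)

    manifest = _manifest(config, de_tables, skipped, candidates, pool, ranked)
    result = PipelineResult(
        config=config,
        cohorts=cohorts,
        norm_discovery=norm_d,
        norm_validation=norm_v,
        de_tables=de_tables,
        skipped_comparisons=skipped,
        candidates=candidates,
        overlap_p=overlap_p,
        pool=pool,
        reports=reports,
        stepwise=stepwise,
        ranked=ranked,
        clusterings=clusterings,
        survival_split=survival_split,
        manifest=manifest,
    )
    if config.out_dir:
        _write_outputs(result, Path(config.out_dir))
    return result


def _combined_correlation(norm_d, norm_v, disc_int, val_int) -> dict[str, float]:
    shared = [p for p in norm_d.protein_ids if p in set(norm_v.protein_ids)]
    counts = pd.concat([norm_d.data.loc[shared], norm_v.data.loc[shared]], axis=1)
    intens = pd.concat(
        [disc_int.data.loc[shared], val_int.data.loc[shared]], axis=1
    ).loc[:, counts.columns]
    r = preprocess.sc_intensity_correlation(
        CountMatrix(counts, layer="normalized_sc"), CountMatrix(intens, layer="intensity")
    )
    return dict(zip(shared, r))


def _combined_features(norm_d, norm_v, act_ann):
    shared = [p for p in norm_d.protein_ids if p in set(norm_v.protein_ids)]
    data = pd.concat([norm_d.data.loc[shared], norm_v.data.loc[shared]], axis=1)
    keep = [s for s in act_ann["sample_id"] if s in data.columns]
    data = data.loc[:, keep]
    lab = act_ann.set_index("sample_id").loc[keep, "response_group"].to_numpy()
    return data, (lab == "PRG").astype(int)


def _score_candidates(
    config, pan_candidates, de_tables, norm_d, norm_v, disc_int, val_int, proteins,
    reports, stepwise,
):
    if not pan_candidates:
        return None, []
    corr_d = dict(
        zip(
            norm_d.protein_ids,
            preprocess.sc_intensity_correlation(norm_d, disc_int.subset_proteins(norm_d.protein_ids)),
        )
    )
    corr_v = dict(
        zip(
            norm_v.protein_ids,
            preprocess.sc_intensity_correlation(norm_v, val_int.subset_proteins(norm_v.protein_ids)),
        )
    )
    meta = proteins.set_index("protein_id")
    records = []
    p_products = {}
    for rec in pan_candidates:
        row_d = _de_row(de_tables, "discovery", rec.protein_id)
        row_v = _de_row(de_tables, "validation", rec.protein_id)
        if row_d is None or row_v is None:
            continue
        mw = float(meta.loc[rec.protein_id, "mw_kda"])
        r = scoring.robustness_components(
            rec.protein_id,
            corr_d.get(rec.protein_id),
            corr_v.get(rec.protein_id),
            float(row_d["mean_up"]),
            float(row_v["mean_up"]),
            rec.tier_discovery,
            rec.tier_validation,
            float(meta.loc[rec.protein_id, "peptides_discovery"]) / mw,
            float(meta.loc[rec.protein_id, "peptides_validation"]) / mw,
        )
        r.signature_score = scoring.signature_score(rec.protein_id, reports, stepwise)
        records.append(r)
        p_products[rec.protein_id] = float(row_d["p_value"]) * float(row_v["p_value"])
    ranked = scoring.composite_rank(records, p_products, threshold=config.robustness_threshold)
    return ranked, records


def _de_row(de_tables, cohort, protein):
    for comparison in ("panNSCLC", "LUAD"):
        tab = de_tables.get((comparison, cohort))
        if tab is not None:
            hit = tab[tab["protein_id"] == protein]
            if len(hit):
                return hit.iloc[0]
    return None


def _manifest(config, de_tables, skipped, candidates, pool, ranked) -> dict:
    cfg = dataclasses.asdict(config)
    cfg_json = json.dumps(cfg, sort_keys=True, default=str)
    return {
        "parameters": cfg,
        "parameter_hash": hashlib.sha256(cfg_json.encode()).hexdigest()[:16],
        "seed": config.seed,
        "comparisons_run": [f"{c}/{h}" for c, h in de_tables],
        "comparisons_skipped": [f"{c}/{h}: {msg}" for c, h, msg in skipped],
        "n_candidates": len(candidates),
        "n_pool": len(pool),
        "n_ranked": 0 if ranked is None else int(len(ranked)),
    }


def _write_outputs(result: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    if result.cohorts is not None:
        from .simulate import write_cohorts

        write_cohorts(result.cohorts, out / "synthetic")
    for (comparison, cohort), tab in result.de_tables.items():
        tab.to_csv(out / f"de_{cohort}_{comparison}.tsv", sep="\t", index=False)
    cc.candidates_to_frame(result.candidates).to_csv(out / "candidates.tsv", sep="\t", index=False)
    if result.ranked is not None:
        result.ranked.to_csv(out / "ranked_candidates.tsv", sep="\t", index=False)
    for cohort, (res, assoc) in result.clusterings.items():
        res.to_frame().to_csv(out / f"clusters_{cohort}.tsv", sep="\t", index=False)
        (out / f"dendrogram_{cohort}.nwk").write_text(clus.dendrogram_newick(res))
    report = {
        "overlap_p": result.overlap_p,
        "survival_split": result.survival_split,
        "stepwise": [
            {"proteins": list(m.proteins), "loocv_auc": m.loocv_auc, "trace": m.trace}
            for m in result.stepwise
        ],
        "cluster_association": {
            cohort: {
                "prs_cluster": assoc.prs_cluster,
                "fisher_p": assoc.fisher_p,
                "logrank_p": assoc.logrank.p_value,
            }
            for cohort, (res, assoc) in result.clusterings.items()
        },
    }
    (out / "report.json").write_text(json.dumps(report, indent=1, default=float))
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=1, default=str))
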