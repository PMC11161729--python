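"""Synthetic paired discovery/validation NSCLC proteomics cohorts.

Generates spectral-count and MS1-intensity matrices with a known ground
truth so the whole discovery pipeline can be exercised and its recovery
quantified.  The generator emulates the statistical structure of archival
FFPE tumour cohorts profiled by single-shot spectral counting:

* overdispersed counts — per protein and sample, counts are beta-binomial
  given the sample's library size, with the biological coefficient of
  variation of the underlying proportion set by ``dispersion``;
* zero inflation — a protein/sample cell drops out entirely with probability
  ``zero_inflation * exp(-expected_count / 20)``, so missingness concentrates
  in low-abundance proteins as it does in real spectral counting;
* planted differential proteins — ``n_planted_de`` proteins whose true mean
  proportion differs by ``planted_fc`` between poor- (PRG) and good- (GRG)
  response samples, with the same direction and effect in both cohorts;
* a poor response/survival (PR/S) sub-cluster — a fixed block of "stromal"
  proteins is up-shifted 3x in member samples, which additionally suffer
  extra dropout among the remaining proteins (fewer protein identifications);
* histology structure — LUAD- and LUSC-marker blocks so unsupervised
  clustering sees subtype-dominated structure with a mixed PR/S cluster;
* count-to-intensity coupling — intensities are counts times a per-protein
  response factor with lognormal noise of width ``sc_intensity_noise``;
* survival — recurrence-free survival drawn per response label with
  group-specific exponential hazards, administratively censored at 36
  months, plus random censoring at ``censor_rate``.

Planted treatment-predictive effects apply only to ACT samples; the first
``n_planted_prognostic`` planted proteins are instead prognostic (effect in
all samples by response label, including the untreated arm), so the
prognostic-flagging path can be exercised.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import INTENSITY, RAW_SC, CountMatrix

# Structural constants of the emulated cohorts (documented in the methods
# note; not part of the per-study configuration surface).
STROMAL_FRACTION = 0.10
STROMAL_MULTIPLIER = 3.0
SUBTYPE_FRACTION = 0.08
SUBTYPE_MULTIPLIER = 2.0
PRS_EXTRA_DROPOUT = 0.15
DROPOUT_SCALE = 20.0  # expected counts at which dropout odds fall by 1/e
PRS_DROPOUT_SCALE = 40.0  # members lose identifications somewhat further up the abundance range
PRS_PRG_WEIGHT = 9.0  # sampling weight of PRG samples when drawing PR/S members
INTERMEDIATE_FRACTION = 0.15
PRG_FRACTION = 0.45  # among samples with a decided (non-intermediate) label
LIBRARY_SIZE_MEAN = 100_000.0
LIBRARY_SIZE_SIGMA = 0.25
ADMIN_CENSOR_MONTHS = 36.0


@dataclass(frozen=True)
class GenerationConfig:
    """Knobs of the synthetic cohort generator.

    Cohort sizes default to the emulated study design: 45 discovery ACT
    samples, 22 validation ACT samples and 10 untreated validation samples;
    the PR/S sub-cluster holds ~26% of each cohort.
    """

    n_proteins: int = 500
    n_samples_discovery: int = 45
    n_samples_validation_act: int = 22
    n_samples_validation_ut: int = 10
    luad_fraction: float = 0.6
    prs_cluster_fraction: float = 0.26
    n_planted_de: int = 50
    planted_fc: float = 2.5
    dispersion: float = 0.3
    zero_inflation: float = 0.10
    sc_intensity_noise: float = 0.3
    rfs_hazard_prg: float = 0.12
    rfs_hazard_grg: float = 0.04
    censor_rate: float = 0.2
    n_planted_prognostic: int = 0
    seed: int = 0

    def validate(self) -> None:
        for name in ("luad_fraction", "prs_cluster_fraction", "zero_inflation", "censor_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "n_proteins",
            "n_samples_discovery",
            "n_samples_validation_act",
            "n_samples_validation_ut",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_planted_de < 0 or self.n_planted_de > self.n_proteins:
            raise ValueError("n_planted_de must be in [0, n_proteins]")
        if self.n_planted_prognostic < 0 or self.n_planted_prognostic > self.n_planted_de:
            raise ValueError("n_planted_prognostic must be in [0, n_planted_de]")
        if self.planted_fc <= 1.0:
            raise ValueError("planted_fc must exceed 1")
        if not 0.0 <= self.dispersion < 1.0:
            raise ValueError("dispersion must be in [0, 1)")
        if self.rfs_hazard_prg <= 0 or self.rfs_hazard_grg <= 0:
            raise ValueError("hazards must be positive")
        if self.sc_intensity_noise < 0:
            raise ValueError("sc_intensity_noise must be non-negative")


def default_config(seed: int = 0) -> GenerationConfig:
    """Configuration mirroring the emulated study's cohort composition."""
    return GenerationConfig(seed=seed)


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generator."""

    planted_de: list[tuple[str, str, float]]  # (protein_id, direction, true fc)
    prognostic_proteins: list[str]
    prs_members: set[str]
    response_label: dict[str, str]
    stromal_proteins: list[str]

    def to_json(self, path) -> None:
        payload = {
            "planted_de": [list(t) for t in self.planted_de],
            "prognostic_proteins": self.prognostic_proteins,
            "prs_members": sorted(self.prs_members),
            "response_label": self.response_label,
            "stromal_proteins": self.stromal_proteins,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass
class SyntheticCohorts:
    discovery: CountMatrix
    validation: CountMatrix
    discovery_intensity: CountMatrix
    validation_intensity: CountMatrix
    proteins: pd.DataFrame
    samples: pd.DataFrame
    truth: SyntheticTruth


def _draw_rfs(rng: np.random.Generator, label: str, cfg: GenerationConfig) -> float:
    if label == "PRG":
        # exponential truncated to (0, 16]
        h = cfg.rfs_hazard_prg
        u = rng.uniform()
        return -np.log1p(-u * (1.0 - np.exp(-h * 16.0))) / h
    if label == "GRG":
        return 24.0 + rng.exponential(1.0 / cfg.rfs_hazard_grg)
    return rng.uniform(16.0, 24.0)


def generate_cohorts(config: GenerationConfig) -> SyntheticCohorts:
    """Generate paired discovery/validation cohorts with planted truth.

    Identical configurations (including the seed) yield bit-identical
    output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_prot = config.n_proteins
    protein_ids = [f"P{i:04d}" for i in range(1, n_prot + 1)]

    # --- protein roles ---------------------------------------------------
    base_w = rng.lognormal(mean=0.0, sigma=1.5, size=n_prot)
    perm = rng.permutation(n_prot)
    planted_idx = perm[: config.n_planted_de]
    remaining = perm[config.n_planted_de :]
    # stromal block from the mid-abundance range: visible to clustering but
    # with a small compositional footprint on the rest of the proteome
    n_stromal = max(1, int(round(STROMAL_FRACTION * n_prot)))
    lo, hi = np.quantile(base_w, [0.2, 0.6])
    mid = remaining[(base_w[remaining] >= lo) & (base_w[remaining] <= hi)]
    if len(mid) < n_stromal:
        mid = remaining
    stromal_idx = mid[:n_stromal]
    rest = np.array([i for i in remaining if i not in set(stromal_idx)])
    n_sub = max(1, int(round(SUBTYPE_FRACTION * n_prot)))
    luad_idx = rest[:n_sub]
    lusc_idx = rest[n_sub : 2 * n_sub]

    directions = np.where(np.arange(config.n_planted_de) % 2 == 0, "PRG_up", "GRG_up")
    prognostic_idx = planted_idx[: config.n_planted_prognostic]

    # --- samples ----------------------------------------------------------
    arms = (
        [("discovery", "ACT", config.n_samples_discovery, "D")]
        + [("validation", "ACT", config.n_samples_validation_act, "V")]
        + [("validation", "UT", config.n_samples_validation_ut, "U")]
    )
    rows = []
    for cohort, treatment, n, prefix in arms:
        for j in range(1, n + 1):
            rows.append({"sample_id": f"{prefix}{j:02d}", "cohort": cohort, "treatment": treatment})
    samples = pd.DataFrame(rows)
    n_samples = len(samples)

    subtype = np.where(rng.uniform(size=n_samples) < config.luad_fraction, "LUAD", "LUSC")
    subtype[samples["treatment"].to_numpy() == "UT"] = "LUAD"
    samples["subtype"] = subtype

    p_int = INTERMEDIATE_FRACTION
    labels = rng.choice(
        ["PRG", "GRG", "intermediate"],
        size=n_samples,
        p=[PRG_FRACTION * (1 - p_int), (1 - PRG_FRACTION) * (1 - p_int), p_int],
    )

    # PR/S members per cohort, weighted towards PRG samples
    prs_members: set[str] = set()
    for cohort in ("discovery", "validation"):
        in_cohort = samples.index[samples["cohort"] == cohort].to_numpy()
        n_members = int(round(config.prs_cluster_fraction * len(in_cohort)))
        weights = np.where(labels[in_cohort] == "PRG", PRS_PRG_WEIGHT, 1.0)
        weights /= weights.sum()
        chosen = rng.choice(in_cohort, size=n_members, replace=False, p=weights)
        prs_members.update(samples.loc[chosen, "sample_id"])

    rfs = np.array([_draw_rfs(rng, lab, config) for lab in labels])
    event = np.ones(n_samples, dtype=bool)
    over = rfs > ADMIN_CENSOR_MONTHS
    rfs = np.minimum(rfs, ADMIN_CENSOR_MONTHS)
    event[over] = False
    random_censor = rng.uniform(size=n_samples) < config.censor_rate
    event[random_censor] = False
    samples["rfs_months"] = np.round(rfs, 2)
    samples["event"] = event.astype(int)
    samples["tcp"] = np.clip(np.round(rng.normal(55, 10, size=n_samples)), 30, 90).astype(int)

    # --- per-sample true proportions --------------------------------------
    effect = np.ones((n_prot, n_samples))
    is_act = (samples["treatment"] == "ACT").to_numpy()
    for j, (idx, direction) in enumerate(zip(planted_idx, directions)):
        target = labels == ("PRG" if direction == "PRG_up" else "GRG")
        if idx not in prognostic_idx:
            target = target & is_act
        effect[idx, target] *= config.planted_fc
    member_mask = samples["sample_id"].isin(prs_members).to_numpy()
    effect[np.ix_(stromal_idx, np.where(member_mask)[0])] *= STROMAL_MULTIPLIER
    effect[np.ix_(luad_idx, np.where(subtype == "LUAD")[0])] *= SUBTYPE_MULTIPLIER
    effect[np.ix_(lusc_idx, np.where(subtype == "LUSC")[0])] *= SUBTYPE_MULTIPLIER

    props = base_w[:, None] * effect
    props /= props.sum(axis=0, keepdims=True)

    lib = np.round(
        rng.lognormal(np.log(LIBRARY_SIZE_MEAN) - LIBRARY_SIZE_SIGMA**2 / 2, LIBRARY_SIZE_SIGMA, size=n_samples)
    ).astype(np.int64)

    # --- beta-binomial counts ---------------------------------------------
    cv = config.dispersion
    if cv > 0:
        # per-cell beta with mean p and CV(q) = cv: Var(q) = (cv p)^2
        phi = np.clip(cv**2 * props / (1.0 - props), 1e-12, 0.999)
        s = 1.0 / phi - 1.0
        q = rng.beta(props * s, (1.0 - props) * s)
    else:
        q = props
    counts = rng.binomial(lib[None, :], q)

    # --- dropout -----------------------------------------------------------
    # abundance-dependent: low-abundance proteins lose identifications first
    expected = props * LIBRARY_SIZE_MEAN
    dropout_p = config.zero_inflation * np.exp(-expected / DROPOUT_SCALE)
    non_stromal = np.ones(n_prot, dtype=bool)
    non_stromal[stromal_idx] = False
    cells = np.ix_(non_stromal, np.where(member_mask)[0])
    dropout_p[cells] = dropout_p[cells] + PRS_EXTRA_DROPOUT * np.exp(
        -expected[cells] / PRS_DROPOUT_SCALE
    )
    counts[rng.uniform(size=counts.shape) < dropout_p] = 0

    # --- intensities -------------------------------------------------------
    resp_factor = rng.lognormal(np.log(1e5), 0.5, size=n_prot)
    noise = rng.lognormal(0.0, config.sc_intensity_noise, size=counts.shape)
    intens = counts * resp_factor[:, None] * noise

    # --- protein metadata --------------------------------------------------
    mw = rng.lognormal(np.log(50.0), 0.5, size=n_prot)
    pep_d = rng.poisson(0.18 * mw) + 1
    pep_v = rng.poisson(0.18 * mw) + 1
    proteins = pd.DataFrame(
        {
            "protein_id": protein_ids,
            "mw_kda": np.round(mw, 2),
            "peptides_discovery": pep_d,
            "peptides_validation": pep_v,
        }
    )

    sample_ids = samples["sample_id"].to_numpy()
    disc_cols = sample_ids[(samples["cohort"] == "discovery").to_numpy()]
    val_cols = sample_ids[(samples["cohort"] == "validation").to_numpy()]
    count_df = pd.DataFrame(counts, index=protein_ids, columns=sample_ids)
    intens_df = pd.DataFrame(np.round(intens, 1), index=protein_ids, columns=sample_ids)

    truth = SyntheticTruth(
        planted_de=[
            (protein_ids[idx], direction, config.planted_fc)
            for idx, direction in zip(planted_idx, directions)
        ],
        prognostic_proteins=[protein_ids[i] for i in prognostic_idx],
        prs_members=set(prs_members),
        response_label=dict(zip(sample_ids, labels)),
        stromal_proteins=[protein_ids[i] for i in stromal_idx],
    )

    return SyntheticCohorts(
        discovery=CountMatrix(count_df.loc[:, disc_cols], layer=RAW_SC),
        validation=CountMatrix(count_df.loc[:, val_cols], layer=RAW_SC),
        discovery_intensity=CountMatrix(intens_df.loc[:, disc_cols], layer=INTENSITY),
        validation_intensity=CountMatrix(intens_df.loc[:, val_cols], layer=INTENSITY),
        proteins=proteins,
        samples=samples,
        truth=truth,
    )


def write_cohorts(cohorts: SyntheticCohorts, out_dir) -> None:
    """Write the TSV/JSON artifact bundle for a generated cohort pair."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohorts.discovery.to_tsv(out / "counts_discovery.tsv")
    cohorts.validation.to_tsv(out / "counts_validation.tsv")
    cohorts.discovery_intensity.to_tsv(out / "intensities_discovery.tsv")
    cohorts.validation_intensity.to_tsv(out / "intensities_validation.tsv")
    cohorts.samples.to_csv(out / "samples.tsv", sep="\t", index=False)
    cohorts.proteins.to_csv(out / "proteins.tsv", sep="\t", index=False)
    cohorts.truth.to_json(out / "truth.json")


def config_from_dict(d: dict) -> GenerationConfig:
    known = {f.name for f in dataclasses.fields(GenerationConfig)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown generation parameters: {sorted(unknown)}")
    return GenerationConfig(**d)
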