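# Methods

This note documents the statistical models, the synthetic data generator,
the numerical choices and the known limitations of `ptxrank`.

## Count model and differential test

Spectral counts are treated as draws from a beta-binomial distribution: for
one protein, sample *s* contributes *k_s* spectra out of *n_s* total spectra
in that sample, where the latent per-sample proportion *q_s* ~
Beta(α, β) with mean π = α/(α+β) and overdispersion φ = 1/(α+β+1).
φ → 0 recovers the plain binomial (pure counting noise); larger φ adds
between-sample biological and technical variability.

The two-group test is a likelihood-ratio test. The null model fits one
(π, φ) to both groups pooled; the alternative fits group-specific means
(π_A, π_B) with a shared φ. Twice the log-likelihood gain is referred to
χ²(1). Inference is two-sided through the LRT; direction is read from the
fitted group means. Design points:

* **Optimization** — bounded L-BFGS-B with analytic gradients (digamma
  functions), bounds π ∈ [1e-9, 1−1e-9], φ ∈ [1e-9, 0.999], and three
  starts for the overdispersion (method-of-moments estimate, 0.25, 0.01) to
  avoid flat-likelihood stalls. The best of the starts is kept.
* **Shared vs per-group φ** — shared φ is the default (the mean difference
  is the target of inference; a per-group-φ variant is available via
  `per_group_phi=True` / `--per-group-phi` for sensitivity analysis).
* **Degenerate inputs** — all-zero counts in both groups return p = 1;
  samples with zero totals are excluded with a warning; fewer than two
  usable samples per group is an error.
* **Normalized counts as input** — normalization equalizes sample totals,
  so the per-sample trial count is the (common) normalized sample sum and
  normalized values are rounded back to integers to keep count support.
  With library sizes near 10⁵ the rounding bias is negligible.
* **Calibration** — under a simulated null (π = 0.001, φ = 0.05, 10 vs 10
  samples, library size 10⁵) the measured type-I error at α = 0.05 is
  ≈ 0.05 (the acceptance script recomputes this with 2,000 simulated
  proteins).
* **Multiplicity** — the tier system deliberately filters on raw p < 0.05
  and uses cross-cohort replication as the error control; a
  Benjamini–Hochberg FDR column is emitted for information only.

Significance tiers: T1 = p < 0.05 (strict); T2 = T1 and data presence
≥ 0.60 (inclusive) in the upregulated group; T3 = T2 and fold-change > 1.5
(strict). Fold-changes are reported as a ratio ≥ 1 plus an upregulated-group
flag, with a pseudocount (default 0.5 normalized counts) guarding
division by zero; a "downregulated by more than 1.5-fold" call is the same
ratio with the direction flag reversed.

## Cross-cohort candidates

A candidate must reach the chosen tier with the same direction in both
cohorts, in the LUAD and/or pan-NSCLC comparison (any-of, per-direction
concordant); discordant-direction proteins are excluded and logged. The
hypergeometric overlap test uses as universe the proteins tested in both
cohorts after filtering — only co-testable proteins can overlap. Prognostic
flagging uses T1 with concordant direction in the untreated arm: effects
that replicate without treatment indicate prognosis, not treatment
response. The LUSC validation comparison is typically refused as
underpowered (< 2 samples in a response group) and the pipeline records the
skip rather than aborting.

## Signature search

Subsets of candidate proteins (gated on combined-cohort spectral-count to
intensity correlation > 0.75) are scored as classifiers of PRG vs GRG:

* Features are log2(x+1) normalized counts, standardized per training fold.
* The classifier is logistic regression with a small L2 penalty
  (λ = 1e-3 on standardized features), fit by Newton/IRLS. The penalty
  guarantees finite estimates under the perfect separation that small
  subsets of ~60 samples routinely produce. The IRLS implementation is
  validated in the test suite against scikit-learn's LogisticRegression on
  full enumerations; it exists because the combinatorial search performs
  10⁴–10⁵ fits and needs a numpy-only hot loop.
* Performance is the AUC of pooled leave-one-out held-out probabilities
  (exactly *n* fits per subset). Pooled-LOO AUC is *pessimistic under the
  null* — the held-out sample's class is always under-represented in its
  training fold, so uninformative subsets score below 0.5 on average. This
  bias is shared by all subsets and therefore harmless for ranking, but the
  absolute AUC of a null subset should not be read as 0.5.
* Exhaustive search evaluates every k-subset exactly once (C(62,4) =
  557,845 for the full-scale pool; a count-only mode verifies the
  combinatorics instantly). Random probing draws subsets uniformly without
  within-draw replacement; duplicate draws are scored once and deduplicated
  in the report. Ties in AUC are broken lexicographically on protein ids,
  making all searches order-independent and deterministic.
* Stepwise construction starts from the highest single-protein AUC or a
  designated (most robust) marker and greedily adds the protein with the
  largest AUC gain, stopping when the gain is ≤ ε (default 0.005) or the
  signature reaches 6 proteins.
* Protein frequencies are counted over the top F = 100 combinations
  (configurable); positional signature scores use the top-30 lists of the
  4- and 5-mer searches.
* The pipeline caps the number of scored subsets (`exhaustive_max_combos`,
  default 5,000, falling back to random probing beyond it, and `n_draws`,
  default 2,000): these are compute-scaling knobs of the orchestration; the
  operation-level functions implement the full-scale semantics.

## Robustness rubric and composite rank

Component bins follow a half-open-from-below convention with the top bin
closed, so touching bin edges (0.85, 0.95) are deterministic and monotone:

* (a) SC:intensity correlation, binned on the *minimum* of the two cohorts:
  < 0.75 → 0; [0.75, 0.85) → 1; [0.85, 0.95) → 2; ≥ 0.95 → 3. A missing
  correlation (constant vector) scores 0 and is logged.
* (b) mean abundance in the upregulated group, first match from the top:
  both cohorts ≥ 30 → 3; both ≥ 15 → 2; both ≤ 5 → 0; anything else → 1.
  The "both ≤ 5" rule is checked before the residual mixed-low rule so the
  overlapping phrasings resolve deterministically.
* (c) tier pair: T3:T3 → 3; T2:T3 or T3:T2 → 2; T2:T2 → 1; anything with a
  side below T2 → 0.
* (d) unique peptides ÷ molecular weight (kDa): > 0.2 in both cohorts → 2;
  otherwise ≥ 0.1 in both → 1; < 0.1 in either → 0 (the ambiguous region
  with one cohort in [0.1, 0.2) and the other above 0.2 resolves to 1 by
  first-match from the top).

Robustness = a+b+c+d ∈ [0, 11]; signature score ∈ [0, 4] (best top-30
position mapped 1–10 → 3, 11–20 → 2, 21–30 → 1, plus 1 for stepwise
membership); composite = sum ∈ [0, 15]. Ranking sorts by composite, then
robustness, then the product of the two cohorts' p-values, then protein id.
The "robust candidate" threshold (default 7) applies to the robustness
total, with the signature score displayed separately.

## Survival analysis

Response groups: PRG iff RFS ≤ 16 months, GRG iff RFS > 24 months,
intermediate otherwise (excluded from DE, retained elsewhere). The event
indicator covers recurrence or death from any cause. Kaplan–Meier and
log-rank are computed with `lifelines`. Abundance splits use the
linear-interpolation sample quantile with ties assigned to the lower group;
this reproduces a 7-vs-21 high/low split at the 0.75 quantile of 28
samples. The split operation is subset-agnostic: callers choose the sample
subset.

## Cohort structure

Samples are clustered on per-protein z-scores of log2(x+1) normalized
counts with correlation distance and average linkage, cut at K = 3 (a
LUAD-enriched, a LUSC-enriched and a mixed-histology cluster are the
expected structure; K, distance and linkage are configurable, and
silhouette values are reported but not used for selection). Row scaling
matters: without it, all samples of a cohort correlate at ≈ 0.95 through
the common abundance distribution and linkage degenerates into one blob
plus singletons. The cluster with the highest PRG fraction is flagged as
the candidate PR/S cluster, tested for enrichment with a one-sided Fisher
exact test and compared to the remaining samples by log-rank. Per-sample
protein-identification counts are reported so the "fewer identifications in
the PR/S cluster" signature can be checked directly.

## Synthetic cohort generator

The generator emulates the statistical structure of two archival FFPE NSCLC
cohorts quantified by single-shot spectral counting. Defaults mirror the
emulated study design: 45 discovery ACT samples, 22 validation ACT samples,
10 untreated (all-LUAD) validation samples, ~60 % LUAD, a PR/S sub-cluster
of 26 % of each cohort, 50 planted differential proteins at fold-change
2.5, and survival hazards 0.12 (PRG) vs 0.04 (GRG) events/month with
administrative censoring at 36 months plus 20 % random censoring.
Intermediate-response samples (RFS in (16, 24]) occur at ~15 % so the
exclusion path is exercised.

Mechanics and the reasoning behind them:

* **Abundance** — per-protein base weights are lognormal(0, 1.5);
  per-sample library sizes are lognormal around 100,000 total counts
  (plausible single-shot depth; downstream analysis is scale-free).
* **Overdispersion** — the `dispersion` parameter is the biological
  coefficient of variation of a protein's true proportion across samples
  (default 0.3). It is realized per protein as a beta-binomial with
  φ_i = cv²·p_i/(1−p_i), so every protein is exactly beta-binomial (the
  test's assumption) while all proteins share one biological CV. A single
  shared φ across proteins would instead give low-abundance proteins a CV
  of √(φ/p) — hundreds of percent — which real data do not show.
* **Dropout** — a cell is zeroed with probability
  `zero_inflation · exp(−expected_count/20)`: missingness concentrates in
  low-abundance proteins, as in real spectral counting. PR/S members get
  extra dropout (+0.15 at scale 40), producing their reduced
  protein-identification counts.
* **PR/S cluster** — members (26 % of each cohort, drawn with 9:1 weight
  towards PRG samples) up-shift a fixed block of 10 % "stromal" proteins
  3-fold. The stromal block is drawn from the 20–60th abundance percentile:
  the up-shift is then clearly visible to clustering while its compositional
  footprint (proportions must sum to one, so boosting one block deflates
  all others) stays small. The residual compositional shift still induces
  some genuine, replicated differential expression beyond the planted list
  — as the cluster does in real cohorts — which is why recovery tests
  treat stromal proteins as true signal.
* **Histology** — two 8 % marker blocks are up-shifted 2-fold in LUAD and
  LUSC samples respectively, giving the subtype-dominated clustering
  structure; the multiplier is kept below the stromal block's so
  mixed-histology PR/S members cluster by their stromal signature rather
  than by subtype.
* **Planted effects** — planted proteins alternate PRG-up/GRG-up with the
  configured fold-change applied to the true proportions of the respective
  response group in both cohorts; effects are treatment-predictive (ACT
  samples only) except for an optional prognostic subset
  (`n_planted_prognostic`) whose effect also applies in the untreated arm.
* **Survival** — PRG times are truncated-exponential on (0, 16], GRG times
  are 24 plus an exponential tail, intermediates uniform on (16, 24), so
  generated labels stay consistent with the RFS thresholds used downstream.
* **Intensities** — counts × per-protein response factor × lognormal noise
  (σ = `sc_intensity_noise`), zeros staying zero, giving the high
  count↔intensity correlation that rubric component (a) expects.

What the generator does **not** emulate: peptide-to-protein inference and
shared-peptide ambiguity, batch/run-order effects, real missingness
mechanisms beyond abundance-dependent dropout, correlated protein modules
beyond the three planted blocks, non-exponential survival, or tumour-cell
percentage effects (tcp is annotation plumbing only). Passing recovery
tests therefore demonstrate correctness of the analysis logic under the
stated model, not performance on real cohorts.

## Problem sizes in the shipped tests and acceptance script

The combinatorial search semantics are verified at full scale where cheap
(the 62-pool 4-mer count, 557,845, via count-only mode) and on complete
enumerations of small pools where fits are involved. End-to-end recovery
runs 10 replicate default cohorts (500 proteins) through the pan-NSCLC
comparisons; the acceptance script uses 5 replicates plus one full run with
a scaled-down search (a few hundred scored subsets). Test-time beta-binomial
calibration uses 2,000 simulated null proteins. These sizes were chosen to
give stable Monte-Carlo margins; all are configuration, not code limits.

## Known limitations

* The LRT's χ²(1) reference is asymptotic; with very small groups (n ≈ 4–5,
  as in the untreated arm) p-values are approximate. Zero-inflated
  low-abundance proteins mildly inflate the test's type-I error (the
  filtering step removes most of them).
* The cluster-vs-rest log-rank is power-limited in a 32-sample cohort; at
  the default 3-fold hazard contrast roughly half of simulated validation
  cohorts reach p < 0.05 (the larger discovery cohort mostly does).
* Pooled-LOO AUC is biased low under the null (see above); compare AUCs
  only within a search, not across sample sizes.
* The pipeline evaluates a capped number of subsets by default; full-scale
  searches are available through the operation functions and CLI flags but
  cost hours at C(62,4) × n LOOCV fits.
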