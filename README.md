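# ptxrank

Discovery and ranking of platinum-response protein biomarkers from
spectral-count proteomics of paired patient cohorts.

## The problem

Patients with resected non-small cell lung cancer (NSCLC) routinely receive
platinum-based adjuvant chemotherapy (ACT), yet a large fraction derives no
benefit and no tissue biomarker exists to select responders. Given
label-free, spectral-count protein quantification of two independent tumour
cohorts (a discovery and a validation cohort) with recurrence-free survival
(RFS) follow-up, `ptxrank` implements the complete analysis that turns those
count matrices into a ranked list of response-prediction biomarker
candidates:

1. **Normalization & filtering** — per-sample spectral counts are scaled on
   the sum of counts of all identified proteins relative to the average
   sample sum; proteins are kept when data presence (fraction of samples
   with a nonzero count) reaches a threshold in at least one subtype×cohort
   stratum.
2. **Response groups** — samples are split on RFS into a poor
   response/survival group (PRG, RFS ≤ 16 months) and a good
   response/survival group (GRG, RFS > 24 months); the band in between is
   excluded from differential testing.
3. **Differential expression** — per protein, a beta-binomial
   likelihood-ratio test compares PRG vs GRG. Counts `k_s` of library size
   `n_s` follow a beta-binomial with mean proportion π and overdispersion
   φ = 1/(α+β+1); the null model shares π across groups, the alternative
   fits (π_PRG, π_GRG) with shared φ, and 2·(ℓ₁−ℓ₀) is referred to χ²(1).
   Results are tiered: **T1** p < 0.05; **T2** T1 + data presence ≥ 60 % in
   the upregulated group; **T3** T2 + fold-change > 1.5.
4. **Cross-cohort candidates** — proteins significant with concordant
   direction in *both* cohorts (LUAD and/or pan-NSCLC comparison) become
   candidates; overlap significance is an upper-tail hypergeometric test,
   and candidates that replicate in the untreated (surgery-only) arm are
   flagged as prognostic rather than predictive.
5. **Signature search** — small protein subsets are scored as
   ridge-stabilized logistic classifiers by the AUC of pooled leave-one-out
   held-out probabilities: exhaustive 4-mer search, random 5-mer probing,
   and forward stepwise signature construction.
6. **Robustness & composite ranking** — each candidate receives a 0–11
   robustness score from (a) spectral-count:intensity correlation,
   (b) abundance in the upregulated group, (c) the T1–T3 tier pair and
   (d) unique peptides per kDa, plus a 0–4 signature score from its standing
   in the top-30 combination lists and stepwise signatures; candidates are
   ranked by the composite.
7. **Cohort structure & survival** — hierarchical clustering recovers the
   poor-response/stromal (PR/S) sub-cluster and associates it with outcome
   (Fisher exact + log-rank); top-quartile abundance splits of single
   proteins are compared by Kaplan–Meier/log-rank.

Because the underlying patient data are access-controlled, the package ships
a first-class **synthetic cohort generator** that emulates the statistical
structure of such cohorts (overdispersed beta-binomial counts,
abundance-dependent dropout, a planted PR/S sub-cluster with stromal
up-shift and reduced protein identifications, planted differential proteins
with known fold-change, count↔intensity coupling, and group-dependent
survival hazards) so every stage is testable against known ground truth.

## Worked example

```python
from ptxrank import default_config
from ptxrank.pipeline import PipelineConfig, run_pipeline

config = PipelineConfig(
    generation=default_config(seed=7),   # simulate cohorts: 45 + (22 ACT + 10 UT) samples
    seed=7,
    n_draws=400,                         # 5-protein random probing depth
    exhaustive_max_combos=400,           # cap on scored 4-protein subsets
)
result = run_pipeline(config)
```

Printing the headline results of this run:

```
candidates (T1:T1, direction-concordant): 77
pan-NSCLC overlap significance p = 6.36e-30
robust candidates (robustness >= 7): 68
 rank protein_id  comp_a  comp_b  comp_c  comp_d  robustness_total  signature_score  composite  passes_threshold
    1      P0101       2       3       3       2                10                4         14              True
    2      P0277       1       3       3       2                 9                3         12              True
    3      P0218       1       3       3       2                 9                3         12              True
    4      P0274       1       3       3       2                 9                3         12              True
    5      P0329       1       3       3       2                 9                3         12              True
PR/S cluster: 2 Fisher p = 0.000118 log-rank p = 0.102
top candidate P0101: top-quartile split 6 vs 16, log-rank p = 0.0339
```

77 proteins replicate across the two simulated cohorts at T1 with the same
direction — far more than chance (hypergeometric p ≈ 6e-30). The top-ranked
candidate P0101 is a planted marker: tier T3 in both cohorts (comp_c = 3),
abundant (comp_b = 3), well-supported by peptide evidence (comp_d = 2) and a
member of top signature combinations (signature score 4). Its top-quartile
abundance split separates recurrence-free survival in the validation ACT arm
(log-rank p = 0.034). The mixed-histology PR/S cluster found by unsupervised
clustering is strongly enriched for poor responders (Fisher p = 1.2e-4).

The same stages are exposed as a CLI:

```bash
ptxrank simulate --out sim/ --seed 7
ptxrank preprocess --counts sim/counts_discovery.tsv --samples sim/samples.tsv --out prep/
ptxrank detest --counts prep/normalized_counts.tsv --samples sim/samples.tsv \
        --comparison panNSCLC --cohort discovery --out de_disc.tsv
ptxrank cluster --counts prep/normalized_counts.tsv --samples sim/samples.tsv --out clus/
ptxrank run --config pipeline.yaml
```

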