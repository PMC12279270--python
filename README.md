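# micromet

Integrative microbiome–metabolome association-network analysis for
case–control cohorts, built around the design of treatment-naïve ("inception")
IBD studies: three groups — healthy controls (HC), Crohn's disease (CD) and
ulcerative colitis (UC) — each contributing 16S rRNA amplicon sequence variant
(ASV) counts, per-sample total bacterial 16S copy numbers from qPCR, and
metabolite concentration panels.

It is aimed at microbiome bioinformaticians who want the full analysis chain
as tested, scriptable Python rather than a collection of R sessions and web
servers:

* **Absolute abundance** — counts are rescaled to ecosystem abundance,
  `A(f,s) = count(f,s) / libsize(s) × total16S(s)`, so every sample's column
  sum equals its measured biomass (no rarefaction).
* **Diversity** — Shannon (−Σ p ln p), inverse Simpson (1/Σ p²), classic
  Chao1 (S + F₁²/2F₂) and Faith PD per sample; Aitchison β-diversity
  (Euclidean distance on centered log-ratio vectors), PCoA/NMDS ordination,
  one-factor PERMANOVA (pseudo-F, 999 permutations, exact enumeration for
  tiny designs) and a betadisper-style dispersion test.
* **Univariate statistics** — Kruskal–Wallis omnibus plus pairwise rank
  contrasts (HCvsCD, HCvsUC, CDvsUC) with Benjamini–Hochberg q-values;
  q < 0.1 flags significance.
* **Association networks (the core)** — per cohort, Spearman ρ between every
  taxon and metabolite; BH-FDR across the cohort's whole test family; edges
  kept at q ≤ 0.05 and |ρ| ≥ 0.5. ASV-level edges collapse to genus, and the
  strongly positive (ρ ≥ 0.5) genus–metabolite sets feed Venn-region counts,
  per-genus association-variability rankings, median ρ per genus–metabolite
  pair, healthy/disease sign-flip selection (HC median ≥ 0.4 and disease
  median ≤ −0.4) and a DyNet-style node-rewiring score
  Dn(v) = mean over states of ‖w_state − w̄‖ over the union neighbourhood.
* **Enrichment** — hypergeometric over-representation of network metabolites
  against a GMT pathway library, with the observed/expected enrichment ratio.
* **Synthetic cohorts** — a Gaussian-copula generator (negative-binomial ASV
  margins, lognormal metabolites, qPCR biomass) that plants cohort-specific
  genus–metabolite Spearman correlations exactly in expectation
  (latent Pearson = 2 sin(πρ/6)) and emits the ground-truth table, so every
  downstream stage is testable without any sequencing download.

## Worked example

Simulate a cohort at the usual inception-cohort group sizes (20 HC, 23 CD,
37 UC) with three planted genus–metabolite correlations, and run the whole
pipeline:

```sh
cat > sim.yaml <<EOF
n_genera: 12
asvs_per_genus: 2
n_metabolites: 10
drivers_per_edge: 2
planted_edges:
  - {genus: g001, metabolite: m001, group: HC, rho: 0.7}
  - {genus: g002, metabolite: m002, group: CD, rho: 0.7}
  - {genus: g003, metabolite: m003, group: UC, rho: -0.6}
EOF
micromet run-all --sim-config sim.yaml --out run --seed 11
```

The run directory contains every stage's TSV plus `manifest.json` (config,
seeds, checksums). Since the inputs were simulated, the planted truth is
scored automatically:

```text
$ cat run/recovery.tsv
planted_edges  recall          filtered_edges  precision  false_edges  signflip_planted  signflip_recall
3              0.666666666667  2               1          0            0
```

Two of the three planted edges passed the (q ≤ 0.05, |ρ| ≥ 0.5) filter in
their cohorts and nothing spurious got through (precision 1). The missed edge
is the HC one: at n = 20 a true ρ of 0.7 clears the BH-corrected filter in
roughly 80–90% of draws, and this draw missed — exactly the sampling behaviour
the replicated studies below quantify. Group separation is also summarised:

```text
$ cat run/beta_diversity_tests.tsv
statistic      p_value  n_permutations  seed       method       test
1.2520318957   0.136    999             617747441  permutation  permanova
0.396311676652 0.673    999             617747441  permutation  dispersion
```

With nothing planted that separates whole communities, the Aitchison-distance
PERMANOVA is null (p = 0.136), as it should be. The rewiring table ranks nodes
by how much their weighted neighbourhood changes across the three cohort
networks:

```text
$ head -3 run/rewiring_scores.tsv
node_id  node_type  dn             union_degree  degree_corrected_dn
g002     genus      0.36627140975  1             0.36627140975
g003     genus      0.33421144108  1             0.33421144108
```

The same stages are available individually (`micromet simulate`,
`preprocess`, `diversity`, `univariate`, `network`, `differential`,
`enrich`, `evaluate`) and as library functions (`micromet.build_networks`,
`micromet.rewiring_scores`, ...).

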