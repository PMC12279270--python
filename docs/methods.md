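# Methods

This note documents the statistical model behind `micromet`, the defaults and
why they were chosen, what the synthetic-cohort generator does and does not
emulate, and the numerical conventions that make results reproducible.

## Analysis model

The pipeline treats a cohort as three sample groups (HC, CD, UC) measured on
three aligned tables: ASV counts (features × samples), metabolite
concentrations, and a per-sample total bacterial 16S copy number from qPCR.
Sample alignment is by intersection: every statistic in the pipeline needs
complete cases, so samples missing from any input are dropped (and logged)
rather than imputed.

**Absolute abundance.** 16S counts are compositional; dividing by library
size and multiplying by the qPCR total converts them to ecosystem abundance,
`A(f,s) = c(f,s)/Σ_f c(f,s) × B(s)`, with the invariant that column sums
equal the measured biomass exactly. This removes any need for rarefaction.
Per-sample renormalisation of the result recovers the original relative
composition, and genus aggregation commutes with the transform (both conserve
per-sample totals).

**Genus level and prevalence.** ASVs aggregate to genus by summation. ASVs
without a genus label are retained as `<family>_unclassified` pseudo-genera
rather than dropped, because family-level taxa can carry real signal. Genera
present (> 0) in fewer than 20% of all samples — pooled across groups, before
any cohort split — are removed as rare taxa / sequencing artifacts.

**Diversity.** Shannon entropy uses the natural log; inverse Simpson is
1/Σp²; Chao1 is the classic S + F₁²/(2F₂) with the bias form
S + F₁(F₁−1)/2 when no doubletons exist; Faith PD sums the branch lengths of
the subtree spanning the observed ASVs *including the path to the root* (the
convention of the common phylogenetic toolchains). β-diversity is the
Aitchison distance: Euclidean distance between centered log-ratio vectors,
computed on absolute abundance with a pseudocount (below). Ordination is
classical PCoA (axes ordered by eigenvalue); non-metric MDS initialised from
the PCoA solution is provided as an alternative because both conventions are
common for Aitchison geometry. PERMANOVA partitions the squared distances
(pseudo-F = (SS_between/(a−1))/(SS_within/(n−a))); the dispersion test is the
betadisper construction — per-sample distance to the group centroid in the
positive-eigenvalue PCoA space, one-way F, labels permuted over the fixed
distances.

**Univariate tests.** The omnibus is the tie-corrected Kruskal–Wallis H with
a χ²(k−1) reference; the pairwise contrasts use the two-sided rank-sum test
with the tie-corrected normal approximation (for two groups this is a
monotone function of two-group Kruskal–Wallis, so the p-values coincide;
output columns are labelled `anova_p` to mirror conventional figure captions
but the statistic is always rank-based — no parametric ANOVA is computed).
BH correction runs, by default, per contrast across features, which is how
per-feature q-values are reported next to an omnibus p; a per-feature family
over the three contrasts is available as a switch. Contrasts are significant
at q < 0.1.

**Association networks.** For each cohort independently, Spearman ρ is
computed for every taxon × metabolite pair on that cohort's samples.
ρ is the Pearson correlation of average ranks (tie-safe); the two-sided
p-value uses the t approximation with n−2 df for n ≥ 10 and complete
permutation enumeration below that; constant vectors yield (ρ=0, p=1), are
flagged degenerate, and are excluded from the BH family. The BH family is
all pairs within one cohort (the cohorts are separate analyses; a pooled
family is available as a switch). The filtered network keeps q ≤ 0.05 and
|ρ| ≥ 0.5, both signs; the cross-cohort set analyses use the strongly
positive subset (ρ ≥ +0.5).

Correlations are computed at ASV level and collapsed to genus afterwards.
The median-per-pair summary — the median of all member-ASV ρ values for a
(genus, metabolite, cohort) triple, over *all tested* ASVs, not only
significant ones — exists precisely to capture genera whose strains disagree,
which requires ASV-level input. The abundance scale fed to the correlations
is untransformed absolute abundance. Note that this is *not* a no-op for a
rank statistic: scaling each sample by biomass/library-size permutes
cross-sample ranks, so the choice is recorded as part of the model (see the
generator section for the consequence).

**Differential network analyses.** Sign-flip (anticorrelation) pairs are
genus–metabolite pairs with healthy median ρ ≥ 0.4 and disease median
ρ ≤ −0.4 (CD, UC, or their union); pairs untested in a cohort are excluded
from that contrast, not imputed as zero. Node rewiring follows the DyNet Dn
idea made concrete: for node v with partner-union P across S states, one
zero-filled weight vector per state over P, centroid w̄, and
Dn(v) = (1/S) Σ_s ‖w_s − w̄‖, plus Dn/|P| as a degree-corrected variant.
The original application does not publish its exact normalisation, so this
definition is fixed here and verified against an independent brute-force
implementation; both variants are reported.

**Enrichment.** Over-representation uses the upper-tail hypergeometric test
P(X ≥ k) with the measured-and-mappable metabolites as background (standard
ORA practice of conditioning on the measured universe), BH across tested
pathways, and enrichment ratio = observed/expected with
expected = |query|·K/N. The reversed ratio (expected/observed) is available
behind a flag for compatibility with sources that print it that way.

## Synthetic cohorts

The generator produces the statistical structure the analysis assumes, not
sequencing reads. Per group it draws a latent Gaussian vector over
(ASVs + metabolites); a planted (genus, metabolite, group, ρ) edge makes the
genus' first `drivers_per_edge` ASVs load on the metabolite's latent factor
at 2 sin(πρ/6), the Gaussian-copula identity that makes the target Spearman
exact in expectation because the subsequent quantile transforms are monotone.
Drivers have independent residuals, so a genus mixes associated and null
strains whenever it has more ASVs than drivers. A genus planted against
several metabolites in one group is feasible while the squared loadings sum
below one; otherwise the offending edges are reported as an infeasible
correlation block.

Margins: ASV counts are negative-binomial quantiles (per-ASV means lognormal,
ln-mean ln 300, ln-sd 1.0; common dispersion/size 0.5 — strong, realistic
overdispersion); metabolites are lognormal (ln-sd 1.0, per-metabolite
baselines). Missing metabolite cells are injected completely at random at a
configurable rate (default 0: quantified panels are near-complete; the
imputation path is exercised explicitly in tests). Group sizes default to
HC 20 / CD 23 / UC 37 — a typical three-arm inception-cohort design — so
simulation studies run at realistic n.

**Biomass is coupled to the community.** The measured load is generated as
`B(s) = libsize(s)/median(libsize) × exp(N(ln 1e10, 0.15))`, i.e. the qPCR
value is consistent with the size of the community that produced the counts,
up to a lognormal measurement error (ln-sd 0.15, a typical qPCR technical
scale; ln-mean ln 1e10 ≈ total 16S copies per gram of stool). Under this
coupling the absolute-abundance transform is, per sample, a near-constant
rescaling of the counts, so planted cross-sample rank correlations survive to
the scale the network analysis actually consumes. The alternative — drawing
biomass independently of the counts — would inject sample-level
multiplicative noise shared by every taxon of a sample; at a realistic
independent load spread (ln-sd ≈ 1) that noise dominates the rank signal and
planted correlations of 0.7 become largely unrecoverable at n ≤ 37. Real
cohorts sit between these regimes: true load and composition co-vary
strongly within a stool sample, but inter-subject load differences are larger
than a pure measurement error. The generator's `biomass_log_mean/log_sd`
therefore scale the absolute-abundance axis and its noise without touching
counts (relative-abundance ranks are invariant to them by construction).

What the generator does **not** emulate: sequencing-depth artifacts and read
errors, compositional closure effects (counts are drawn per-ASV, not
multinomially from a fixed depth), phylogenetic correlation between taxa,
covariate structure (age, sex, BMI are carried but never generated or
modelled), cohort-level shifts in total load, and informative missingness.
Passing recovery tests on these cohorts therefore demonstrates that the
statistical machinery is correct and well calibrated — not that real IBD
data will yield comparable power.

## Replicated simulation studies

`micromet.validation` fixes three study designs, chosen once by an a-priori
power analysis and sized to run in minutes on one CPU:

* **Recovery** — 12 genera × 2 strains, 10 metabolites, ten ρ = 0.7 edges
  per cohort (two driver strains each; every (genus, metabolite) pair planted
  in exactly one cohort so that a planted edge surfacing in another cohort's
  network is unambiguous misassignment). 100 replicates; per-cohort-size
  recovery through the (q ≤ 0.05, ρ ≥ 0.5) filter and the misassignment rate.
* **Sign-flip** — four genera of eight co-associating strains planted at
  +0.6 (HC) / −0.6 (CD) over eight 2-strain null genera, 100 replicates.
  The median rule needs several strain-level correlations per genus to
  concentrate: with a single strain the ±0.4 rule at n = 20 selects a true
  ±0.6 pair in only ~3 of 4 draws, whereas the median over eight strains is
  selected in > 90% — and dominant gut genera genuinely carry many strains,
  which is the stated motivation for the median summary.
* **Null calibration** — the default 15 × 2-strain genera and 10 metabolites
  with nothing planted, 200 replicates; the fraction of cohort families with
  any strongly positive edge (≈ the BH family-wise error, expected a few
  percent) and the fraction of genera with any univariate q < 0.05.

`scripts/acceptance.py --seed <s> --out <json>` reruns all three from
scratch plus a bit-identical rerun check of the full pipeline.

## Numerical conventions

* Permutation p-values use the add-one convention, (1 + #{≥ observed})/(1+N),
  so p > 0 always; when the number of distinct label assignments is at most
  10 × the requested permutations the test switches to complete enumeration
  (identity included, no add-one — the p is then exact). The seed is recorded
  in every result.
* The CLR pseudocount defaults to 0.5 — half of one 16S copy, below any
  observed positive absolute abundance — and is required whenever zeros are
  present.
* Missing metabolite cells impute as half the feature's minimum observed
  positive value (standard metabolomics half-minimum rule); entirely missing
  features are dropped with a warning.
* Rankings break ties lexicographically by name; TSV floats are written with
  12 significant digits so write→read round trips are the identity in
  practice; one run seed fans out to per-stage child seeds by a stable hash
  of the stage name, making stages reproducible independently of execution
  order.
* Degenerate (constant) vectors never enter a BH family; empty samples
  report diversity as missing rather than zero.

## Known limitations

* One-factor PERMANOVA only; covariate-adjusted distance models and linear
  mixed-effects adjustments are out of scope, as are OPLS-DA-style
  multivariate models.
* Plain Spearman associations: no partial correlations and no
  compositionality-aware estimators (SparCC-type); on absolute-abundance
  input with few dominant taxa, compositional coupling can attenuate or
  induce associations.
* The Dn normalisation is this package's fixed reconstruction of the cited
  rewiring idea; other implementations may scale differently, so compare
  rankings, not raw values.
* No negative-eigenvalue corrections (Lingoes/Cailliez) in PCoA; Aitchison
  distance is Euclidean on CLR, so eigenvalues are non-negative up to
  round-off in the intended use.
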