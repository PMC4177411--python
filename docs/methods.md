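# Methods

This note records the statistical conventions the package implements, the
model behind the synthetic cohort generator, the numerical choices, and
the limits of what a passing test establishes.

## Study design and data model

The unit of analysis is the matched **triplet**: a psoriasis patient's
lesional swab, the same patient's contralateral clinically-unaffected
swab, and a site-matched swab from a distinct healthy control subject.
The default cohort has 51 triplets (153 samples). Input objects are an
OTU count table (taxa × samples, non-negative integers), a rooted
phylogeny whose tips are the OTUs, a five-rank taxonomy lineage per OTU
(phylum, class, order, family, genus; unassigned ranks labelled "Other"),
and per-sample clinical metadata. Samples are retained only when their
sequencing depth is *strictly greater than* 1,000 reads (configurable).
Chimera flags, when present, are summarised but never used to filter:
flagged OTUs stay in every downstream statistic.

## Synthetic cohort generator

The generator emulates the structure the analysis assumes; its defaults
are the stated world of the tests and are not tuned to outcomes.

**Community model.** Each sample draws a latent community type
("cutaneotype") — type 2 with probability 0.30 / 0.50 / 0.60 for
control / unaffected / lesion. Each type has a genus-level base
composition: type 1 is Proteobacteria-dominated, type 2
Firmicutes/Actinobacteria-dominated, with geometrically decaying mass
inside each phylum block. The four skin genera (*Corynebacterium*,
*Propionibacterium*, *Staphylococcus*, *Streptococcus*) carry ~15% of
type-1 mass and ~35% of type-2 mass, so a 70/30 control mixture sits near
22% combined abundance and a lesion mixture with the 1.6× skin-genera
multiplier lands near 34% — the magnitudes a psoriasis cohort shows.
Genus probabilities are perturbed by a log-normal **subject effect**
(SD 0.3 per genus) shared by the lesion and unaffected members of a
triplet (the matched design); the control subject gets an independent
effect. Genus mass spreads to OTUs by a fixed geometric split (ratio
0.6), OTUs of one genus forming a clade of the simulated phylogeny (Yule
backbone over genera, Yule subtrees within, exponential branch lengths of
mean 0.1).

**Noise model.** Counts are Dirichlet-multinomial: composition ~
Dirichlet(θ·p) with concentration θ = 50 (realistic overdispersion for
16S skin data; configurable), depth ~ discretised lognormal with median
≈ 8,600 reads (log-SD 0.42, matching an IQR of roughly 5,000–11,400).

**Markers.** Two designated marker OTUs (in the *Gp4* and *Schlegelella*
genera) are jointly present with probability 0.78 / 0.53 / 0.20 per skin
type. When present they take fixed shares (0.8% and 0.5%) of the
composition rather than passing through the Dirichlet draw: at these
shares a present marker is essentially never lost to sampling at depths
above the 1,000-read filter, so the realised double-positive rate matches
the configured prevalence. Severity scores (PASI/BSA/PGA) are lognormal
with means 8.7 / 9.4 / 6.6 (SDs 10.1 / 13.9 / 6.9) as scale anchors, with
a configurable coupling shifting the log-mean when markers are depleted.

**Longitudinal mode.** Weeks 0/12/36 share subject identities and subject
effects; the lesion and unaffected skin-genera multipliers shrink toward
the control multiplier by a configurable fraction per visit, with an
optional transient overshoot of the unaffected multiplier at week 12 (the
rise-then-fall pattern treatment induces). Attrition defaults to 17
triplets at weeks 0 and 12 and 9 at week 36.

**What the generator does not emulate:** read-level artefacts (no
sequences, no chimera generation), body-site or microenvironment effects
on composition (metadata columns exist and vary, but composition ignores
them by default), temporal autocorrelation beyond the shared subject
effect, and real taxonomic richness (40 genera, 500 OTUs versus tens of
thousands in a real survey). A green recovery test therefore establishes
that the pipeline detects the planted effect structure at realistic
sizes, not that any specific real-data value is reproduced.

## Method conventions

**Shannon index** uses natural log (the community-ecology convention);
the base is an argument. Rarefaction subsamples **without replacement**
via the multivariate hypergeometric distribution, 10 replicates by
default; at full depth it returns the observed index exactly, and the
closed form E[S_d] = S − Σᵢ C(N−nᵢ, d)/C(N, d) serves as the test oracle.
Group trends are tested at a depth of 2,000 reads by Kruskal–Wallis.
Triplet-relative α diversity subtracts the control member's index;
control differences (identically zero) are never emitted. Taxa-sharing
uses presence = at least one read and excludes taxa seen in fewer than
three samples.

**UniFrac.** Unweighted: unique observed branch length over total
observed branch length, the denominator computed pairwise over the union
of the two samples only. Weighted: Σ b_e·|A_e/A_T − B_e/B_T|, normalised
by default by the abundance-weighted root-to-tip scaling
Σ_tips d(root,tip)·(p_A + p_B) so values lie in [0, 1] (the raw variant is
available as `weighted-unifrac-raw`). Both are computed for all pairs at
once through the branch × sample matrix; tests verify exact agreement
with a per-branch enumeration oracle and with scikit-bio. **√JSD** uses
natural log, 0·log 0 = 0, no pseudocount (the mixture m is positive
wherever either argument is), bounded by √ln 2 and metric (triangle
inequality is property-tested). The intra/intergroup summary bins all
C(n,2) pairwise distances into six categories; the ANOVA + Tukey HSD on
those bins treats dependent pairs as independent — this replicates the
conventional procedure and the caveat travels in the result object.

**Ordination.** Cailliez's constant is the largest real eigenvalue of the
2n × 2n block matrix built from the Gower-centred −½d² and −½d; values
below 1e-7·max(d) collapse to zero (the companion eigenproblem carries
~1e-8 numerical noise). PCoA eigendecomposes the Gower-centred −½d²;
negative eigenvalues within 1e-8 of the largest (relative) are clamped to
zero, axes with non-positive eigenvalues are dropped, and variance
explained is reported **over positive eigenvalues only** (the convention
is stated because corrected and raw spectra differ).

**PERMANOVA.** Sequential (Type I) sums of squares in the user-given term
order via orthonormal bases of the nested design spaces (rank-revealing
SVD, so collinear terms raise an error rather than silently absorbing
zero df); categorical terms enter as dummy blocks, numeric columns as a
single centred regressor, `a:b` as the combined-factor dummies.
p = (#{F* ≥ F} + 1)/(B + 1) with B = 9,999 by default, so p is never
zero. Strata restrict permutations within levels; when the within-strata
permutation space has ≤ 10,000 arrangements it is enumerated exactly.
Across-term adjustment reports both Bonferroni (capped at 1) and BH.

**Community typing.** Clustering operates on genus-level relative
abundances (the enterotype convention; the level is an argument). PAM is
deterministic: search spaces with ≤ 10,000 candidate medoid sets are
solved exactly (global optimum, lexicographic tie-break); larger
instances use BUILD + SWAP with best-improvement steps and
lowest-index tie-breaks. The exact route exists because classic SWAP —
including the reference R implementation — stalls in single-swap local
optima on a few percent of small instances, while the package promises
the global optimum wherever it is affordable. The Calinski–Harabasz index
is computed directly from squared distances (W as the per-cluster mean of
squared within-pair distances, B = T − W), which equals the classical
centroid form for Euclidean input; chosen k maximises CH with ties going
to the smaller k, and the full curve is returned so callers can refuse to
typify flat-curve data (no silent forcing of k = 2). The gap statistic
draws its reference sets uniformly over the bounding box of the √JSD PCoA
embedding (Tibshirani's simpler reference) and selects the smallest k
with Gap(k) ≥ Gap(k+1) − s_{k+1}; k = 1 is an admissible no-structure
verdict. Cluster-phenotype association uses Pearson χ² (Fisher exact for
2×2 tables with expected counts < 1) and reports the lesion-vs-control
odds ratio of membership in the lesion-enriched cluster.

**Markers.** The abundance filter is **inclusive** at its 1% threshold.
Kruskal–Wallis uses the tie-corrected rank statistic; BH families are per
taxonomic level for differential abundance, per severity score for
correlations, and per pair set for post hoc tests. Prevalence and
positivity mean count ≥ 1 read. The odds-ratio default estimator is the
**conditional MLE with exact (Fisher) CI**; the sample cross-product OR is
always co-reported, because the two conventions differ visibly on tables
of this size and published values may follow either. AUC is the scaled
Mann–Whitney U, (concordant + ties/2)/(n₁n₂). The chimera summary reports
the flagged fraction to one decimal as a percentage and tests flagged
abundance across skin types, body sites and microenvironments without
removing anything.

## Pipeline and reproducibility

Every stage's seed derives from the master seed by a fixed offset
(modulo 2³¹−1), so changing one stage's seed leaves the others untouched.
The run directory contains per-stage TSVs, the generator truth ledger as
JSON, and a manifest with seeds, stage status and SHA-256 digests of the
scientific outputs; identical configurations reproduce identical digests.
A failing optional stage is recorded in the manifest and does not abort
the remaining stages.

## Known limitations

- The β-diversity ANOVA's independence violation (shared samples across
  pairs) is inherited from the conventional procedure; its p values are
  approximate and should be read qualitatively.
- PERMANOVA supports sequential SS only; marginal (Type II/III) tests are
  out of scope, so term order is part of the analysis specification and
  is logged.
- The gap statistic clusters each reference set afresh; with large k
  ranges it is the most expensive step and is off by default in the
  pipeline.
- Synthetic cohorts cannot validate real-data quantities that depend on
  the true cutaneous ecology (e.g. the fraction of variance on the first
  PCoA plane); such numbers require the original controlled-access data.
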