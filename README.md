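# cutaneo

Community analysis for **triplet-matched cutaneous 16S microbiome
cohorts** — the study design in which each psoriasis patient contributes a
lesional swab and a contralateral clinically-unaffected swab, matched to a
site-matched swab from a healthy control subject.

`cutaneo` implements the complete downstream statistical pipeline such a
study needs, driven by a ground-truthed synthetic cohort generator so
every stage is testable without access-restricted clinical data:

- **I/O and data model** — OTU count tables (TSV / BIOM-style JSON),
  Newick phylogenies, taxonomy lineages, clinical metadata; depth
  filtering (keep samples with > 1,000 reads), relative abundances,
  taxonomic collapsing.
- **α diversity** — richness and Shannon index
  (H = −Σ pᵢ ln pᵢ, nats) on rarefied subsamples drawn without
  replacement; per-skin-type trend tests; triplet-relative diversity
  (lesion/unaffected minus the triplet's control); taxa-sharing analysis.
- **β diversity** — unweighted and (normalised) weighted UniFrac computed
  from the branch-by-sample matrix, √JSD for community typing, and the
  intra/intergroup decomposition with one-way ANOVA + Tukey HSD.
- **Ordination** — Cailliez correction (smallest additive constant making
  a dissimilarity Euclidean-embeddable, from the 2n × 2n companion
  eigenproblem) followed by principal coordinates analysis, with per-axis
  group tests.
- **PERMANOVA** — adonis-style distance-based MANOVA: sequential (Type I)
  sums of squares of the Gower-centred −½d² matrix, permutation pseudo-F
  (F = (SS/df)/(SS_res/df_res)), optional within-subject stratification
  with exhaustive enumeration of small permutation spaces, and post hoc
  pairwise tests.
- **Community typing ("cutaneotypes")** — PAM clustering on √JSD
  distances, Calinski–Harabasz model selection over k = 2..20
  (CH = [B/(k−1)]/[W/(n−k)] in its distance-based form), gap-statistic
  corroboration, and cluster-phenotype association with a
  conditional-MLE odds ratio.
- **Marker battery** — Kruskal–Wallis + Benjamini–Hochberg differential
  abundance of taxa ≥ 1% mean relative abundance, post hoc rank-sum
  pairs, prevalence χ², the two-OTU double-positive incidence predictor
  with exact odds ratios, combined skin-genera abundance
  (*Corynebacterium*, *Propionibacterium*, *Staphylococcus*,
  *Streptococcus*), ROC/AUC via Mann–Whitney, Spearman severity
  correlations (PASI/BSA/PGA) and a chimera-QC summary.
- **Synthetic cohorts** — Dirichlet-multinomial communities over a
  simulated phylogeny with two latent community types, group-dependent
  type mixing, a lesion multiplier on the skin-genera block,
  presence/absence marker OTUs and matched-design subject effects, plus a
  longitudinal mode with treatment shrinkage and attrition.

## Worked example

```python
import cutaneo as c

cfg = c.SimulationConfig(cohort_seed=42)        # 51 triplets, 500 OTUs
table, metadata, taxonomy, tree, truth = c.simulate_cohort(cfg)

profiles = c.to_relative(c.collapse_taxonomy(table, taxonomy, "genus"))
combined = c.combined_genera_marker(profiles, metadata)
typing = c.typify(profiles, metadata, k_range=range(2, 11))
dm = c.pairwise_distances(table, tree, "weighted-unifrac")
ordination = c.pcoa(dm, cailliez=True)
dp = c.double_positive_predictor(table, metadata, truth.marker_otus)
```

With this seed the run prints:

```
samples: 153  OTUs: 500  median depth: 8595
combined skin-genera abundance:
  control 23.5% ± 1.6%   unaffected 28.2% ± 1.9%   lesion 38.3% ± 1.8%
  Kruskal-Wallis p = 6.8e-07 ; lesion-vs-control AUC = 0.803
community typing: chosen k = 2 ; chi2 p = 0.026 ;
  lesion-enriched-cluster OR = 2.81 (95% CI 1.18-6.87)
ordination: Cailliez c = 0.193 ; PC1+PC2 explain 30.1%
  PC1 ANOVA (by skin type) p = 2.6e-04
double-positive predictor: control 80%, unaffected 57%, lesion 25%
  lesion-vs-control OR = 0.086 (0.029 to 0.232)
```

Reading the output: the combined abundance of the four major
skin-associated genera rises from control to lesion and classifies lesion
vs control with AUC ≈ 0.8; the cohort splits into two community types with
the lesion-enriched type showing odds ratio ≈ 2.8 against control; the
leading PCoA axis of weighted-UniFrac distances aligns with clinical skin
type; and joint presence of the two designated marker OTUs is strongly
depleted in lesions (OR ≈ 0.09). All of these signals are planted by the
generator at configured effect sizes, so recovery is checked against the
truth ledger, not eyeballed.

A command-line interface mirrors the stages
(`cutaneo simulate | alpha | beta | ordinate | permanova | cutaneotype |
markers | run | longitudinal`); `cutaneo run --seed 0 --out run/` executes
everything and writes TSV tables plus a manifest with per-stage seeds and
file digests.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full pipeline from scratch on the default synthetic cohort
(all stages must complete) including a longitudinal pass, and writes the
result JSON to `--out`.

## Documentation

`docs/methods.md` describes the statistical model of the generator, each
method's exact conventions (log bases, normalisations, tie-breaks,
estimators), numerical tolerances, and what the synthetic cohorts do and
do not establish about real data.
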