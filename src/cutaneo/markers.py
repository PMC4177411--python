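"""Marker discovery: differential abundance, incidence predictors, ROC,
severity correlations and chimera QC.

All abundance tests run on the highly abundant taxa (mean relative
abundance at or above 1% by default). Omnibus differences across the three
clinical skin types use Kruskal-Wallis with Benjamini-Hochberg FDR control
within each taxonomic level; post hoc rank-sum tests localise the
difference to a pair. Presence/absence signals use Pearson chi-square on
prevalence and a double-positive predictor (both designated OTUs present)
whose group-pair odds ratios are estimated by conditional maximum
likelihood with exact confidence intervals (the sample cross-product OR is
co-reported). Classification strength is the ROC AUC, equal to the
Mann-Whitney U statistic scaled by the product of group sizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, kruskal, mannwhitneyu, spearmanr
from scipy.stats.contingency import odds_ratio as _scipy_odds_ratio
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .io import CountTable, RelativeAbundanceTable, SampleMetadata, SKIN_TYPES

logger = logging.getLogger("cutaneo")


# ---------------------------------------------------------------------------
# Abundance filter
# ---------------------------------------------------------------------------

def abundant_taxa(profiles: RelativeAbundanceTable, threshold: float = 0.01) -> list:
    """Taxa whose mean relative abundance across samples is >= threshold.

    The threshold is inclusive; taxa at exactly 1% are retained.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    means = profiles.data.mean(axis=1)
    kept = means.index[means >= threshold].tolist()
    if not kept:
        logger.warning("no taxa pass the %.3f abundance filter", threshold)
    return kept


# ---------------------------------------------------------------------------
# Differential abundance
# ---------------------------------------------------------------------------

def kruskal_wallis_fdr(profiles: RelativeAbundanceTable, metadata: SampleMetadata,
                       taxa=None) -> pd.DataFrame:
    """Kruskal-Wallis across skin types per taxon, BH within this family.

    Returns per-taxon statistic, df, per-group median relative abundance,
    raw p and BH q. A taxon constant across all samples gets p = 1 and a
    degenerate flag.
    """
    taxa = list(taxa) if taxa is not None else list(profiles.data.index)
    types = metadata.data.loc[profiles.sample_ids, "skin_type"]
    rows = []
    for taxon in taxa:
        vals = profiles.data.loc[taxon]
        groups = [vals[types == t].to_numpy() for t in SKIN_TYPES]
        medians = {f"median_{t}": float(np.median(g)) for t, g in zip(SKIN_TYPES, groups)}
        if np.ptp(vals.to_numpy()) == 0.0:
            rows.append({"taxon": taxon, "statistic": 0.0, "df": 2, "p_value": 1.0,
                         "degenerate": True, **medians})
            continue
        stat, p = kruskal(*groups)
        rows.append({"taxon": taxon, "statistic": float(stat), "df": 2,
                     "p_value": float(p), "degenerate": False, **medians})
    out = pd.DataFrame(rows).set_index("taxon")
    out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def posthoc_pairwise(profiles: RelativeAbundanceTable, metadata: SampleMetadata,
                     taxa) -> pd.DataFrame:
    """Rank-sum tests on the three skin-type pairs for omnibus-significant
    taxa, BH-adjusted over the three pairs within each taxon."""
    taxa = list(taxa)
    if not taxa:
        raise ValueError("post hoc testing requires omnibus-significant taxa")
    types = metadata.data.loc[profiles.sample_ids, "skin_type"]
    pairs = [("control", "unaffected"), ("control", "lesion"), ("unaffected", "lesion")]
    rows = []
    for taxon in taxa:
        vals = profiles.data.loc[taxon]
        ps = []
        for a, b in pairs:
            ga, gb = vals[types == a], vals[types == b]
            if np.ptp(np.concatenate([ga, gb])) == 0.0:
                ps.append(1.0)
            else:
                ps.append(float(mannwhitneyu(ga, gb, alternative="two-sided").pvalue))
        qs = multipletests(ps, method="fdr_bh")[1]
        for (a, b), p, q in zip(pairs, ps, qs):
            rows.append({"taxon": taxon, "pair": f"{a}-{b}", "p_value": p, "q_value": q})
    return pd.DataFrame(rows)


def differential_abundance(table: CountTable, taxonomy, metadata: SampleMetadata,
                           levels=("phylum", "class", "order", "family", "genus", "otu"),
                           threshold: float = 0.01) -> pd.DataFrame:
    """The full per-level battery: collapse, filter, KW + BH per level."""
    from .io import collapse_taxonomy, to_relative
    frames = []
    for level in levels:
        collapsed = collapse_taxonomy(table, taxonomy, level)
        profiles = to_relative(collapsed)
        keep = abundant_taxa(profiles, threshold)
        if not keep:
            continue
        res = kruskal_wallis_fdr(profiles, metadata, keep)
        res.insert(0, "level", level)
        frames.append(res.reset_index())
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Combined skin-genera marker
# ---------------------------------------------------------------------------

def _genus_rows(profiles: RelativeAbundanceTable, genus: str) -> list:
    """Rows matching a genus name, whether ids are bare names or
    ';'-joined lineage strings ending in the genus."""
    idx = profiles.data.index
    return [t for t in idx if t == genus or str(t).endswith(";" + genus)]


@dataclass
class RocResult:
    """ROC AUC with its Mann-Whitney significance test."""

    auc: float
    u_statistic: float
    p_value: float
    n_positive: int
    n_negative: int


def roc_auc(scores, labels) -> RocResult:
    """AUC as the scaled Mann-Whitney U: (concordant + ties/2) / (n1*n2).

    ``labels`` are binary; the positive class is the one with the larger
    label value. Two-sided Mann-Whitney p value.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("roc_auc requires exactly two classes, both non-empty")
    pos, neg = scores[labels == classes[1]], scores[labels == classes[0]]
    res = mannwhitneyu(pos, neg, alternative="two-sided")
    auc = float(res.statistic) / (len(pos) * len(neg))
    return RocResult(auc=auc, u_statistic=float(res.statistic),
                     p_value=float(res.pvalue), n_positive=len(pos), n_negative=len(neg))


def combined_genera_marker(profiles: RelativeAbundanceTable, metadata: SampleMetadata,
                           genera=("Corynebacterium", "Propionibacterium",
                                   "Staphylococcus", "Streptococcus")) -> dict:
    """Combined relative abundance of the major skin genera as a marker.

    Sums the named genera per sample (missing genera contribute zero with
    a warning), tests across skin types (Kruskal-Wallis + post hoc
    rank-sum pairs), and scores lesion-vs-control classification by ROC
    AUC. Both the full set and the set minus Propionibacterium are
    evaluated.
    """
    types = metadata.data.loc[profiles.sample_ids, "skin_type"]

    def evaluate(gset) -> dict:
        rows = []
        for g in gset:
            r = _genus_rows(profiles, g)
            if not r:
                logger.warning("genus %r absent from profiles; contributes 0", g)
            rows.extend(r)
        combined = profiles.data.loc[rows].sum(axis=0) if rows else pd.Series(
            0.0, index=profiles.sample_ids)
        groups = [combined[types == t].to_numpy() for t in SKIN_TYPES]
        stat, p = kruskal(*groups)
        pairs = {}
        for a, b in (("control", "lesion"), ("unaffected", "lesion"),
                     ("control", "unaffected")):
            pairs[f"{a}-{b}"] = float(
                mannwhitneyu(combined[types == a], combined[types == b],
                             alternative="two-sided").pvalue)
        lc = types.isin(["lesion", "control"])
        roc = roc_auc(combined[lc], (types[lc] == "lesion").astype(int))
        summary = {t: {"mean": float(g.mean()),
                       "sem": float(g.std(ddof=1) / np.sqrt(len(g)))}
                   for t, g in zip(SKIN_TYPES, groups)}
        return {"combined": combined, "kw_statistic": float(stat), "kw_p": float(p),
                "pairwise_p": pairs, "roc": roc, "group_summary": summary}

    return {
        "four_genera": evaluate(list(genera)),
        "three_genera": evaluate([g for g in genera if g != "Propionibacterium"]),
    }


# ---------------------------------------------------------------------------
# Prevalence and the double-positive predictor
# ---------------------------------------------------------------------------

def prevalence_chi2(table: CountTable, metadata: SampleMetadata, taxa) -> pd.DataFrame:
    """Pearson chi-square on presence/absence (count >= 1) per taxon,
    2 x 3 over skin types, BH across taxa."""
    types = metadata.data.loc[table.sample_ids, "skin_type"]
    rows = []
    for taxon in taxa:
        pres = table.data.loc[taxon] >= 1
        rates = {f"prevalence_{t}": float(pres[types == t].mean()) for t in SKIN_TYPES}
        if pres.all() or not pres.any():
            rows.append({"taxon": taxon, "chi2": 0.0, "p_value": 1.0,
                         "degenerate": True, **rates})
            continue
        ct = pd.crosstab(pres, types)
        chi2, p, _, _ = chi2_contingency(ct)
        rows.append({"taxon": taxon, "chi2": float(chi2), "p_value": float(p),
                     "degenerate": False, **rates})
    out = pd.DataFrame(rows).set_index("taxon")
    out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


@dataclass
class OddsRatioResult:
    """2x2 odds ratio with both estimator conventions.

    ``estimate`` is the conditional maximum-likelihood OR with its exact
    (Fisher) confidence interval; ``sample_or`` is the cross-product
    ad/bc. ``p_value`` is the two-sided Fisher exact test.
    """

    counts: tuple               # (a, b, c, d) row-major
    estimate: float
    ci_low: float
    ci_high: float
    sample_or: float
    p_value: float
    estimator: str = "conditional-mle"


def odds_ratio(a: int, b: int, c: int, d: int, alpha: float = 0.05) -> OddsRatioResult:
    """Odds ratio of the 2x2 table [[a, b], [c, d]].

    Conditional MLE point estimate with exact CI; sample cross-product OR
    co-reported (inf/nan-safe for zero margins).
    """
    table = np.array([[a, b], [c, d]], dtype=int)
    res = _scipy_odds_ratio(table, kind="conditional")
    ci = res.confidence_interval(1.0 - alpha)
    with np.errstate(divide="ignore", invalid="ignore"):
        sample = (a * d) / (b * c) if b * c > 0 else np.inf if a * d > 0 else np.nan
    _, p = fisher_exact(table)
    if min(table.sum(axis=0).min(), table.sum(axis=1).min()) == 0:
        logger.warning("zero margin in 2x2 table; CI from the exact method only")
    return OddsRatioResult(counts=(a, b, c, d), estimate=float(res.statistic),
                           ci_low=float(ci.low), ci_high=float(ci.high),
                           sample_or=float(sample), p_value=float(p))


def double_positive_predictor(table: CountTable, metadata: SampleMetadata,
                              otu_pair) -> dict:
    """Incidence-based predictor: both designated OTUs present (>= 1 read).

    Reports per-skin-type single- and double-positivity percentages and
    the three group-pair odds ratios (each group pair as rows of the 2x2:
    [first group: double-positive, not; second group: double-positive,
    not]).
    """
    o1, o2 = otu_pair
    for o in (o1, o2):
        if o not in table.data.index:
            raise KeyError(f"OTU {o!r} not in the table")
    types = metadata.data.loc[table.sample_ids, "skin_type"]
    p1 = table.data.loc[o1] >= 1
    p2 = table.data.loc[o2] >= 1
    dp = p1 & p2
    rates = {}
    for t in SKIN_TYPES:
        sel = types == t
        rates[t] = {
            "n": int(sel.sum()),
            f"positive_{o1}_pct": float(100.0 * p1[sel].mean()),
            f"positive_{o2}_pct": float(100.0 * p2[sel].mean()),
            "double_positive_pct": float(100.0 * dp[sel].mean()),
            "double_positive_n": int(dp[sel].sum()),
        }
    ors = {}
    for a, b in (("lesion", "control"), ("unaffected", "control"), ("lesion", "unaffected")):
        na, nb = rates[a]["n"], rates[b]["n"]
        da, db = rates[a]["double_positive_n"], rates[b]["double_positive_n"]
        ors[f"{a}_vs_{b}"] = odds_ratio(da, na - da, db, nb - db)
    return {"rates": rates, "odds_ratios": ors, "otu_pair": (o1, o2)}


# ---------------------------------------------------------------------------
# Severity correlations
# ---------------------------------------------------------------------------

def severity_correlation(profiles: RelativeAbundanceTable, metadata: SampleMetadata,
                         taxa, scores=("PASI", "BSA", "PGA")) -> pd.DataFrame:
    """Spearman correlation of taxon abundance with severity scores.

    Restricted to lesion samples carrying the score; BH adjustment within
    each score across taxa. Constant scores are flagged undefined.
    """
    md = metadata.data.loc[profiles.sample_ids]
    lesion = md.index[(md["skin_type"] == "lesion")]
    frames = []
    for score in scores:
        sc = md.loc[lesion, score].dropna()
        rows = []
        if sc.nunique() <= 1:
            logger.warning("severity score %r constant or absent; flagged undefined", score)
            for taxon in taxa:
                rows.append({"taxon": taxon, "score": score, "rho": np.nan,
                             "p_value": np.nan, "undefined": True})
            frames.append(pd.DataFrame(rows))
            continue
        for taxon in taxa:
            vals = profiles.data.loc[taxon, sc.index]
            if vals.nunique() <= 1:
                rows.append({"taxon": taxon, "score": score, "rho": np.nan,
                             "p_value": np.nan, "undefined": True})
                continue
            rho, p = spearmanr(vals, sc)
            rows.append({"taxon": taxon, "score": score, "rho": float(rho),
                         "p_value": float(p), "undefined": False})
        df = pd.DataFrame(rows)
        ok = ~df["undefined"]
        df["q_value"] = np.nan
        if ok.any():
            df.loc[ok, "q_value"] = multipletests(df.loc[ok, "p_value"], method="fdr_bh")[1]
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Chimera QC
# ---------------------------------------------------------------------------

def chimera_qc_summary(table: CountTable, chimera_flags: pd.Series,
                       metadata: SampleMetadata | None = None) -> dict:
    """Summarise putatively chimeric OTUs without removing them.

    Returns the flagged fraction as a percentage (1 decimal), the
    per-sample relative abundance of flagged OTUs, and -- when metadata is
    given -- Kruskal-Wallis tests of that abundance across skin types,
    body sites and microenvironments.
    """
    flags = chimera_flags.reindex(table.taxon_ids)
    if flags.isna().any():
        raise ValueError("chimera flags do not align with the table's taxa")
    flags = flags.astype(bool)
    pct = round(100.0 * flags.sum() / len(flags), 1)
    depths = table.depths
    flagged_abund = table.data.loc[flags.to_numpy()].sum(axis=0) / depths
    out = {"flagged_pct": float(pct), "n_flagged": int(flags.sum()),
           "n_total": int(len(flags)), "per_sample_abundance": flagged_abund}
    if metadata is not None:
        md = metadata.data.loc[table.sample_ids]
        tests = {}
        for factor in ("skin_type", "body_site", "microenvironment"):
            if factor not in md.columns:
                continue
            groups = [flagged_abund[md[factor] == lv].to_numpy()
                      for lv in md[factor].dropna().unique()]
            groups = [g for g in groups if len(g) > 0]
            if len(groups) < 2 or np.ptp(np.concatenate(groups)) == 0:
                tests[factor] = {"statistic": np.nan, "p_value": np.nan}
                continue
            stat, p = kruskal(*groups)
            tests[factor] = {"statistic": float(stat), "p_value": float(p)}
        out["kw_tests"] = tests
    return out
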