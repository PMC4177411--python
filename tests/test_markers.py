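import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from cutaneo import (
    CountTable,
    RelativeAbundanceTable,
    SampleMetadata,
    abundant_taxa,
    chimera_qc_summary,
    combined_genera_marker,
    double_positive_predictor,
    kruskal_wallis_fdr,
    odds_ratio,
    posthoc_pairwise,
    prevalence_chi2,
    roc_auc,
    severity_correlation,
    to_relative,
)
from statsmodels.stats.multitest import multipletests
from conftest import triplet_metadata


def profiles_from(matrix, taxa, samples) -> RelativeAbundanceTable:
    df = pd.DataFrame(matrix, index=taxa, columns=samples, dtype=float)
    return RelativeAbundanceTable(df / df.sum(axis=0))


class TestAbundantTaxa:
    def test_threshold_inclusive(self):
        prof = RelativeAbundanceTable(pd.DataFrame(
            {"s1": [0.01, 0.99], "s2": [0.01, 0.99]}, index=["low", "high"]))
        assert abundant_taxa(prof, 0.01) == ["low", "high"]

    def test_below_threshold_excluded(self):
        prof = RelativeAbundanceTable(pd.DataFrame(
            {"s1": [0.005, 0.995], "s2": [0.005, 0.995]}, index=["low", "high"]))
        assert abundant_taxa(prof, 0.01) == ["high"]

    def test_matches_brute_force_mean_scan(self, small_cohort):
        prof = to_relative(small_cohort[0])
        got = abundant_taxa(prof, 0.01)
        expected = [t for t in prof.data.index if prof.data.loc[t].mean() >= 0.01]
        assert got == expected

    def test_invalid_threshold(self, small_cohort):
        with pytest.raises(ValueError):
            abundant_taxa(to_relative(small_cohort[0]), 1.5)


class TestKruskalWallis:
    def test_hand_rank_value(self):
        """Groups (1,2,3 | 4,5,6 | 7,8,9) give H = 7.2 by the rank formula."""
        md = triplet_metadata(3)
        order = [f"T{t:02d}.{st}" for st in ("control", "unaffected", "lesion")
                 for t in range(3)]
        vals = {s: v for s, v in zip(order, range(1, 10))}
        base = np.array([[vals[s] for s in md.data.index]], dtype=float)
        prof = profiles_from(np.vstack([base, 100 - base]), ["tx", "rest"],
                             list(md.data.index))
        res = kruskal_wallis_fdr(prof, md, taxa=["tx"])
        assert res.loc["tx", "statistic"] == pytest.approx(7.2, abs=1e-10)

    def test_identical_groups_zero_statistic(self):
        md = triplet_metadata(2)
        prof = profiles_from(np.ones((2, 6)), ["a", "b"], list(md.data.index))
        res = kruskal_wallis_fdr(prof, md)
        assert (res["statistic"] == 0).all() or res["degenerate"].all()

    def test_bh_step_up_example(self):
        """p = (0.01, 0.02, 0.03, 0.04) over m = 4 tests gives q = 0.04 for all."""
        q = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        assert np.allclose(q, 0.04)

    def test_bh_matches_step_up_definition_on_random_vectors(self):
        """q_(i) = min_{j>=i} p_(j) m / j, monotone in p (1,000 vectors)."""
        rng = np.random.default_rng(0)
        for _ in range(1000):
            m = int(rng.integers(2, 12))
            p = rng.random(m)
            q = multipletests(p, method="fdr_bh")[1]
            order = np.argsort(p)
            expected = np.empty(m)
            running = np.minimum.accumulate(
                (p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
            expected[order] = np.minimum(running, 1.0)
            assert np.allclose(q, expected)
            assert (np.diff(q[order]) >= -1e-12).all()

    def test_medians_reported_per_group(self, small_cohort):
        table, metadata, _, _, _ = small_cohort
        prof = to_relative(table)
        res = kruskal_wallis_fdr(prof, metadata, taxa=prof.data.index[:5])
        for col in ("median_control", "median_unaffected", "median_lesion"):
            assert col in res.columns
        assert (res["q_value"] >= res["p_value"] - 1e-12).all()


class TestPosthoc:
    def test_lesion_shift_localised(self):
        """Only the lesion-involving pairs flag when just lesion is shifted,
        in at least 90% of seeds."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(400 + seed)
            md = triplet_metadata(20)
            types = md.data["skin_type"]
            base = rng.normal(10, 1, size=60)
            base[(types == "lesion").to_numpy()] += 4.0
            prof = profiles_from(np.vstack([base, 100 - base]), ["tx", "rest"],
                                 list(md.data.index))
            out = posthoc_pairwise(prof, md, ["tx"]).set_index("pair")
            flagged = (out.loc["control-lesion", "q_value"] < 0.05
                       and out.loc["unaffected-lesion", "q_value"] < 0.05)
            clean = out.loc["control-unaffected", "q_value"] > 0.05
            hits += flagged and clean
        assert hits >= 18

    def test_empty_taxon_list_rejected(self, small_cohort):
        table, metadata, _, _, _ = small_cohort
        with pytest.raises(ValueError, match="omnibus"):
            posthoc_pairwise(to_relative(table), metadata, [])


class TestCombinedGenera:
    def test_sum_arithmetic(self):
        md = triplet_metadata(1)
        taxa = ["P;Corynebacterium", "P;Propionibacterium", "P;Staphylococcus",
                "P;Streptococcus", "P;Other"]
        col = np.array([0.10, 0.05, 0.04, 0.03, 0.78])
        prof = RelativeAbundanceTable(pd.DataFrame(
            {s: col for s in md.data.index}, index=taxa))
        res = combined_genera_marker(prof, md)
        assert np.allclose(res["four_genera"]["combined"], 0.22)
        assert np.allclose(res["three_genera"]["combined"], 0.17)

    def test_lesion_enrichment_detected(self, default_cohort):
        from cutaneo import collapse_taxonomy
        table, metadata, taxonomy, _, _ = default_cohort
        prof = to_relative(collapse_taxonomy(table, taxonomy, "genus"))
        res = combined_genera_marker(prof, metadata)
        four = res["four_genera"]
        assert four["group_summary"]["lesion"]["mean"] > four["group_summary"]["control"]["mean"]
        assert four["kw_p"] < 0.01
        assert four["roc"].auc > 0.5

    def test_missing_genus_contributes_zero(self, caplog):
        md = triplet_metadata(1)
        prof = RelativeAbundanceTable(pd.DataFrame(
            {s: [1.0] for s in md.data.index}, index=["P;Other"]))
        res = combined_genera_marker(prof, md)
        assert np.allclose(res["four_genera"]["combined"], 0.0)


class TestPrevalenceChi2:
    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(5)
        md = triplet_metadata(51)
        types = md.data["skin_type"]
        pres = pd.Series(False, index=md.data.index)
        for t, rate in (("control", 0.8), ("unaffected", 0.6), ("lesion", 0.4)):
            ids = md.data.index[types == t]
            pres[ids] = rng.random(len(ids)) < rate
        counts = pd.DataFrame(0, index=["tx"], columns=md.data.index)
        counts.loc["tx", pres] = 5
        counts.loc["pad"] = 10
        res = prevalence_chi2(CountTable(counts), md, ["tx"])
        # textbook Pearson chi2 on the realised 2x3 table
        obs = pd.crosstab(pres, types).to_numpy()
        expected = obs.sum(1)[:, None] * obs.sum(0)[None, :] / obs.sum()
        chi2 = ((obs - expected) ** 2 / expected).sum()
        assert res.loc["tx", "chi2"] == pytest.approx(chi2, abs=1e-10)

    def test_degenerate_taxon_flagged(self):
        md = triplet_metadata(2)
        counts = pd.DataFrame(1, index=["everywhere"], columns=md.data.index)
        res = prevalence_chi2(CountTable(counts), md, ["everywhere"])
        assert res.loc["everywhere", "degenerate"]
        assert res.loc["everywhere", "p_value"] == 1.0


class TestOddsRatio:
    def test_equal_rates_give_unity(self):
        res = odds_ratio(10, 10, 10, 10)
        assert res.estimate == pytest.approx(1.0, abs=1e-6)
        assert res.sample_or == 1.0

    def test_cmle_between_sample_or_and_one(self):
        """The conditional-MLE estimate shrinks toward 1 relative to the
        cross-product OR on all-positive tables."""
        rng = np.random.default_rng(6)
        for _ in range(30):
            a, b, c, d = rng.integers(1, 40, size=4)
            res = odds_ratio(int(a), int(b), int(c), int(d))
            lo, hi = sorted([res.sample_or, 1.0])
            assert lo - 1e-9 <= res.estimate <= hi + 1e-9

    def test_ci_contains_estimate(self):
        res = odds_ratio(12, 30, 25, 9)
        assert res.ci_low <= res.estimate <= res.ci_high


class TestDoublePositive:
    def _cohort_with_rates(self, rates, seed=0):
        rng = np.random.default_rng(seed)
        md = triplet_metadata(51)
        types = md.data["skin_type"]
        counts = pd.DataFrame(0, index=["m1", "m2", "pad"], columns=md.data.index)
        counts.loc["pad"] = 100
        for t, rate in rates.items():
            ids = md.data.index[types == t]
            k = int(round(rate * len(ids)))
            both = rng.permutation(ids)[:k]
            counts.loc[["m1", "m2"], both] = 3
        return CountTable(counts), md

    def test_rates_and_or_orientation(self):
        table, md = self._cohort_with_rates(
            {"control": 40 / 51, "unaffected": 27 / 51, "lesion": 10 / 51})
        res = double_positive_predictor(table, md, ("m1", "m2"))
        assert res["rates"]["control"]["double_positive_n"] == 40
        assert res["rates"]["lesion"]["double_positive_n"] == 10
        lvc = res["odds_ratios"]["lesion_vs_control"]
        assert lvc.sample_or == pytest.approx((10 * 11) / (41 * 40), abs=1e-12)
        assert lvc.estimate < 1.0

    def test_equal_rates_or_one(self):
        table, md = self._cohort_with_rates(
            {"control": 0.5, "unaffected": 0.5, "lesion": 0.5}, seed=1)
        res = double_positive_predictor(table, md, ("m1", "m2"))
        for orr in res["odds_ratios"].values():
            assert 0.3 < orr.estimate < 3.0

    def test_missing_otu_rejected(self, small_cohort):
        table, metadata, _, _, _ = small_cohort
        with pytest.raises(KeyError):
            double_positive_predictor(table, metadata, ("nope1", "nope2"))


class TestRocAuc:
    def test_perfect_separation(self):
        res = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.auc == 1.0

    def test_brute_force_pair_concordance(self):
        """AUC equals (concordant + ties/2) / (n1 n2) counted over all
        pairs, on random instances with n1*n2 <= 400."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            n1, n2 = int(rng.integers(2, 20)), int(rng.integers(2, 20))
            pos = rng.integers(0, 10, n1).astype(float)
            neg = rng.integers(0, 10, n2).astype(float)
            scores = np.concatenate([neg, pos])
            labels = np.array([0] * n2 + [1] * n1)
            res = roc_auc(scores, labels)
            conc = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert res.auc == pytest.approx(conc / (n1 * n2), abs=1e-12)

    def test_hand_example(self):
        res = roc_auc([1, 2, 3, 2, 3, 4], [0, 0, 0, 1, 1, 1])
        # (2,3,4) vs (1,2,3): 6 concordant pairs + 2 ties -> 7 of 9
        assert res.auc == pytest.approx(7 / 9, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])


class TestSeverityCorrelation:
    def _md_with_scores(self, n, scores):
        md = triplet_metadata(n).data.copy()
        lesion = md.index[md["skin_type"] == "lesion"]
        for k, v in scores.items():
            md[k] = np.nan
            md.loc[lesion, k] = v
        return SampleMetadata(md)

    def test_monotone_decreasing_gives_rho_minus_one(self):
        n = 8
        pasi = np.arange(1, n + 1, dtype=float)
        md = self._md_with_scores(n, {"PASI": pasi, "BSA": pasi, "PGA": pasi})
        lesion = md.data.index[md.data["skin_type"] == "lesion"]
        abund = pd.Series(0.5, index=md.data.index)
        abund[lesion] = np.linspace(0.9, 0.1, n)
        prof = RelativeAbundanceTable(pd.DataFrame(
            {s: [abund[s], 1 - abund[s]] for s in md.data.index}, index=["tx", "rest"]))
        res = severity_correlation(prof, md, ["tx"], scores=("PASI",))
        assert res.loc[0, "rho"] == pytest.approx(-1.0)

    def test_tie_corrected_rank_formula(self):
        n = 6
        pasi = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 4.0])
        md = self._md_with_scores(n, {"PASI": pasi})
        lesion = md.data.index[md.data["skin_type"] == "lesion"]
        vals = np.array([0.3, 0.1, 0.1, 0.4, 0.2, 0.5])
        abund = pd.Series(0.5, index=md.data.index)
        abund[lesion] = vals
        prof = RelativeAbundanceTable(pd.DataFrame(
            {s: [abund[s], 1 - abund[s]] for s in md.data.index}, index=["tx", "rest"]))
        res = severity_correlation(prof, md, ["tx"], scores=("PASI",))
        rx, ry = rankdata(vals), rankdata(pasi)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert res.loc[0, "rho"] == pytest.approx(expected, abs=1e-10)

    def test_constant_score_flagged(self):
        md = self._md_with_scores(5, {"PASI": np.ones(5)})
        prof = RelativeAbundanceTable(pd.DataFrame(
            {s: [0.4, 0.6] for s in md.data.index}, index=["tx", "rest"]))
        res = severity_correlation(prof, md, ["tx"], scores=("PASI",))
        assert res["undefined"].all()


class TestChimeraQc:
    def test_reported_percentage(self, small_cohort):
        table, metadata, _, _, _ = small_cohort
        flags = pd.Series(False, index=table.taxon_ids)
        flags.iloc[: round(0.079 * len(flags))] = True
        res = chimera_qc_summary(table, flags, metadata)
        expected = round(100 * flags.sum() / len(flags), 1)
        assert res["flagged_pct"] == expected

    def test_no_flags_zero_percent(self, small_cohort):
        table, metadata, _, _, _ = small_cohort
        flags = pd.Series(False, index=table.taxon_ids)
        res = chimera_qc_summary(table, flags, metadata)
        assert res["flagged_pct"] == 0.0
        assert (res["per_sample_abundance"] == 0).all()

    def test_per_sample_abundance_is_masked_column_sum(self, small_cohort):
        table, metadata, _, _, _ = small_cohort
        rng = np.random.default_rng(8)
        flags = pd.Series(rng.random(len(table.taxon_ids)) < 0.3,
                          index=table.taxon_ids)
        res = chimera_qc_summary(table, flags, metadata)
        expected = table.data.loc[flags.to_numpy()].sum(axis=0) / table.depths
        assert np.allclose(res["per_sample_abundance"], expected)
        assert "skin_type" in res["kw_tests"]

    def test_misaligned_flags_rejected(self, small_cohort):
        table, _, _, _, _ = small_cohort
        with pytest.raises(ValueError, match="align"):
            chimera_qc_summary(table, pd.Series([True]), None)


class TestNullCalibrationBattery:
    def test_marker_tests_hold_type_i_error_under_null(self):
        """Under the generator's null configuration every marker test
        rejects at about the nominal 5% rate (binomial band over 500 runs)."""
        from cutaneo import null_config, simulate_cohort
        n_sim = 500
        rej = {"kw": 0, "prevalence": 0, "auc": 0}
        for seed in range(n_sim):
            cfg = null_config(n_triplets=8, n_otus=32, n_genera=8,
                              cohort_seed=9000 + seed)
            table, metadata, _, _, truth = simulate_cohort(cfg)
            prof = to_relative(table)
            taxon = prof.data.mean(axis=1).idxmax()
            kw = kruskal_wallis_fdr(prof, metadata, taxa=[taxon])
            rej["kw"] += kw.loc[taxon, "p_value"] < 0.05
            marker = truth.marker_otus[0]
            pv = prevalence_chi2(table, metadata, [marker])
            if not pv.loc[marker, "degenerate"]:
                rej["prevalence"] += pv.loc[marker, "p_value"] < 0.05
            types = metadata.data["skin_type"]
            lc = types.isin(["lesion", "control"])
            roc = roc_auc(prof.data.loc[taxon][lc],
                          (types[lc] == "lesion").astype(int))
            rej["auc"] += roc.p_value < 0.05
        se = np.sqrt(0.05 * 0.95 / n_sim)
        for name, count in rej.items():
            assert abs(count / n_sim - 0.05) < 1.96 * se + 0.015, (name, count / n_sim)
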