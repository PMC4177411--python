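import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import f_oneway

from cutaneo import DistanceMatrix, SampleMetadata, adonis, pairwise_adonis, stratified_adonis


def md_from(columns: dict) -> SampleMetadata:
    n = len(next(iter(columns.values())))
    ids = [f"s{i}" for i in range(n)]
    return SampleMetadata(pd.DataFrame(columns, index=ids))


def dm_1d(y) -> DistanceMatrix:
    y = np.asarray(y, dtype=float)
    ids = [f"s{i}" for i in range(len(y))]
    return DistanceMatrix(ids, squareform(pdist(y[:, None])), "euclidean")


class TestAdonis:
    def test_pseudo_f_equals_classical_anova_f(self):
        """On 1-D Euclidean data a one-factor PERMANOVA's pseudo-F is
        exactly the classical one-way ANOVA F."""
        rng = np.random.default_rng(0)
        for _ in range(10):
            y = rng.normal(size=14)
            g = np.array(["a"] * 7 + ["b"] * 7)
            res = adonis(dm_1d(y), md_from({"grp": g}), ["grp"], B=19, seed=0)
            f_classic = f_oneway(y[g == "a"], y[g == "b"])[0]
            assert res.table.loc["grp", "pseudo_F"] == pytest.approx(f_classic, rel=1e-10)

    def test_ss_decomposition(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=12)
        g = np.array(["a", "b", "c"] * 4)
        res = adonis(dm_1d(y), md_from({"grp": g}), ["grp"], B=19, seed=0)
        t = res.table
        assert (t.loc["grp", "sum_sq"] + t.loc["Residual", "sum_sq"]
                == pytest.approx(t.loc["Total", "sum_sq"], abs=1e-8))
        # one-factor total SS identity: sum of squared distances / n
        d = dm_1d(y)
        expected_total = (d.data ** 2).sum() / (2 * d.n)
        assert t.loc["Total", "sum_sq"] == pytest.approx(expected_total, abs=1e-8)

    def test_null_type_i_error_calibrated(self):
        """Under random labels the permutation p value rejects at about the
        nominal 5% rate (500 simulations, B = 199)."""
        rng = np.random.default_rng(2)
        rejections = 0
        n_sim = 500
        for i in range(n_sim):
            y = rng.normal(size=12)
            g = rng.permutation(["a"] * 6 + ["b"] * 6)
            res = adonis(dm_1d(y), md_from({"grp": g}), ["grp"], B=199, seed=i)
            rejections += res.table.loc["grp", "p_value"] <= 0.05
        rate = rejections / n_sim
        se = np.sqrt(0.05 * 0.95 / n_sim)
        assert abs(rate - 0.05) < 1.96 * se + 1e-9

    def test_separated_groups_attain_minimal_p(self):
        """Perfectly separated groups reach the smallest attainable p of
        1/(B+1), up to the random permutations that happen to reproduce
        the group partition (each of which ties the observed F)."""
        y = np.concatenate([np.zeros(6), np.ones(6) * 10])
        g = np.array(["a"] * 6 + ["b"] * 6)
        res = adonis(dm_1d(y), md_from({"grp": g}), ["grp"], B=199, seed=3)
        # oracle: replay the permutation stream and count partition ties
        rng = np.random.default_rng(3)
        ties = 0
        for _ in range(199):
            perm = rng.permutation(12)
            groups = frozenset([frozenset(perm[:6]), frozenset(perm[6:])])
            ties += groups == frozenset([frozenset(range(6)), frozenset(range(6, 12))])
        assert res.table.loc["grp", "p_value"] == pytest.approx((ties + 1) / 200)
        assert res.table.loc["grp", "p_value"] >= 1 / 200

    def test_sequential_order_matters_for_confounded_terms(self):
        rng = np.random.default_rng(3)
        g1 = np.array(["a"] * 8 + ["b"] * 8)
        g2 = np.where(rng.random(16) < 0.8, g1, np.where(g1 == "a", "b", "a"))
        y = (g1 == "a") * 2.0 + rng.normal(size=16) * 0.3
        md = md_from({"g1": g1, "g2": g2})
        r12 = adonis(dm_1d(y), md, ["g1", "g2"], B=19, seed=0)
        r21 = adonis(dm_1d(y), md, ["g2", "g1"], B=19, seed=0)
        assert (r12.table.loc["g1", "sum_sq"]
                != pytest.approx(r21.table.loc["g1", "sum_sq"], abs=1e-12))
        # totals agree regardless of order
        assert r12.table.loc["Total", "sum_sq"] == pytest.approx(
            r21.table.loc["Total", "sum_sq"])

    def test_single_level_term_rejected(self):
        y = np.arange(6.0)
        with pytest.raises(ValueError, match="single level"):
            adonis(dm_1d(y), md_from({"grp": ["a"] * 6}), ["grp"], B=9, seed=0)

    def test_missing_levels_dropped_with_warning(self, caplog):
        y = np.arange(8.0)
        g = ["a", "a", "b", "b", "a", "b", None, "a"]
        res = adonis(dm_1d(y), md_from({"grp": g}), ["grp"], B=19, seed=0)
        assert res.table.loc["Total", "df"] == 6     # one sample dropped


class TestStratifiedAdonis:
    def test_exhaustive_enumeration_for_paired_strata(self):
        """With s strata of size 2 the within-strata permutation space has
        exactly 2^s elements and is enumerated exhaustively."""
        rng = np.random.default_rng(5)
        s = 6
        y = rng.normal(size=2 * s)
        subject = np.repeat([f"p{i}" for i in range(s)], 2)
        cond = np.tile(["lesion", "unaffected"], s)
        md = md_from({"cond": cond, "subject_id": subject})
        res = stratified_adonis(dm_1d(y), md, "cond", strata="subject_id", B=10)
        assert res.exhaustive
        assert res.n_permutations == 2 ** s - 1   # identity excluded

    def test_constant_term_within_strata_gives_p_one(self):
        rng = np.random.default_rng(6)
        s = 5
        y = rng.normal(size=2 * s)
        subject = np.repeat([f"p{i}" for i in range(s)], 2)
        cond = np.repeat(["x", "y", "x", "y", "x"], 2)    # constant per stratum
        md = md_from({"cond": cond, "subject_id": subject})
        res = stratified_adonis(dm_1d(y), md, "cond", strata="subject_id", B=50)
        assert res.table.loc["cond", "p_value"] == pytest.approx(1.0)

    def test_stratification_removes_confounding(self):
        """A factor constant within each subject is confounded with the
        subject effect: free permutations call it significant, while
        within-subject permutations cannot move it (p = 1)."""
        rng = np.random.default_rng(7)
        s = 8
        subj_effect = np.where(np.arange(s) < s // 2, 0.0, 6.0)
        y, cond, subject = [], [], []
        for i in range(s):
            for _ in range(2):
                y.append(subj_effect[i] + rng.normal(scale=0.5))
                # cond constant within subject, aligned with the effect
                cond.append("x" if i < s // 2 else "y")
                subject.append(f"p{i}")
        md = md_from({"cond": cond, "subject_id": subject})
        free = adonis(dm_1d(np.array(y)), md, ["cond"], B=499, seed=1)
        strat = stratified_adonis(dm_1d(np.array(y)), md, "cond",
                                  strata="subject_id", B=499, seed=1)
        assert free.table.loc["cond", "p_value"] < 0.05
        assert strat.table.loc["cond", "p_value"] == pytest.approx(1.0)

    def test_exhaustive_agrees_with_monte_carlo(self):
        rng = np.random.default_rng(8)
        s = 5
        y = rng.normal(size=2 * s)
        y[::2] += 1.0
        subject = np.repeat([f"p{i}" for i in range(s)], 2)
        cond = np.tile(["a", "b"], s)
        md = md_from({"cond": cond, "subject_id": subject})
        exact = stratified_adonis(dm_1d(y), md, "cond", strata="subject_id", B=10)
        p_exact = exact.table.loc["cond", "p_value"]
        # independent oracle: enumerate all within-pair swaps by hand
        idx = np.arange(2 * s)

        def pseudo_f(order):
            yy = y[order]
            a = yy[np.asarray(cond) == "a"]
            b = yy[np.asarray(cond) == "b"]
            return f_oneway(a, b)[0]

        f_obs = pseudo_f(idx)
        count = 0
        total = 0
        for flips in itertools.product([0, 1], repeat=s):
            order = idx.copy()
            for i, f in enumerate(flips):
                if f:
                    order[2 * i], order[2 * i + 1] = order[2 * i + 1], order[2 * i]
            if all(f == 0 for f in flips):
                continue
            total += 1
            count += pseudo_f(order) >= f_obs - 1e-12
        p_manual = (count + 1) / (total + 1)
        assert p_exact == pytest.approx(p_manual, abs=1e-12)


class TestPairwiseAdonis:
    def test_four_level_factor_yields_six_pairs(self):
        rng = np.random.default_rng(9)
        y = rng.normal(size=20)
        g = np.repeat(["body", "head", "upper", "lower"], 5)
        out = pairwise_adonis(dm_1d(y), md_from({"site": g}), "site", B=99, seed=0)
        assert len(out) == 6
        assert set(out.columns) >= {"pair", "pseudo_F", "p_value", "p_bonferroni", "p_bh"}

    def test_only_separated_pair_flagged(self):
        """Two shifted levels among four: across seeds, the separated pair is
        significant and the null pairs are not, in at least 90% of runs."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            y = rng.normal(size=24)
            g = np.repeat(["a", "b", "c", "d"], 6)
            y[g == "a"] += 4.0     # a separated from all; b,c,d mutually null
            out = pairwise_adonis(dm_1d(y), md_from({"lvl": g}), "lvl", B=199, seed=seed)
            out = out.set_index("pair")
            sep = out.loc["a/b", "p_value"] < 0.05
            nulls = out.loc[["b/c", "b/d", "c/d"], "p_value"] > 0.05
            hits += sep and nulls.all()
        assert hits >= 18

    def test_small_level_skipped(self, caplog):
        y = np.arange(8.0)
        g = ["a"] * 3 + ["b"] * 3 + ["c"] * 2
        out = pairwise_adonis(dm_1d(y), md_from({"lvl": g}), "lvl", B=19, seed=0)
        assert set(out["pair"]) == {"a/b"}

    def test_two_level_factor_rejected(self):
        y = np.arange(6.0)
        with pytest.raises(ValueError, match=">= 3 levels"):
            pairwise_adonis(dm_1d(y), md_from({"lvl": ["a", "b"] * 3}), "lvl", B=9, seed=0)
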