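"""Distance-based multivariate analysis of variance (adonis-style).

The squared pairwise distances stand in for the covariance matrix: the
Gower-centred matrix G of -1/2 d^2 is partitioned by projection onto nested
design spaces in the user-given term order (sequential, Type I sums of
squares). Each term's pseudo-F is (SS/df)/(SS_res/df_res) and its
significance comes from permuting sample labels -- freely, or within strata
when the design is matched -- with the add-one rule, so p is never zero.
When strata are given and the exact permutation space is small (<= 10,000
arrangements) it is enumerated exhaustively instead of sampled.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .beta import DistanceMatrix
from .io import SampleMetadata
from .ordination import gower_center

logger = logging.getLogger("cutaneo")

_ENUMERATION_LIMIT = 10_000


@dataclass
class PermanovaTable:
    """Sequential-SS PERMANOVA results.

    ``table`` has one row per model term plus Residual and Total rows with
    columns df, sum_sq, pseudo_F, p_value, p_bonferroni, p_bh.
    """

    table: pd.DataFrame
    n_permutations: int
    seed: int
    term_order: list
    exhaustive: bool = False


def _design_columns(metadata: pd.DataFrame, term: str) -> np.ndarray:
    """Design-matrix columns for one term.

    Categorical factors become dummy indicators (all levels; rank handled
    by projection), numeric columns a single column, and 'a:b' the product
    dummies of the combined factor.
    """
    if ":" in term:
        parts = [p.strip() for p in term.split(":")]
        combo = metadata[parts[0]].astype(str)
        for p in parts[1:]:
            combo = combo + "|" + metadata[p].astype(str)
        return pd.get_dummies(combo).to_numpy(dtype=float)
    col = metadata[term]
    if pd.api.types.is_numeric_dtype(col) and col.nunique() > 6:
        return (col.to_numpy(dtype=float) - col.mean())[:, None]
    if col.nunique() < 2:
        raise ValueError(f"term {term!r} has a single level")
    return pd.get_dummies(col.astype(str)).to_numpy(dtype=float)


def _orthobasis(X: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space (rank-revealing via SVD)."""
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-10)) if s.size else 0
    return u[:, :rank]


def _stratified_permutations(strata: np.ndarray, B: int,
                             rng: np.random.Generator) -> tuple[np.ndarray, bool]:
    """Permutation set restricted within strata.

    Returns (permutation array, exhaustive flag). Exhaustive enumeration is
    used when the full within-strata permutation space has at most
    10,000 elements (identity excluded from the null sample count logic
    upstream via the add-one rule).
    """
    n = len(strata)
    groups = {}
    for i, s in enumerate(strata):
        groups.setdefault(s, []).append(i)
    sizes = [len(v) for v in groups.values()]
    singletons = [s for s, v in groups.items() if len(v) == 1]
    if singletons:
        logger.warning("strata of size 1 contribute no permutations: %s", singletons)
    space = math.prod(math.factorial(k) for k in sizes)
    if space <= _ENUMERATION_LIMIT:
        per_group = [list(itertools.permutations(v)) for v in groups.values()]
        perms = []
        for combo in itertools.product(*per_group):
            perm = np.empty(n, dtype=int)
            for orig, permuted in zip(groups.values(), combo):
                perm[orig] = permuted
            perms.append(perm)
        return np.asarray(perms), True
    perms = np.empty((B, n), dtype=int)
    for b in range(B):
        perm = np.arange(n)
        for v in groups.values():
            idx = np.asarray(v)
            perm[idx] = idx[rng.permutation(len(idx))]
        perms[b] = perm
    return perms, False


def adonis(dist: DistanceMatrix, metadata: SampleMetadata, terms,
           B: int = 9999, seed: int = 0, strata: str | None = None) -> PermanovaTable:
    """Permutational MANOVA with sequential sums of squares.

    Parameters
    ----------
    terms : ordered list of factor names; 'a:b' denotes an interaction.
    strata : optional metadata column restricting permutations to occur
        within its levels (e.g. subject for matched designs).
    """
    md = metadata.data.loc[dist.ids]
    terms = list(terms)
    missing = md[[t for t in set(sum((t.split(":") for t in terms), []))]].isna().any(axis=1)
    if missing.any():
        dropped = md.index[missing].tolist()
        logger.warning("dropping samples with missing factor levels: %s", dropped)
        dist = dist.submatrix(md.index[~missing].tolist())
        md = md.loc[dist.ids]
    n = dist.n
    G = gower_center(dist.data ** 2)
    total_ss = float(np.trace(G))

    bases, dfs = [], []
    X = np.ones((n, 1))
    prev_basis = _orthobasis(X)
    prev_rank = 1
    for term in terms:
        X = np.hstack([X, _design_columns(md, term)])
        basis = _orthobasis(X)
        rank = basis.shape[1]
        if rank == prev_rank:
            raise ValueError(f"term {term!r} adds no degrees of freedom")
        bases.append(basis)
        dfs.append(rank - prev_rank)
        prev_basis, prev_rank = basis, rank
    full_basis = bases[-1]
    df_res = n - prev_rank
    if df_res <= 0:
        raise ValueError("model saturates the data; no residual degrees of freedom")

    def term_stats(Gm: np.ndarray) -> tuple[np.ndarray, float]:
        # tr(H_j G) over the nested hat matrices; the intercept term is 0
        # for a Gower-centred G but kept for generality
        hat = [float(np.sum(b * (Gm @ b))) for b in bases]
        base0 = float(Gm.sum()) / n
        seq = np.diff([base0] + hat)
        ss_res = float(np.trace(Gm)) - hat[-1]
        return seq, ss_res

    seq_ss, ss_res = term_stats(G)
    f_obs = (seq_ss / np.asarray(dfs)) / (ss_res / df_res)

    rng = np.random.default_rng(seed)
    exhaustive = False
    if strata is not None:
        perms, exhaustive = _stratified_permutations(
            md[strata].to_numpy(), B, rng)
    else:
        perms = np.asarray([rng.permutation(n) for _ in range(B)])

    exceed = np.zeros(len(terms))
    n_eff = 0
    for perm in perms:
        if exhaustive and np.array_equal(perm, np.arange(n)):
            continue                      # identity handled by the add-one rule
        Gp = G[np.ix_(perm, perm)]
        seq_p, res_p = term_stats(Gp)
        with np.errstate(invalid="ignore", divide="ignore"):
            f_p = (seq_p / np.asarray(dfs)) / (res_p / df_res)
        exceed += f_p >= f_obs - 1e-12
        n_eff += 1
    p_raw = (exceed + 1.0) / (n_eff + 1.0)

    p_bonf = np.minimum(p_raw * len(terms), 1.0)
    p_bh = multipletests(p_raw, method="fdr_bh")[1] if len(terms) > 1 else p_raw.copy()

    rows = []
    for term, df_t, ss, f, pr, pb, ph in zip(terms, dfs, seq_ss, f_obs, p_raw, p_bonf, p_bh):
        rows.append({"term": term, "df": df_t, "sum_sq": ss, "pseudo_F": f,
                     "p_value": pr, "p_bonferroni": pb, "p_bh": ph})
    rows.append({"term": "Residual", "df": df_res, "sum_sq": ss_res,
                 "pseudo_F": np.nan, "p_value": np.nan,
                 "p_bonferroni": np.nan, "p_bh": np.nan})
    rows.append({"term": "Total", "df": n - 1, "sum_sq": total_ss,
                 "pseudo_F": np.nan, "p_value": np.nan,
                 "p_bonferroni": np.nan, "p_bh": np.nan})
    table = pd.DataFrame(rows).set_index("term")
    return PermanovaTable(table=table, n_permutations=n_eff, seed=seed,
                          term_order=terms, exhaustive=exhaustive)


def stratified_adonis(dist: DistanceMatrix, metadata: SampleMetadata, term: str,
                      strata: str = "subject_id", B: int = 9999,
                      seed: int = 0) -> PermanovaTable:
    """adonis with permutations restricted within strata (e.g. subject)."""
    if metadata.data.loc[dist.ids, strata].isna().any():
        raise ValueError(f"strata column {strata!r} has missing values")
    return adonis(dist, metadata, [term], B=B, seed=seed, strata=strata)


def pairwise_adonis(dist: DistanceMatrix, metadata: SampleMetadata, factor: str,
                    B: int = 9999, seed: int = 0) -> pd.DataFrame:
    """Post hoc one-factor PERMANOVA on every level pair of a factor.

    Pairs where either level has fewer than 3 samples are skipped with a
    warning. p values are adjusted across pairs (Bonferroni capped at 1,
    BH also reported).
    """
    md = metadata.data.loc[dist.ids]
    levels = sorted(md[factor].dropna().unique())
    if len(levels) < 3:
        raise ValueError("pairwise testing expects a factor with >= 3 levels")
    rows = []
    for i, (a, b) in enumerate(itertools.combinations(levels, 2)):
        ids = md.index[md[factor].isin([a, b])].tolist()
        counts = md.loc[ids, factor].value_counts()
        if counts.min() < 3:
            logger.warning("pair (%s, %s) skipped: fewer than 3 samples per level", a, b)
            continue
        sub = dist.submatrix(ids)
        res = adonis(sub, metadata, [factor], B=B, seed=seed + i)
        row = res.table.loc[factor]
        rows.append({"pair": f"{a}/{b}", "df": row["df"], "sum_sq": row["sum_sq"],
                     "pseudo_F": row["pseudo_F"], "p_value": row["p_value"]})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_bonferroni"] = np.minimum(out["p_value"] * len(out), 1.0)
        out["p_bh"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out
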