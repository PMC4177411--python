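"""Phylogenetic and information-theoretic beta diversity.

UniFrac in both flavours: the unweighted variant is the fraction of
observed branch length unique to one of the two samples; the weighted
variant accumulates branch-length-weighted differences of the read
fractions under each branch, optionally normalised by the
abundance-weighted root-to-tip scaling so values land in [0, 1]. The
square-root Jensen-Shannon divergence (a true metric on probability
vectors, bounded by sqrt(ln 2) in nats) serves community typing.

The intra/intergroup decomposition bins all pairwise distances into the
six within/between skin-type categories and tests them with one-way ANOVA
plus Tukey HSD. The ANOVA treats pairs as independent observations, which
they are not; this replicates the conventional procedure and the caveat is
carried in the output.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon, pdist, squareform
from scipy.stats import f_oneway
from skbio import TreeNode
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .io import CountTable, RelativeAbundanceTable, SampleMetadata, SKIN_TYPES, to_relative

logger = logging.getLogger("cutaneo")

_SQRT_LN2 = float(np.sqrt(np.log(2.0)))

#: per-metric admissible range (None = unbounded above)
_METRIC_RANGE = {
    "unweighted-unifrac": (0.0, 1.0),
    "weighted-unifrac": (0.0, 1.0),
    "weighted-unifrac-raw": (0.0, None),
    "sqrt-jsd": (0.0, _SQRT_LN2),
    "euclidean": (0.0, None),
    "other": (0.0, None),
}


@dataclass
class DistanceMatrix:
    """Symmetric sample-by-sample dissimilarity matrix with a metric tag."""

    ids: list
    data: np.ndarray
    metric: str = "other"

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        d = np.asarray(self.data, dtype=float)
        n = len(self.ids)
        if d.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.all(np.isfinite(d)):
            raise ValueError("non-finite distances")
        if not np.allclose(d, d.T, atol=1e-10):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-10):
            raise ValueError("non-zero diagonal")
        lo, hi = _METRIC_RANGE.get(self.metric, (0.0, None))
        if d.min() < lo - 1e-9 or (hi is not None and d.max() > hi + 1e-9):
            raise ValueError(
                f"distances outside admissible range for metric {self.metric!r}"
            )
        self.data = (d + d.T) / 2.0
        np.fill_diagonal(self.data, 0.0)

    @property
    def n(self) -> int:
        return len(self.ids)

    def loc(self, a, b) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.data[i, j])

    def submatrix(self, ids) -> "DistanceMatrix":
        idx = [self.ids.index(s) for s in ids]
        return DistanceMatrix(list(ids), self.data[np.ix_(idx, idx)], self.metric)

    def condensed(self) -> np.ndarray:
        return squareform(self.data, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.ids, columns=self.ids)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="#SampleID")

    @classmethod
    def read_tsv(cls, path, metric: str = "other") -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(), metric)


# ---------------------------------------------------------------------------
# Branch bookkeeping
# ---------------------------------------------------------------------------

def branch_matrix(tree: TreeNode, taxon_ids) -> tuple[np.ndarray, np.ndarray]:
    """Branch lengths and branch-by-taxon incidence of a rooted tree.

    Row e of the incidence matrix marks the requested taxa that are tips in
    the subtree below branch e (the edge above each non-root node). Raises
    ``KeyError`` if a requested taxon is not a tip of the tree.
    """
    taxon_ids = list(taxon_ids)
    pos = {t: i for i, t in enumerate(taxon_ids)}
    tip_names = {t.name for t in tree.tips()}
    missing = [t for t in taxon_ids if t not in tip_names]
    if missing:
        raise KeyError(f"taxa absent from tree tips: {missing}")
    below = {}
    lengths, rows = [], []
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            vec = np.zeros(len(taxon_ids), dtype=bool)
            if node.name in pos:
                vec[pos[node.name]] = True
        else:
            vec = np.zeros(len(taxon_ids), dtype=bool)
            for child in node.children:
                vec |= below[id(child)]
        below[id(node)] = vec
        if not node.is_root():
            lengths.append(0.0 if node.length is None else float(node.length))
            rows.append(vec)
    return np.asarray(lengths), np.vstack(rows)


# ---------------------------------------------------------------------------
# Pairwise operations
# ---------------------------------------------------------------------------

def unweighted_unifrac(tree: TreeNode, present_a, present_b) -> float:
    """Fraction of observed branch length unique to one sample.

    ``present_a``/``present_b`` are collections of taxon ids observed in
    each sample. Branches subtending no observed tip are ignored.
    """
    a, b = set(present_a), set(present_b)
    if not a or not b:
        raise ValueError("empty sample in unweighted UniFrac")
    taxa = sorted(a | b)
    lengths, inc = branch_matrix(tree, taxa)
    in_a = inc[:, [taxa.index(t) for t in sorted(a)]].any(axis=1)
    in_b = inc[:, [taxa.index(t) for t in sorted(b)]].any(axis=1)
    union = float(lengths[in_a | in_b].sum())
    unique = float(lengths[in_a ^ in_b].sum())
    if union == 0.0:
        return 0.0
    return unique / union


def weighted_unifrac(tree: TreeNode, counts_a: pd.Series, counts_b: pd.Series,
                     normalized: bool = True) -> float:
    """Abundance-weighted UniFrac between two count vectors.

    Raw form: sum over branches of b_e * |A_e/A_T - B_e/B_T| with A_e the
    reads of sample A below branch e. The normalised form divides by the
    abundance-weighted sum of root-to-tip distances so the result is in
    [0, 1].
    """
    counts_a, counts_b = counts_a.astype(float), counts_b.astype(float)
    if counts_a.sum() <= 0 or counts_b.sum() <= 0:
        raise ValueError("empty sample in weighted UniFrac")
    taxa = sorted(set(counts_a.index) | set(counts_b.index))
    pa = counts_a.reindex(taxa, fill_value=0.0).to_numpy() / counts_a.sum()
    pb = counts_b.reindex(taxa, fill_value=0.0).to_numpy() / counts_b.sum()
    lengths, inc = branch_matrix(tree, taxa)
    qa, qb = inc @ pa, inc @ pb
    raw = float(np.sum(lengths * np.abs(qa - qb)))
    if not normalized:
        return raw
    root_tip = lengths @ inc          # per-taxon root-to-tip distance
    denom = float(root_tip @ (pa + pb))
    if denom == 0.0:
        return 0.0
    return raw / denom


def jsd_distance(p, q) -> float:
    """Square root of the Jensen-Shannon divergence (natural log)."""
    p, q = np.asarray(p, dtype=float), np.asarray(q, dtype=float)
    if (p < 0).any() or (q < 0).any():
        raise ValueError("negative entries in probability vector")
    if not (np.isclose(p.sum(), 1.0) and np.isclose(q.sum(), 1.0)):
        raise ValueError("inputs must each sum to 1")
    return float(jensenshannon(p, q, base=np.e))


def pairwise_distances(table: CountTable, tree: TreeNode | None, metric: str) -> DistanceMatrix:
    """All-pairs distance matrix for one of the supported metrics.

    The UniFrac metrics are computed in vectorised form through the
    branch-by-sample matrix, equivalent branch by branch to the per-pair
    definitions.
    """
    X = table.data.to_numpy(dtype=float)
    depths = X.sum(axis=0)
    if (depths == 0).any():
        empty = [s for s, d in zip(table.sample_ids, depths) if d == 0]
        raise ValueError(f"empty samples: {empty}")
    P = X / depths
    ids = table.sample_ids

    if metric == "sqrt-jsd":
        d = squareform(pdist(P.T, metric="jensenshannon"))
        return DistanceMatrix(ids, d, "sqrt-jsd")
    if metric == "euclidean":
        return DistanceMatrix(ids, squareform(pdist(P.T)), "euclidean")
    if metric in ("unweighted-unifrac", "weighted-unifrac", "weighted-unifrac-raw"):
        if tree is None:
            raise ValueError("UniFrac metrics require a tree")
        lengths, inc = branch_matrix(tree, table.taxon_ids)
        if metric == "unweighted-unifrac":
            pres = (inc.astype(float) @ (X > 0)) > 0       # branches x samples
            W = lengths[:, None] * pres
            t = W.sum(axis=0)
            shared = W.T @ pres
            unique = t[:, None] + t[None, :] - 2.0 * shared
            union = t[:, None] + t[None, :] - shared
            with np.errstate(invalid="ignore", divide="ignore"):
                d = np.where(union > 0, unique / union, 0.0)
            np.fill_diagonal(d, 0.0)
            return DistanceMatrix(ids, d, "unweighted-unifrac")
        Q = inc.astype(float) @ P                         # branches x samples
        raw = squareform(pdist((lengths[:, None] * Q).T, metric="cityblock"))
        if metric == "weighted-unifrac-raw":
            return DistanceMatrix(ids, raw, "weighted-unifrac-raw")
        root_tip = lengths @ inc
        s = root_tip @ P
        denom = s[:, None] + s[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(denom > 0, raw / denom, 0.0)
        np.fill_diagonal(d, 0.0)
        return DistanceMatrix(ids, d, "weighted-unifrac")
    raise ValueError(f"unsupported metric {metric!r}")


# ---------------------------------------------------------------------------
# Intra/intergroup summary
# ---------------------------------------------------------------------------

@dataclass
class BetaGroupSummary:
    """Within/between skin-type decomposition of pairwise distances."""

    summary: pd.DataFrame       # category, mean, sem, n_pairs
    anova_f: float
    anova_p: float
    tukey: pd.DataFrame         # pairwise category comparisons, adjusted p
    caveat: str = (
        "Pairwise distances are not independent observations; the ANOVA "
        "replicates the conventional procedure and p values are approximate."
    )


def _pair_category(ta: str, tb: str) -> str:
    if ta == tb:
        return f"within-{ta}"
    a, b = sorted([ta, tb], key=SKIN_TYPES.index)
    return f"{a}-{b}"


def beta_group_summary(dist: DistanceMatrix, metadata: SampleMetadata) -> BetaGroupSummary:
    """Bin pairwise distances into the six skin-type categories and test.

    Mean +/- SEM per category, one-way ANOVA across categories and Tukey
    HSD adjusted pairwise comparisons. Categories with fewer than two pairs
    are dropped with a warning.
    """
    types = metadata.data.loc[dist.ids, "skin_type"]
    cats, vals = [], []
    for i, j in itertools.combinations(range(dist.n), 2):
        cats.append(_pair_category(types.iloc[i], types.iloc[j]))
        vals.append(dist.data[i, j])
    df = pd.DataFrame({"category": cats, "distance": vals})
    counts = df["category"].value_counts()
    small = counts[counts < 2].index.tolist()
    if small:
        logger.warning("dropping categories with < 2 pairs: %s", small)
        df = df[~df["category"].isin(small)]
    groups = [g["distance"].to_numpy() for _, g in df.groupby("category")]
    if len(groups) < 2:
        raise ValueError("need at least two categories for ANOVA")
    f, p = f_oneway(*groups)
    tk = pairwise_tukeyhsd(df["distance"].to_numpy(), df["category"].to_numpy())
    tukey = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    summary = (
        df.groupby("category")["distance"]
        .agg(mean="mean", sem=lambda x: x.std(ddof=1) / np.sqrt(len(x)), n_pairs="count")
        .reset_index()
    )
    return BetaGroupSummary(summary=summary, anova_f=float(f), anova_p=float(p), tukey=tukey)
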