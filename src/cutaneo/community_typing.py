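"""Community typing: PAM clustering, model selection, phenotype association.

Skin communities are clustered on square-root Jensen-Shannon distances
between genus-level relative-abundance profiles with partitioning around
medoids (BUILD initialisation then SWAP to a local optimum, deterministic
with ties broken by lowest sample index). The Calinski-Harabasz index in
its distance-based form selects the number of community types over
k = 2..20; the gap statistic corroborates it against uniform reference
data drawn over the bounding box of the PCoA embedding. The discovered
types ("cutaneotypes") are then tested for association with clinical skin
type by Pearson chi-square, with a lesion-versus-control odds ratio for
membership in the lesion-enriched type.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import chi2_contingency, fisher_exact

from .beta import DistanceMatrix
from .io import RelativeAbundanceTable, SampleMetadata
from .markers import OddsRatioResult, odds_ratio
from .ordination import pcoa

logger = logging.getLogger("cutaneo")


# ---------------------------------------------------------------------------
# PAM
# ---------------------------------------------------------------------------

#: search spaces up to this many medoid sets are solved exactly
_EXACT_PAM_LIMIT = 10_000


def _pam_exact(d: np.ndarray, k: int) -> list:
    """Global optimum over all medoid sets, lexicographic tie-break."""
    n = d.shape[0]
    best_cost, best = np.inf, None
    for meds in itertools.combinations(range(n), k):
        cost = d[:, meds].min(axis=1).sum()
        if cost < best_cost - 1e-12:
            best_cost, best = cost, list(meds)
    return best


def pam(dist: DistanceMatrix, k: int, method: str = "auto") -> tuple[pd.Series, list]:
    """Partitioning around medoids.

    BUILD greedily seeds k medoids; SWAP exchanges (medoid, non-medoid)
    pairs while any exchange lowers the total distance to nearest medoid.
    SWAP can stall in a local optimum that exhaustive search avoids, so
    small search spaces (at most 10,000 candidate medoid sets) are solved
    exactly by default; ``method`` forces either route. Deterministic
    given the input order; all ties break toward the lowest sample index.
    Returns (labels in 1..k indexed by sample id, medoid ids).
    """
    n = dist.n
    if not 2 <= k < n:
        raise ValueError(f"k must satisfy 2 <= k < n (k={k}, n={n})")
    d = dist.data
    if method not in ("auto", "exact", "build-swap"):
        raise ValueError(f"unknown method {method!r}")
    if method == "exact" or (
        method == "auto" and math.comb(n, k) <= _EXACT_PAM_LIMIT
    ):
        medoids = _pam_exact(d, k)
        med_d = d[:, medoids]
        labels = np.argmin(med_d, axis=1) + 1
        return (pd.Series(labels, index=dist.ids, name="cluster"),
                [dist.ids[m] for m in medoids])

    # BUILD: first medoid minimises total distance; then greedily add the
    # point with the largest reduction.
    medoids = [int(np.argmin(d.sum(axis=1)))]
    dn = d[:, medoids[0]].copy()          # distance to nearest medoid
    while len(medoids) < k:
        gains = np.sum(np.maximum(dn[:, None] - d, 0.0), axis=0)
        gains[medoids] = -np.inf
        new = int(np.argmax(gains))
        medoids.append(new)
        dn = np.minimum(dn, d[:, new])

    medoids = sorted(medoids)

    def total_cost(meds: list) -> float:
        return float(d[:, meds].min(axis=1).sum())

    cost = total_cost(medoids)
    improved = True
    while improved:
        improved = False
        best = (0.0, None, None)
        med_d = d[:, medoids]
        nearest_idx = np.argmin(med_d, axis=1)
        dn = med_d[np.arange(n), nearest_idx]
        part = np.partition(med_d, 1, axis=1)
        ds = part[:, 1] if k > 1 else np.full(n, np.inf)   # second nearest
        for mi, m in enumerate(medoids):
            is_m = nearest_idx == mi
            for h in range(n):
                if h in medoids:
                    continue
                dh = d[:, h]
                delta = np.where(
                    is_m,
                    np.minimum(dh, ds) - dn,
                    np.minimum(dh - dn, 0.0),
                ).sum()
                if delta < best[0] - 1e-12:
                    best = (delta, mi, h)
        if best[1] is not None:
            delta, mi, h = best
            medoids[mi] = h
            medoids = sorted(medoids)
            cost += delta
            improved = True

    med_d = d[:, medoids]
    labels = np.argmin(med_d, axis=1) + 1
    return (pd.Series(labels, index=dist.ids, name="cluster"),
            [dist.ids[m] for m in medoids])


def pam_objective(dist: DistanceMatrix, labels: pd.Series, medoids: list) -> float:
    """Total distance of every sample to its cluster medoid."""
    total = 0.0
    for lab, med in zip(sorted(labels.unique()), medoids):
        members = labels.index[labels == lab]
        total += sum(dist.loc(s, med) for s in members)
    return total


# ---------------------------------------------------------------------------
# Calinski-Harabasz (distance form)
# ---------------------------------------------------------------------------

def _within_dispersion(d: np.ndarray, labels: np.ndarray) -> float:
    """W = sum over clusters of (sum of squared within-pair distances)/n_r."""
    w = 0.0
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if len(idx) > 1:
            sub = d[np.ix_(idx, idx)]
            w += float((sub ** 2).sum()) / (2.0 * len(idx))
    return w


def calinski_harabasz(dist: DistanceMatrix, labels: pd.Series) -> float:
    """CH = [B/(k-1)] / [W/(n-k)] from squared pairwise distances.

    W sums, per cluster, the squared within-cluster pairwise distances
    divided by the cluster size; B = T - W with T the same quantity over
    all samples. For Euclidean distances this equals the classical
    centroid-based variance-ratio criterion exactly.
    """
    lab = labels.loc[dist.ids].to_numpy()
    uniq, counts = np.unique(lab, return_counts=True)
    k = len(uniq)
    if k < 2:
        raise ValueError("Calinski-Harabasz requires k >= 2")
    if (counts == 0).any():
        raise ValueError("empty cluster")
    n = dist.n
    d = dist.data
    t = float((d ** 2).sum()) / (2.0 * n)
    w = _within_dispersion(d, lab)
    b = t - w
    return float((b / (k - 1)) / (w / (n - k)))


# ---------------------------------------------------------------------------
# Model selection
# ---------------------------------------------------------------------------

@dataclass
class CommunityTypingResult:
    """Chosen k, labels, medoids and the model-selection evidence."""

    k: int
    labels: pd.Series
    medoids: list
    ch_curve: pd.Series                        # CH(k) over the k range
    weak_structure: bool = False
    gap_curve: pd.DataFrame | None = None      # Gap(k), s_k, log W_k
    gap_k: int | None = None
    contingency: pd.DataFrame | None = None
    chi2: float | None = None
    chi2_p: float | None = None
    association_exact: bool = False
    odds_ratio: "OddsRatioResult | None" = None
    lesion_enriched_cluster: int | None = None


def choose_k(dist: DistanceMatrix, k_range=range(2, 21),
             weak_threshold: float | None = None) -> CommunityTypingResult:
    """PAM at every k; pick the k maximising the CH index (ties -> smaller).

    The full CH curve is returned so callers can refuse to typify data with
    a flat curve; if ``weak_threshold`` is given and max CH falls below it
    the result is flagged ``weak_structure``.
    """
    k_range = [k for k in k_range if 1 < k < dist.n]
    if not k_range:
        raise ValueError("empty k range")
    ch = {}
    fits = {}
    for k in k_range:
        labels, medoids = pam(dist, k)
        fits[k] = (labels, medoids)
        ch[k] = calinski_harabasz(dist, labels)
    curve = pd.Series(ch).sort_index()
    best_k = int(curve.index[np.argmax(curve.to_numpy())])   # argmax -> first = smallest k
    labels, medoids = fits[best_k]
    weak = weak_threshold is not None and curve.max() < weak_threshold
    return CommunityTypingResult(k=best_k, labels=labels, medoids=medoids,
                                 ch_curve=curve, weak_structure=weak)


def _log_w(d: np.ndarray, labels: np.ndarray) -> float:
    w = _within_dispersion(d, labels)
    return float(np.log(max(w, 1e-300)))


def gap_statistic(profiles: RelativeAbundanceTable, k_range=range(1, 11),
                  B_ref: int = 50, seed: int = 0) -> tuple[pd.DataFrame, int]:
    """Gap statistic on sqrt-JSD profiles with a uniform box reference.

    The observed data are embedded by PCoA of their sqrt-JSD distances;
    reference sets are drawn uniformly over the bounding box of that
    embedding and clustered the same way (PAM on Euclidean distances).
    Gap(k) = mean_ref log W*_k - log W_k; the selected k is the smallest k
    with Gap(k) >= Gap(k+1) - s_{k+1}. k = 1 is admissible (no structure).
    """
    if B_ref < 10:
        raise ValueError("B_ref must be >= 10")
    k_range = sorted(k_range)
    X = profiles.data.to_numpy().T
    ids = profiles.sample_ids
    d_obs = squareform(pdist(X, metric="jensenshannon"))
    dm_obs = DistanceMatrix(ids, d_obs, "sqrt-jsd")
    coords = pcoa(dm_obs).coordinates.to_numpy()
    lo, hi = coords.min(axis=0), coords.max(axis=0)
    if np.allclose(lo, hi):
        raise ValueError("degenerate reference box")
    rng = np.random.default_rng(seed)

    def cluster_logw(dm: DistanceMatrix, k: int) -> float:
        if k == 1:
            labels = np.zeros(dm.n, dtype=int)
        else:
            labels = pam(dm, k)[0].to_numpy()
        return _log_w(dm.data, labels)

    log_w = {k: cluster_logw(dm_obs, k) for k in k_range}
    ref_log_w = {k: [] for k in k_range}
    for _ in range(B_ref):
        ref = rng.uniform(lo, hi, size=coords.shape)
        dref = squareform(pdist(ref))
        dm_ref = DistanceMatrix([str(i) for i in range(len(ref))], dref, "euclidean")
        for k in k_range:
            ref_log_w[k].append(cluster_logw(dm_ref, k))
    rows = []
    for k in k_range:
        r = np.asarray(ref_log_w[k])
        gap = float(r.mean() - log_w[k])
        sk = float(r.std(ddof=0) * np.sqrt(1.0 + 1.0 / B_ref))
        rows.append({"k": k, "gap": gap, "s_k": sk, "log_w": log_w[k]})
    curve = pd.DataFrame(rows).set_index("k")
    selected = k_range[-1]
    for k, k_next in zip(k_range[:-1], k_range[1:]):
        if curve.loc[k, "gap"] >= curve.loc[k_next, "gap"] - curve.loc[k_next, "s_k"]:
            selected = k
            break
    return curve, int(selected)


# ---------------------------------------------------------------------------
# Phenotype association
# ---------------------------------------------------------------------------

def cutaneotype_association(labels: pd.Series, metadata: SampleMetadata) -> CommunityTypingResult:
    """Cluster-by-skin-type contingency, chi-square, lesion odds ratio.

    The odds ratio compares membership in the lesion-enriched cluster
    between lesion and control samples (conditional-MLE estimator with
    exact CI, sample OR co-reported). If any expected cell count is < 1
    and the table is 2x2, a Fisher exact test replaces the chi-square.
    """
    types = metadata.data.loc[labels.index, "skin_type"]
    if labels.nunique() < 2 or types.nunique() < 2:
        raise ValueError("association needs >= 2 clusters and >= 2 phenotype levels")
    table = pd.crosstab(labels, types)
    chi2, p, _, expected = chi2_contingency(table)
    exact = False
    if (expected < 1).any():
        if table.shape == (2, 2):
            _, p = fisher_exact(table.to_numpy())
            exact = True
            logger.warning("expected counts < 1; Fisher exact test used")
        else:
            logger.warning("expected counts < 1; chi-square approximation is poor")

    # lesion-enriched cluster: highest fraction of its members lesional
    lesion_frac = {}
    for c in table.index:
        members = labels.index[labels == c]
        lesion_frac[c] = float((types.loc[members] == "lesion").mean())
    enriched = max(sorted(lesion_frac), key=lambda c: lesion_frac[c])

    in_c = labels == enriched
    a = int((in_c & (types == "lesion")).sum())
    b = int((~in_c & (types == "lesion")).sum())
    c_ = int((in_c & (types == "control")).sum())
    d_ = int((~in_c & (types == "control")).sum())
    orr = odds_ratio(a, b, c_, d_)

    return CommunityTypingResult(
        k=int(labels.nunique()), labels=labels, medoids=[],
        ch_curve=pd.Series(dtype=float), contingency=table,
        chi2=float(chi2), chi2_p=float(p), association_exact=exact,
        odds_ratio=orr, lesion_enriched_cluster=int(enriched),
    )


def typify(profiles: RelativeAbundanceTable, metadata: SampleMetadata,
           k_range=range(2, 21), gap: bool = False, B_ref: int = 50,
           seed: int = 0) -> CommunityTypingResult:
    """End-to-end community typing from relative-abundance profiles.

    sqrt-JSD distances -> PAM + CH model selection -> phenotype
    association; the gap statistic is optional corroboration.
    """
    X = profiles.data.to_numpy().T
    d = squareform(pdist(X, metric="jensenshannon"))
    dm = DistanceMatrix(profiles.sample_ids, d, "sqrt-jsd")
    res = choose_k(dm, k_range)
    assoc = cutaneotype_association(res.labels, metadata)
    res.contingency = assoc.contingency
    res.chi2, res.chi2_p = assoc.chi2, assoc.chi2_p
    res.association_exact = assoc.association_exact
    res.odds_ratio = assoc.odds_ratio
    res.lesion_enriched_cluster = assoc.lesion_enriched_cluster
    if gap:
        res.gap_curve, res.gap_k = gap_statistic(
            profiles, k_range=range(1, max(k_range) + 1), B_ref=B_ref, seed=seed)
    return res
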