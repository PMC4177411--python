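"""Alpha diversity: rarefaction, group trends, triplet-relative indices.

Richness (number of observed taxa) and the Shannon index H = -sum p ln p
(natural log by default) are computed on rarefied subsamples drawn without
replacement, the classical rarefaction procedure. The triplet-relative
transform subtracts the control member's index from the lesion and
unaffected members, removing shared environmental variation in matched
designs. The taxa-sharing analysis classifies each taxon by the set of
clinical skin types in which it occurs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import kruskal

from .io import CountTable, SampleMetadata, SKIN_TYPES

logger = logging.getLogger("cutaneo")


def shannon_index(column, base: float | None = None) -> float:
    """Shannon index of one count (or abundance) vector.

    Natural log by default; pass ``base`` for another logarithm base.
    Zero entries contribute nothing; an all-zero vector is an error.
    """
    x = np.asarray(column, dtype=float)
    total = x.sum()
    if total <= 0:
        raise ValueError("Shannon index undefined for an all-zero vector")
    p = x[x > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def richness(column) -> int:
    """Number of taxa with at least one read."""
    return int((np.asarray(column) > 0).sum())


@dataclass
class RarefactionCurve:
    """Mean and SD of a diversity index over subsample replicates.

    ``mean`` and ``sd`` are depth-by-sample frames; entries are NaN where a
    sample's depth is below the rarefaction depth.
    """

    index: str                  # "richness" or "shannon"
    depths: list
    mean: pd.DataFrame
    sd: pd.DataFrame
    reps: int


def rarefaction_curve(table: CountTable, depths, reps: int = 10, seed: int = 0,
                      index: str = "richness") -> RarefactionCurve:
    """Rarefy each sample to each depth ``reps`` times without replacement.

    Subsampling uses the multivariate hypergeometric distribution (drawing
    reads without replacement), so at full depth the subsample is the
    sample itself and observed richness is recovered exactly.
    """
    depths = list(depths)
    if any(d <= 0 for d in depths):
        raise ValueError("rarefaction depths must be positive")
    if sorted(depths) != depths:
        raise ValueError("depths must be sorted ascending")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    stat = {"richness": richness, "shannon": shannon_index}[index]
    rng = np.random.default_rng(seed)
    mean = pd.DataFrame(np.nan, index=depths, columns=table.sample_ids, dtype=float)
    sd = pd.DataFrame(np.nan, index=depths, columns=table.sample_ids, dtype=float)
    for s in table.sample_ids:
        col = table.data[s].to_numpy()
        n = int(col.sum())
        for d in depths:
            if n < d:
                continue
            if n == d:
                vals = [stat(col)] * reps
            else:
                vals = [stat(rng.multivariate_hypergeometric(col, d)) for _ in range(reps)]
            mean.loc[d, s] = float(np.mean(vals))
            sd.loc[d, s] = float(np.std(vals, ddof=1)) if reps > 1 else 0.0
    return RarefactionCurve(index=index, depths=depths, mean=mean, sd=sd, reps=reps)


def group_alpha_trend(curve: RarefactionCurve, metadata: SampleMetadata,
                      depth: int = 2000) -> dict:
    """Per-skin-type mean +/- SEM of the rarefied index at one depth,
    with a Kruskal-Wallis test across skin types.

    Groups with no sample observed at the depth are dropped with a
    warning; groups of a single sample are an error.
    """
    if depth not in curve.depths:
        raise ValueError(f"depth {depth} not on the rarefaction grid {curve.depths}")
    vals = curve.mean.loc[depth]
    types = metadata.data.loc[vals.index, "skin_type"]
    groups, summary = {}, {}
    for t in SKIN_TYPES:
        g = vals[(types == t) & vals.notna()]
        if len(g) == 0:
            logger.warning("group %r has no sample at depth %d; dropped", t, depth)
            continue
        if len(g) == 1:
            raise ValueError(f"group {t!r} has a single sample at depth {depth}; need n >= 2")
        groups[t] = g.to_numpy()
        summary[t] = {
            "mean": float(g.mean()),
            "sem": float(g.std(ddof=1) / np.sqrt(len(g))),
            "n": int(len(g)),
        }
    if len(groups) < 2:
        raise ValueError("need at least two groups at this depth")
    stat, p = kruskal(*groups.values())
    return {"depth": depth, "index": curve.index, "groups": summary,
            "kw_statistic": float(stat), "p_value": float(p)}


def relative_alpha(values: pd.Series, metadata: SampleMetadata) -> pd.Series:
    """Triplet-relative alpha diversity.

    For every complete triplet, subtract the control member's index from
    the lesion and unaffected members. Control members are never emitted
    (their difference is identically zero); incomplete triplets are
    excluded with a warning.
    """
    md = metadata.data.loc[values.index]
    out = {}
    for tid, grp in md.groupby("triplet_id"):
        if sorted(grp["skin_type"]) != sorted(SKIN_TYPES):
            logger.warning("triplet %r incomplete; excluded from relative alpha", tid)
            continue
        by_type = pd.Series(grp.index.to_numpy(), index=grp["skin_type"].to_numpy())
        ctrl = values[by_type["control"]]
        for t in ("unaffected", "lesion"):
            sid = by_type[t]
            out[sid] = float(values[sid] - ctrl)
    return pd.Series(out, name="relative_" + (values.name or "alpha"))


def taxa_sharing(table: CountTable, metadata: SampleMetadata,
                 min_samples: int = 3) -> dict:
    """Classify taxa by the set of skin types where they occur.

    Presence means at least one read. Taxa present in fewer than
    ``min_samples`` samples overall are excluded. Returns the counts of
    taxa unique to one skin type, shared by two, and shared by all three,
    plus the per-taxon classification.
    """
    pres = table.data > 0
    keep = pres.sum(axis=1) >= min_samples
    types = metadata.data.loc[table.sample_ids, "skin_type"]
    classification = {}
    for taxon in table.data.index[keep]:
        where = frozenset(types[pres.loc[taxon]].unique())
        classification[taxon] = where
    counts = {1: 0, 2: 0, 3: 0}
    for where in classification.values():
        counts[len(where)] += 1
    return {
        "n_excluded": int((~keep).sum()),
        "counts": counts,
        "classification": {t: sorted(w) for t, w in classification.items()},
    }
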