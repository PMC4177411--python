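"""Principal coordinates analysis with Cailliez correction.

UniFrac dissimilarities are generally non-Euclidean, so their Gower-centred
matrix has negative eigenvalues. The Cailliez correction adds the smallest
constant c to every off-diagonal dissimilarity such that the corrected
matrix embeds exactly in Euclidean space; c is the largest eigenvalue of
the standard 2n x 2n companion problem. PCoA then eigendecomposes the
Gower-centred matrix of -1/2 d^2 and scales eigenvectors by sqrt(lambda).
Variance explained is reported over positive eigenvalues only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f_oneway
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .beta import DistanceMatrix
from .io import SampleMetadata

#: negative eigenvalues within this fraction of the largest are clamped to 0
_EIG_TOL = 1e-8


def gower_center(d_squared: np.ndarray) -> np.ndarray:
    """Double-centred Gower matrix G = -1/2 J D2 J with J = I - 11'/n."""
    n = d_squared.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ d_squared @ j


def cailliez_correct(dist: DistanceMatrix) -> tuple[DistanceMatrix, float]:
    """Smallest additive constant making a dissimilarity Euclidean.

    Returns the corrected matrix (d + c off-diagonal) and c. c is the
    largest real eigenvalue of the 2n x 2n block matrix built from the
    Gower-centred forms of -1/2 d^2 and -1/2 d; it is 0 (up to numerical
    noise) when the input is already Euclidean-embeddable.
    """
    n = dist.n
    if n < 3:
        raise ValueError("Cailliez correction needs at least 3 samples")
    d = dist.data
    delta1 = gower_center(d ** 2)
    delta2 = gower_center(d)
    zero = np.zeros((n, n))
    eye = np.eye(n)
    block = np.block([[zero, 2.0 * delta1], [-eye, -4.0 * delta2]])
    eigvals = np.linalg.eigvals(block)
    c = float(np.max(eigvals.real))
    # eigenvalues of the companion problem carry O(1e-8) numerical noise;
    # an already-Euclidean input gets c = 0 exactly
    if c < 1e-7 * max(1.0, float(d.max())):
        return DistanceMatrix(dist.ids, d.copy(), dist.metric), 0.0
    corrected = d + c
    np.fill_diagonal(corrected, 0.0)
    return DistanceMatrix(dist.ids, corrected, "other"), c


@dataclass
class OrdinationResult:
    """PCoA embedding: coordinates, eigenvalues, variance explained."""

    coordinates: pd.DataFrame       # samples x axes (PC1, PC2, ...)
    eigenvalues: np.ndarray         # descending, all of them
    proportion_explained: np.ndarray  # over positive eigenvalues
    cailliez_constant: float = 0.0


def pcoa(dist: DistanceMatrix, n_axes: int | None = None,
         cailliez: bool = False) -> OrdinationResult:
    """Classical metric multidimensional scaling of a distance matrix.

    Axes with non-positive eigenvalues are dropped from the coordinates;
    small negative eigenvalues (within 1e-8 of the largest, relatively)
    are clamped to zero. With ``cailliez=True`` the correction is applied
    first and the constant recorded.
    """
    c = 0.0
    if cailliez:
        dist, c = cailliez_correct(dist)
    d = dist.data
    if np.allclose(d, 0.0):
        g = np.zeros_like(d)
    else:
        g = gower_center(d ** 2)
    eigvals, eigvecs = np.linalg.eigh((g + g.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    if eigvals.size and eigvals[0] > 0:
        eigvals[(eigvals < 0) & (eigvals > -_EIG_TOL * eigvals[0])] = 0.0
    pos = eigvals > 0
    if not pos.any():
        if np.allclose(d, 0.0):
            coords = pd.DataFrame(index=dist.ids)
            return OrdinationResult(coords, eigvals, np.array([]), c)
        raise ValueError("degenerate distance matrix: no positive eigenvalues")
    lam = eigvals[pos]
    coords = eigvecs[:, pos] * np.sqrt(lam)
    if n_axes is not None:
        coords = coords[:, :n_axes]
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    prop = lam / lam.sum()
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=dist.ids, columns=cols),
        eigenvalues=eigvals,
        proportion_explained=prop,
        cailliez_constant=c,
    )


def axis_group_test(ordination: OrdinationResult, metadata: SampleMetadata,
                    axes=(1, 2)) -> dict:
    """One-way ANOVA of PCoA coordinates by skin type, per axis, with
    Tukey HSD adjusted pairwise comparisons."""
    results = {}
    types = metadata.data.loc[ordination.coordinates.index, "skin_type"]
    if types.nunique() < 2:
        raise ValueError("axis group test needs at least two skin types")
    for ax in axes:
        col = f"PC{ax}"
        if col not in ordination.coordinates.columns:
            raise ValueError(f"axis {col} not present in the ordination")
        vals = ordination.coordinates[col]
        if np.isclose(vals.std(ddof=0), 0.0):
            raise ValueError(f"axis {col} has constant coordinates; ANOVA undefined")
        groups = [vals[types == t].to_numpy() for t in types.unique()]
        f, p = f_oneway(*groups)
        tk = pairwise_tukeyhsd(vals.to_numpy(), types.to_numpy())
        tukey = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
        results[col] = {"anova_f": float(f), "anova_p": float(p), "tukey": tukey}
    return results
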