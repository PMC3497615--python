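"""Sample clustering on imprinting-inclined SNP posteriors.

Per-sample posteriors (each sample scored on its own, so a SNP gets one
posterior per sample) are transformed with v = max(0, ln(100 * posterior)).
The transform zeroes every posterior at or below the prior (0.01) —
ln(100 * 0.01) = 0 — so only SNPs showing an *increased* probability of
imprinting in at least one sample contribute; all-zero rows are removed.
Samples are then compared by Spearman rank correlation, converted to a
distance, and clustered agglomeratively with average linkage.
"""

from __future__ import annotations

import warnings
from typing import Literal

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr
from skbio.tree import TreeNode

__all__ = ["transform_posteriors", "cluster_samples"]


def transform_posteriors(posteriors: pd.DataFrame) -> pd.DataFrame:
    """Transform a SNP x sample posterior matrix for clustering.

    Values become ``max(0, ln(100 * posterior))`` and rows that are zero
    in every sample are dropped.
    """
    arr = posteriors.to_numpy(dtype=float)
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("posteriors must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        v = np.log(100.0 * arr)
    v = np.maximum(v, 0.0)
    out = pd.DataFrame(v, index=posteriors.index, columns=posteriors.columns)
    return out.loc[(out != 0).any(axis=1)]


def cluster_samples(
    matrix: pd.DataFrame,
    distance: Literal["one_minus", "half_one_minus"] = "one_minus",
) -> tuple[TreeNode, pd.DataFrame]:
    """Average-linkage clustering of samples by Spearman correlation.

    Returns the dendrogram as a tree (exportable to Newick via
    ``tree.write``) and the full pairwise correlation table.  Samples
    with zero variance across retained SNPs have undefined rank
    correlations; their correlations are reported as NA and they are
    excluded from the tree with a warning.
    """
    if matrix.shape[1] < 2 or matrix.shape[0] < 2:
        raise ValueError("need at least 2 samples and 2 retained SNPs")
    labels = list(matrix.columns)
    arr = matrix.to_numpy(dtype=float)
    variances = arr.var(axis=0)
    constant = [lab for lab, v in zip(labels, variances) if v == 0.0]
    corr = pd.DataFrame(np.nan, index=labels, columns=labels, dtype=float)
    usable = [lab for lab in labels if lab not in constant]
    if len(usable) < 2:
        raise ValueError("fewer than 2 samples with nonzero variance")
    if constant:
        warnings.warn(
            "constant samples excluded from clustering: " + ", ".join(constant),
            stacklevel=2,
        )
    sub = matrix[usable].to_numpy(dtype=float)
    rho = spearmanr(sub, axis=0).statistic
    rho = np.atleast_2d(rho) if np.ndim(rho) == 0 else np.asarray(rho)
    if rho.shape != (len(usable), len(usable)):  # spearmanr collapses 2-sample case
        r = float(rho) if rho.size == 1 else float(rho[0, 1])
        rho = np.array([[1.0, r], [r, 1.0]])
    corr.loc[usable, usable] = rho
    dist = 1.0 - rho if distance == "one_minus" else (1.0 - rho) / 2.0
    np.fill_diagonal(dist, 0.0)
    linkage = average(squareform(dist, checks=False))
    tree = TreeNode.from_linkage_matrix(linkage, usable)
    return tree, corr
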