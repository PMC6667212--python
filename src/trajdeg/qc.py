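"""Replicate-quality diagnostics: distances, PCA, and outlier flagging.

QC never mutates counts; it reports.  Excluding a flagged sample from the
analysis is an explicit configuration decision, keeping runs auditable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .data import CountMatrix

__all__ = ["sample_distances", "pca_scores", "flag_outlier_samples"]


def sample_distances(transformed: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Euclidean distances between samples over genes."""
    mat = transformed.to_numpy(dtype=float).T  # samples x genes
    if np.isnan(mat).any():
        raise ValueError("transformed matrix contains missing values")
    d = squareform(pdist(mat, metric="euclidean"))
    return pd.DataFrame(d, index=transformed.columns, columns=transformed.columns)


def pca_scores(transformed: pd.DataFrame, n_components: int = 2):
    """Principal-component scores of samples with variance fractions.

    Genes are centred, the SVD is taken over samples, and each component's
    sign is fixed so that its largest-magnitude gene loading is positive.

    Returns
    -------
    (scores, variance_fractions) : scores is a samples x components
    DataFrame; variance fractions are each component's share of the total
    variance (non-increasing).
    """
    n_samples = transformed.shape[1]
    if n_samples < 2:
        raise ValueError("PCA needs at least two samples")
    if n_components > n_samples - 1:
        raise ValueError(
            f"n_components={n_components} exceeds samples-1={n_samples - 1}"
        )
    x = transformed.to_numpy(dtype=float).T  # samples x genes
    x = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # deterministic sign: largest |loading| positive per component
    for i in range(len(s)):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] *= -1
            u[:, i] *= -1
    total = np.square(s).sum()
    var_frac = np.square(s) / total if total > 0 else np.zeros_like(s)
    scores = pd.DataFrame(
        (u * s)[:, :n_components],
        index=transformed.columns,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return scores, var_frac[:n_components]


def flag_outlier_samples(distances: pd.DataFrame, samples: pd.DataFrame,
                         multiple: float = 2.0) -> list:
    """Flag replicates far from their stage-mates.

    Within each (tissue, stage) group of at least three replicates, a
    sample is flagged when its median distance to the other replicates
    exceeds ``multiple`` times the group's median of those medians.
    Advisory only; flags are invariant to gene and sample order.
    """
    flags = []
    for (_, _), group in samples.groupby(["tissue", "stage"]):
        ids = [s for s in group.index if s in distances.index]
        if len(ids) < 3:
            continue
        med = {}
        for s in ids:
            others = [o for o in ids if o != s]
            med[s] = float(np.median(distances.loc[s, others]))
        group_median = float(np.median(list(med.values())))
        for s in ids:
            if med[s] > multiple * group_median:
                flags.append(s)
    return sorted(flags)
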