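"""Between-sample normalization and count transforms.

Two scaling methods are provided, mirroring the conventions of the
negative-binomial DE literature:

* TMM — trimmed mean of M-values against a reference sample.  The factor
  here is defined on raw counts, so it absorbs both sequencing depth and
  composition bias: normalized counts are simply ``counts / factor`` (the
  factors are rescaled to geometric mean 1).
* RLE — relative log expression (median-of-ratios) size factors.

Plus a variance-stabilising "regularized log"-style transform used by QC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import CountMatrix

__all__ = [
    "NormalizationFactors",
    "filter_low_counts",
    "tmm_factors",
    "rle_size_factors",
    "rlog_like",
]


@dataclass
class NormalizationFactors:
    """Per-sample positive scaling factors with a method tag."""

    factors: pd.Series
    method: str

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValueError("normalization factors must be positive")

    def normalized(self, cm: CountMatrix) -> pd.DataFrame:
        """Counts divided by the per-sample factor."""
        return cm.counts / self.factors[cm.counts.columns]

    def effective_lib_sizes(self, cm: CountMatrix) -> pd.Series:
        """Factors mapped onto the count-total scale.

        Factors carry depth information relative to the matrix average, so
        the effective library size is factor x geometric mean of the column
        totals.
        """
        totals = cm.counts.sum(axis=0).astype(float)
        gmean = np.exp(np.log(totals).mean())
        return self.factors[cm.counts.columns] * gmean


def filter_low_counts(cm: CountMatrix, min_count: int = 1) -> CountMatrix:
    """Drop genes whose count never reaches ``min_count`` in any sample."""
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    if min_count == 0:
        return cm
    keep = cm.counts.max(axis=1) >= min_count
    return cm.subset_genes(cm.counts.index[keep])


def _trim_mask(values: np.ndarray, lo_frac: float, hi_frac: float) -> np.ndarray:
    """Boolean mask keeping the central ranks of ``values``."""
    n = len(values)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    lo = int(np.floor(n * lo_frac))
    hi = n - int(np.floor(n * hi_frac))
    return (ranks >= lo) & (ranks < hi)


def tmm_factors(cm: CountMatrix, trim_m: float = 0.3, trim_a: float = 0.05
                ) -> NormalizationFactors:
    """Trimmed-mean-of-M-values scaling factors.

    The reference sample is the one whose upper-quartile count fraction is
    closest to the mean upper quartile.  For each other sample, M (log2
    count ratio to the reference) and A (average log2 abundance) are
    computed over genes expressed in both samples, the extreme 30 percent
    of M-values and 5 percent of A-values (each tail) are trimmed, and the
    factor is 2 to the inverse-variance-weighted mean of the remaining
    M-values.  Factors are rescaled to geometric mean 1.
    """
    x = cm.counts.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    totals = x.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("every sample needs a positive total count")
    uq = np.array([np.quantile(x[:, j] / totals[j], 0.75) for j in range(x.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    log_factors = np.zeros(x.shape[1])
    for j in range(x.shape[1]):
        if j == ref:
            continue
        both = (x[:, j] > 0) & (x[:, ref] > 0)
        if not both.any():
            raise ValueError(
                f"sample {cm.sample_ids[j]!r} shares no expressed gene with the "
                f"reference {cm.sample_ids[ref]!r}"
            )
        xs, xr = x[both, j], x[both, ref]
        m = np.log2(xs / xr)
        a = 0.5 * np.log2(xs * xr)
        # asymptotic inverse variance of M
        w = 1.0 / ((totals[j] - xs) / (totals[j] * xs)
                   + (totals[ref] - xr) / (totals[ref] * xr))
        keep = _trim_mask(m, trim_m, trim_m) & _trim_mask(a, trim_a, trim_a)
        if not keep.any():
            keep = np.ones(len(m), dtype=bool)
        log_factors[j] = np.average(m[keep], weights=w[keep])

    log_factors -= log_factors.mean()  # geometric mean 1
    return NormalizationFactors(
        factors=pd.Series(np.exp2(log_factors), index=cm.counts.columns),
        method="TMM",
    )


def rle_size_factors(cm: CountMatrix) -> NormalizationFactors:
    """Median-of-ratios size factors (relative log expression)."""
    x = cm.counts.to_numpy(dtype=float)
    everywhere = (x > 0).all(axis=1)
    if not everywhere.any():
        raise ValueError(
            "no gene has positive counts in all samples; filter or subset first"
        )
    sub = x[everywhere]
    gmean = np.exp(np.log(sub).mean(axis=1, keepdims=True))
    sf = np.median(sub / gmean, axis=0)
    return NormalizationFactors(
        factors=pd.Series(sf, index=cm.counts.columns), method="RLE"
    )


def rlog_like(cm: CountMatrix, shrink_strength: float = 10.0) -> pd.DataFrame:
    """Shrunken log2 transform for QC.

    log2(normalized count + 1) with each gene's per-sample values pulled
    toward the gene mean; the pull weight ``k / (k + mean count)`` grows as
    the gene's mean count shrinks, so low-count genes are stabilised while
    high-count genes converge to the plain log transform.
    """
    sf = rle_size_factors(cm)
    norm = sf.normalized(cm)
    logn = np.log2(norm + 1.0)
    gene_mean_log = logn.mean(axis=1)
    mean_count = norm.mean(axis=1)
    w = shrink_strength / (shrink_strength + mean_count)
    return logn.mul(1.0 - w, axis=0).add(gene_mean_log * w, axis=0)
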