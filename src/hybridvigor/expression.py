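"""FPKM normalization, expressed-feature filters, and PCA of transformed counts.

FPKM (fragments per kilobase of feature per million mapped fragments):

    fpkm[g, s] = counts[g, s] / ((length_g / 1e3) * (library_size_s / 1e6))

Library sizes default to column sums of the count matrix and can be
overridden with externally known mapped-fragment totals.

Two expression filters are provided: *expressed* (FPKM > 0 in at least one
sample) and *tissue-expressed* (FPKM > 0 in strictly more than 30% of the
samples of a tissue).

For global pattern checks, counts are median-of-ratios normalized and
log2(x + 1) transformed, then fed to a PCA over samples; per-group 95%
confidence ellipses come from the group covariance of the scores scaled by
the chi-square(2 df) quantile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .diffexpr import size_factors


def fpkm(
    counts: pd.DataFrame,
    lengths: pd.Series,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """FPKM matrix from counts (features × samples) and feature lengths (bp)."""
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        raise ValueError("every feature needs a length")
    if (lengths <= 0).any():
        raise ValueError("feature lengths must be positive")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    library_sizes = library_sizes.reindex(counts.columns)
    if (library_sizes <= 0).any() or library_sizes.isna().any():
        raise ValueError("library sizes must be positive for every sample")
    denom = np.outer(lengths / 1e3, library_sizes / 1e6)
    return pd.DataFrame(counts.to_numpy(float) / denom, index=counts.index, columns=counts.columns)


def expressed_filter(
    fpkm_matrix: pd.DataFrame,
    mode: str = "any_sample",
    sample_subset=None,
    tissue_fraction: float = 0.30,
) -> pd.Series:
    """Boolean mask of features passing the expression filter.

    ``any_sample``: FPKM > 0 somewhere. ``tissue_30pct``: FPKM > 0 in a
    fraction of ``sample_subset`` strictly greater than ``tissue_fraction``
    (so exactly 30% of samples fails the default filter).
    """
    cols = list(fpkm_matrix.columns) if sample_subset is None else list(sample_subset)
    if not cols:
        raise ValueError("empty sample subset")
    sub = fpkm_matrix[cols]
    if mode == "any_sample":
        return sub.gt(0).any(axis=1)
    if mode == "tissue_30pct":
        return sub.gt(0).mean(axis=1) > tissue_fraction
    raise ValueError(f"unknown filter mode {mode!r}")


@dataclass
class PcaResult:
    coordinates: pd.DataFrame          # samples × components
    variance_explained: np.ndarray     # fraction per component
    ellipses: dict                     # group -> dict(center, cov, scale)


def transform_and_pca(
    counts: pd.DataFrame,
    groups: pd.Series | None = None,
    n_components: int = 2,
    confidence: float = 0.95,
) -> PcaResult:
    """PCA of log2(median-of-ratios-normalized counts + 1), over samples.

    The transform is a shrinkage-free stand-in for a regularized-log
    transform; it stabilizes the count scale enough for global structure
    checks. Features are centered; samples are the observations.
    """
    if counts.shape[1] < 3 or counts.shape[0] < 2:
        raise ValueError("need at least 3 samples and 2 features")
    if not counts.to_numpy().any():
        raise ValueError("all-zero count matrix")
    sf = size_factors(counts)
    x = np.log2(counts.to_numpy(float) / sf.to_numpy() + 1.0)
    x = (x - x.mean(axis=1, keepdims=True)).T  # samples × features, centered per feature
    k = min(n_components, min(x.shape) - 1) if min(x.shape) > 1 else 1
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(x)
    coord_df = pd.DataFrame(
        coords, index=counts.columns, columns=[f"PC{i + 1}" for i in range(k)]
    )
    ellipses = {}
    if groups is not None and k >= 2:
        scale = stats.chi2.ppf(confidence, df=2)
        for g, idx in coord_df.groupby(groups.reindex(coord_df.index)).groups.items():
            pts = coord_df.loc[idx, ["PC1", "PC2"]].to_numpy()
            if len(pts) >= 3:
                ellipses[g] = {
                    "center": pts.mean(axis=0),
                    "cov": np.cov(pts, rowvar=False),
                    "scale": scale,
                }
    return PcaResult(coord_df, pca.explained_variance_ratio_, ellipses)
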