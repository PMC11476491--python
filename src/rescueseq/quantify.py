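"""Normalization, FPKM, and sample-level QC on a count matrix.

Size factors use median-of-ratios normalization (each sample's median ratio
to the per-gene geometric mean, over genes expressed in every sample),
rescaled to geometric mean 1.  FPKM divides counts by gene length in kb and
the sample's total counted fragments in millions.  QC is Pearson correlation
of log2(FPKM+1) between samples and PCA of the centred log expression.
"""

from __future__ import annotations

import warnings
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .io import CountMatrix


def size_factors(
    counts: CountMatrix | pd.DataFrame,
    total_count_fallback: bool = False,
    rescale: bool = True,
) -> pd.Series:
    """Median-of-ratios size factor per sample.

    Only genes with a positive count in *every* sample enter the median.  If
    no such gene exists, an error instructs the caller to filter or pass
    ``total_count_fallback=True`` to use library-size ratios instead.
    With ``rescale`` the factors are divided by their geometric mean.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    values = df.to_numpy(dtype=float)
    expressed = (values > 0).all(axis=1)
    if not expressed.any():
        if total_count_fallback:
            totals = values.sum(axis=0)
            factors = totals / np.exp(np.mean(np.log(totals)))
            return pd.Series(factors, index=df.columns, name="size_factor")
        raise ValueError(
            "no gene has positive counts in every sample; filter the matrix "
            "or pass total_count_fallback=True"
        )
    sub = values[expressed]
    log_geo_mean = np.mean(np.log(sub), axis=1)
    ratios = np.log(sub) - log_geo_mean[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    if rescale:
        factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=df.columns, name="size_factor")


def fpkm(counts: CountMatrix) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million counted fragments.

    FPKM_gj = count_gj / (length_g[kb] * total_j[millions]); the per-sample
    total is the column sum of the matrix itself.
    """
    if counts.gene_lengths is None:
        raise ValueError("gene lengths required for FPKM")
    lengths = counts.gene_lengths.reindex(counts.gene_ids)
    bad = lengths.index[~(lengths > 0) | lengths.isna()].tolist()
    if bad:
        raise ValueError(f"missing or non-positive gene lengths: {bad[:10]}")
    values = counts.counts.to_numpy(dtype=float)
    totals = values.sum(axis=0)
    out = values * 1e9 / (lengths.to_numpy()[:, None] * totals[None, :])
    return pd.DataFrame(out, index=counts.gene_ids, columns=counts.sample_ids)


def replicate_correlation(expr: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation of log2(expr + 1) between samples."""
    if expr.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    log_expr = np.log2(expr + 1.0)
    sds = log_expr.std(axis=0)
    flat = sds.index[sds == 0].tolist()
    if flat:
        warnings.warn(f"zero-variance samples, correlation undefined: {flat}")
    return log_expr.corr(method="pearson")


class PCAResult(NamedTuple):
    scores: pd.DataFrame          # samples x components
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame        # genes x components


def pca_coordinates(
    expr: pd.DataFrame,
    gene_subset: Sequence[str],
    n_components: int | None = None,
) -> PCAResult:
    """Sample scores on the leading principal components of log expression.

    Works on centred log2(expr+1) restricted to ``gene_subset``.  Component
    signs are canonicalized so each component's largest-magnitude loading is
    positive, making the output reproducible across SVD implementations.
    """
    gene_subset = [g for g in gene_subset if g in expr.index]
    if len(gene_subset) < 2:
        raise ValueError("need at least 2 genes for PCA")
    X = np.log2(expr.loc[gene_subset] + 1.0).to_numpy().T  # samples x genes
    X = X - X.mean(axis=0, keepdims=True)
    n_samples = X.shape[0]
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    max_rank = min(n_samples - 1, len(gene_subset))
    k = max_rank if n_components is None else min(n_components, max_rank)
    U, s, Vt = U[:, :k], s[:k], Vt[:k]
    # canonical signs: largest-|loading| entry of each component positive
    for c in range(k):
        idx = np.argmax(np.abs(Vt[c]))
        if Vt[c, idx] < 0:
            Vt[c] *= -1.0
            U[:, c] *= -1.0
    scores = U * s
    var = s**2 / (n_samples - 1)
    total_var = X.var(axis=0, ddof=1).sum()
    comps = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=expr.columns, columns=comps),
        explained_variance=var,
        explained_variance_ratio=var / total_var if total_var > 0 else np.zeros(k),
        loadings=pd.DataFrame(Vt.T, index=gene_subset, columns=comps),
    )
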