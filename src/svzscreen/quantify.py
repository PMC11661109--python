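"""Expression quantification and laminar QC: FPKM, shifted-log transform, PCA."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .data import CountMatrix


def compute_fpkm(counts: pd.DataFrame | CountMatrix, lengths: pd.Series) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped reads.

    fpkm[g, j] = counts[g, j] * 1e9 / (total_j * length_bp[g]), with total_j
    the raw column total (not size-factored).
    """
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    missing = counts.index.difference(lengths.index)
    if len(missing):
        raise ValueError(f"no length for gene {missing[0]!r}")
    totals = counts.sum(axis=0).astype(float)
    zero = totals.index[totals <= 0]
    if len(zero):
        raise ValueError(f"sample {zero[0]!r} has zero total counts")
    lens = lengths.loc[counts.index].to_numpy(float)
    fpkm = counts.to_numpy(float) * 1e9 / (totals.to_numpy()[None, :] * lens[:, None])
    return pd.DataFrame(fpkm, index=counts.index, columns=counts.columns)


def log_transform(
    counts: pd.DataFrame | CountMatrix,
    size_factors: pd.Series,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Shifted log2 of normalized counts: log2(c/s + pseudocount).

    A simple variance-stabilizing transform feeding clustering/PCA QC only.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    sf = size_factors.loc[counts.columns].to_numpy(float)
    return pd.DataFrame(
        np.log2(counts.to_numpy(float) / sf[None, :] + pseudocount),
        index=counts.index,
        columns=counts.columns,
    )


@dataclass
class LaminarEmbedding:
    """Per-sample principal-component scores plus explained variance."""

    scores: pd.DataFrame  # samples x components
    explained_variance_ratio: np.ndarray


def laminar_pca(
    transformed: pd.DataFrame, top_n_variable_genes: int = 500, k: int = 2
) -> LaminarEmbedding:
    """Centered PCA of samples on the most variable genes.

    Component signs are fixed by forcing the largest-magnitude gene loading
    of each component positive, so the embedding is deterministic.
    """
    n_genes, n_samples = transformed.shape
    if k > min(n_genes, n_samples):
        raise ValueError(f"k={k} exceeds min(genes, samples)={min(n_genes, n_samples)}")
    variances = transformed.var(axis=1)
    top = variances.sort_values(ascending=False, kind="mergesort").index[
        : min(top_n_variable_genes, n_genes)
    ]
    x = transformed.loc[top].to_numpy(float).T  # samples x genes
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(x)
    loadings = pca.components_
    for i in range(k):
        j = np.argmax(np.abs(loadings[i]))
        if loadings[i, j] < 0:
            loadings[i] *= -1
            scores[:, i] *= -1
    return LaminarEmbedding(
        scores=pd.DataFrame(
            scores,
            index=transformed.columns,
            columns=[f"PC{i + 1}" for i in range(k)],
        ),
        explained_variance_ratio=pca.explained_variance_ratio_,
    )


def layer_mean_fpkm(fpkm: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic replicate-mean FPKM per (layer) cell of one species.

    Returns genes x layers, used by the screen's absolute-expression gates.
    """
    out = {}
    for layer, sub in samples.groupby("layer"):
        out[layer] = fpkm[list(sub.index)].mean(axis=1)
    return pd.DataFrame(out)
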