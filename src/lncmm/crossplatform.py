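"""Cross-platform validation of an RNA-seq signature on an array matrix.

Given a differential signature derived from sequencing counts and an
independently normalized expression matrix (array-style), this module
matches genes and samples across platforms, quantifies per-gene agreement
(Pearson r of log2(FPKM+1) vs the array values), and re-runs the
unsupervised clustering + subgroup-association analysis on the
signature-restricted array matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .unsup import AssociationReport, associate_features, hclust_pearson

__all__ = ["PlatformPairing", "match_platforms", "validate_clustering"]


@dataclass
class PlatformPairing:
    """Genes shared by the two platforms with their cross-platform agreement."""

    shared_genes: list[str]
    shared_samples: list[str]
    per_gene_r: pd.Series
    signature_used: list[str]

    @property
    def median_r(self) -> float:
        return float(self.per_gene_r.median())


def match_platforms(
    seq_expr: pd.DataFrame,
    array_expr: pd.DataFrame,
    signature: Sequence[str],
) -> PlatformPairing:
    """Pair the platforms on signature genes and shared samples.

    *seq_expr* should already be on the log2(FPKM+1) scale; the array matrix
    is taken as given.  Per-gene Pearson r is computed across the shared
    samples.  Genes constant on either platform get r = NaN.
    """
    if seq_expr.empty or array_expr.empty:
        raise ValueError("expression tables must be nonempty")
    shared_samples = [s for s in seq_expr.columns if s in set(array_expr.columns)]
    if not shared_samples:
        raise ValueError("no shared samples between the platforms")
    sig = list(dict.fromkeys(signature))
    shared_genes = [
        g for g in sig if g in seq_expr.index and g in array_expr.index
    ]
    if not shared_genes:
        raise ValueError("no signature gene is present on both platforms")
    x = seq_expr.loc[shared_genes, shared_samples].to_numpy(dtype=float)
    y = array_expr.loc[shared_genes, shared_samples].to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (xc * yc).sum(axis=1) / denom, np.nan)
    return PlatformPairing(
        shared_genes=shared_genes,
        shared_samples=shared_samples,
        per_gene_r=pd.Series(r, index=shared_genes, name="r"),
        signature_used=sig,
    )


def validate_clustering(
    array_expr: pd.DataFrame,
    signature: Sequence[str],
    features: pd.DataFrame,
    k: int | None = None,
    linkage: str = "average",
) -> AssociationReport:
    """Cluster the samples on the signature-restricted array matrix and test
    the association of the dendrogram with the molecular features.

    *features* is samples x features with "positive"/"negative"/"NA" values;
    *k* defaults to the number of features plus one (one branch per
    molecular class plus the remainder).
    """
    genes = [g for g in dict.fromkeys(signature) if g in array_expr.index]
    if not genes:
        raise ValueError("signature and array matrix share no genes")
    sub = array_expr.loc[genes, [s for s in array_expr.columns if s in features.index]]
    dendro = hclust_pearson(sub, linkage=linkage)
    if k is None:
        k = min(features.shape[1] + 1, dendro.n_leaves)
    return associate_features(dendro, features.loc[sub.columns], k)
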