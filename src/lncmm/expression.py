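"""Count-matrix loading, detectability filtering, FPKM and descriptive summaries.

A :class:`CountMatrix` wraps a genes x samples pandas DataFrame of
non-negative integer fragment counts (featureCounts-style) together with
per-gene lengths needed for FPKM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "ExpressionSummary",
    "load_counts",
    "load_gene_lengths",
    "filter_expressed",
    "fpkm",
    "log_fpkm",
    "summarize",
]


@dataclass
class CountMatrix:
    """Genes x samples fragment counts with optional per-gene lengths (bp)."""

    counts: pd.DataFrame
    gene_lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.duplicated().any():
            dup = c.index[c.index.duplicated()][0]
            raise ValueError(f"duplicate gene id: {dup!r}")
        if c.columns.duplicated().any():
            dup = c.columns[c.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        vals = c.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValueError("counts must be numeric")
        if (vals < 0).any():
            g, s = np.argwhere(vals < 0)[0]
            raise ValueError(
                f"negative count at gene {c.index[g]!r}, sample {c.columns[s]!r}"
            )
        if not np.allclose(vals, np.round(vals)):
            g, s = np.argwhere(~np.isclose(vals, np.round(vals)))[0]
            raise ValueError(
                f"non-integer count at gene {c.index[g]!r}, sample {c.columns[s]!r}"
            )
        self.counts = c.astype(np.int64)
        if self.gene_lengths is not None:
            self.gene_lengths = self.gene_lengths.reindex(self.counts.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_genes(self, gene_ids: Sequence[str]) -> "CountMatrix":
        keep = [g for g in gene_ids if g in self.counts.index]
        lengths = None
        if self.gene_lengths is not None:
            lengths = self.gene_lengths.loc[keep]
        return CountMatrix(self.counts.loc[keep], lengths)

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="gene_id")


@dataclass
class ExpressionSummary:
    """Descriptive statistics of a count matrix."""

    per_gene_total: pd.Series
    per_gene_mean: pd.Series
    median_total: float
    frac_mean_lt: dict[float, float] = field(default_factory=dict)
    n_high: dict[float, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_genes": int(len(self.per_gene_total)),
            "total_min": int(self.per_gene_total.min()),
            "total_max": int(self.per_gene_total.max()),
            "median_total": float(self.median_total),
            "frac_mean_lt": {str(k): v for k, v in self.frac_mean_lt.items()},
            "n_high": {str(k): v for k, v in self.n_high.items()},
        }


def load_counts(path: str | Path, lengths_path: str | Path | None = None) -> CountMatrix:
    """Load a TSV count matrix (first column gene ids, header sample ids).

    Validation (integrality, non-negativity, unique ids) happens in the
    :class:`CountMatrix` constructor.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    df.columns.name = None
    lengths = load_gene_lengths(lengths_path) if lengths_path is not None else None
    return CountMatrix(df, lengths)


def load_gene_lengths(path: str | Path) -> pd.Series:
    """Sidecar TSV gene_id -> length in bp (no header required)."""
    df = pd.read_csv(path, sep="\t", index_col=0, header=None)
    first = df.iloc[:, 0]
    if isinstance(first.iloc[0], str):  # had a header line after all
        df = pd.read_csv(path, sep="\t", index_col=0)
        first = df.iloc[:, 0]
    s = first.astype(float)
    s.name = "length"
    return s


def filter_expressed(m: CountMatrix) -> CountMatrix:
    """Keep exactly the genes with a positive total count over all samples."""
    totals = m.counts.sum(axis=1)
    keep = totals[totals > 0].index
    if len(keep) == 0:
        raise ValueError("all genes are unexpressed across the dataset")
    lengths = m.gene_lengths.loc[keep] if m.gene_lengths is not None else None
    return CountMatrix(m.counts.loc[keep], lengths)


def fpkm(m: CountMatrix) -> pd.DataFrame:
    """Fragments per kilobase of gene per million mapped fragments.

    FPKM[g, s] = counts[g, s] * 1e9 / (length[g] * total_counts[s]).
    """
    if m.gene_lengths is None:
        raise ValueError("gene lengths are required for FPKM")
    if m.gene_lengths.isna().any():
        missing = m.gene_lengths.index[m.gene_lengths.isna()][0]
        raise ValueError(f"missing length for gene {missing!r}")
    if (m.gene_lengths <= 0).any():
        bad = m.gene_lengths.index[m.gene_lengths <= 0][0]
        raise ValueError(f"non-positive length for gene {bad!r}")
    totals = m.counts.sum(axis=0)
    if (totals == 0).any():
        bad = totals.index[totals == 0][0]
        raise ValueError(f"sample {bad!r} has zero total count")
    vals = (
        m.counts.to_numpy(dtype=float)
        * 1e9
        / np.outer(m.gene_lengths.to_numpy(dtype=float), totals.to_numpy(dtype=float))
    )
    return pd.DataFrame(vals, index=m.counts.index, columns=m.counts.columns)


def log_fpkm(m: CountMatrix) -> pd.DataFrame:
    """log2(FPKM + 1): the default expression scale for clustering/correlation."""
    return np.log2(fpkm(m) + 1.0)


def summarize(m: CountMatrix, thresholds: Sequence[float] = (30.0, 500.0)) -> ExpressionSummary:
    """Per-gene totals/means and the threshold summaries of the Results text.

    ``frac_mean_lt[t]`` is the fraction of genes with mean count < t;
    ``n_high[t]`` the number with mean > t.  Median of an even count of
    values is the mean of the two central values (numpy convention).
    """
    if m.counts.empty:
        raise ValueError("empty count matrix")
    totals = m.counts.sum(axis=1)
    means = m.counts.mean(axis=1)
    return ExpressionSummary(
        per_gene_total=totals,
        per_gene_mean=means,
        median_total=float(np.median(totals.to_numpy())),
        frac_mean_lt={float(t): float((means < t).mean()) for t in thresholds},
        n_high={float(t): int((means > t).sum()) for t in thresholds},
    )
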