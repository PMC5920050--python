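"""Negative-binomial one-vs-rest differential expression.

The model is the classic count-based RNA-seq test: per-sample size factors
by the median-of-ratios method, a per-gene NB dispersion alpha in
Var = mu + alpha * mu^2 estimated by method of moments with a fitted
1/mu trend, and a Wald test on the log2 fold change between a subgroup and
all remaining samples.  Benjamini-Hochberg controls the FDR across genes.

The statsmodels-style entry point is::

    model = NBDifferential(counts, contrast)
    res = model.fit(fdr=0.01)
    print(res.summary())
    res.signature.up, res.signature.down

The underlying steps (:func:`size_factors`, :func:`estimate_dispersion`,
:func:`nb_wald_test`, :func:`bh_adjust`, :func:`build_signatures`) are plain
functions so each stage can be exercised and validated on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression import CountMatrix

__all__ = [
    "Contrast",
    "DEResult",
    "DESignature",
    "NBDifferential",
    "NBDifferentialResults",
    "size_factors",
    "estimate_dispersion",
    "nb_wald_test",
    "bh_adjust",
    "build_signatures",
    "contrasts_from_cohort",
    "signature_union",
]

#: Pseudo-count (normalized-count units) stabilizing log fold changes.
DEFAULT_PSEUDOCOUNT = 0.5
#: Smallest subgroup analysed; smaller groups are excluded from contrasts.
DEFAULT_MIN_GROUP = 3


@dataclass(frozen=True)
class Contrast:
    """A one-vs-rest comparison: a named subgroup against all other samples.

    Samples with unknown (NA) status for the defining feature belong to
    neither side and are excluded from the test.
    """

    name: str
    positive_samples: frozenset[str]
    negative_samples: frozenset[str]

    def __post_init__(self) -> None:
        if self.positive_samples & self.negative_samples:
            raise ValueError(f"contrast {self.name!r}: sides are not disjoint")

    @property
    def used_samples(self) -> frozenset[str]:
        return self.positive_samples | self.negative_samples


@dataclass(frozen=True)
class DEResult:
    """Per-gene differential-expression statistics for one contrast."""

    gene_id: str
    base_mean: float
    log2_fold_change: float
    lfc_se: float
    wald_stat: float
    p_value: float
    q_value: float
    direction: str  # "UP", "DW" or "none"


@dataclass
class DESignature:
    """Up/down gene lists for one contrast at an FDR threshold."""

    contrast: str
    up: list[str] = field(default_factory=list)
    down: list[str] = field(default_factory=list)
    fdr_threshold: float = 0.01

    @property
    def genes(self) -> list[str]:
        return self.up + self.down

    def direction_of(self, gene_id: str) -> str:
        if gene_id in self.up:
            return "UP"
        if gene_id in self.down:
            return "DW"
        return "none"


def size_factors(m: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    For each sample s, factor[s] is the median over reference genes g (those
    with a positive count in every sample) of counts[g, s] / geomean_g(counts).
    """
    counts = m.counts.to_numpy(dtype=float)
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has positive counts in every sample; "
            "median-of-ratios needs at least one (consider a pseudo-reference)"
        )
    ref = counts[positive]
    geomean = np.exp(np.log(ref).mean(axis=1, keepdims=True))
    factors = np.median(ref / geomean, axis=0)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=m.counts.columns, name="size_factor")


def _mom_alpha(norm: np.ndarray) -> np.ndarray:
    """Method-of-moments dispersion per gene: max(0, (s^2 - mu) / mu^2)."""
    mu = norm.mean(axis=1)
    s2 = norm.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (s2 - mu) / mu**2
    alpha = np.where(mu > 0, alpha, 0.0)
    return np.maximum(alpha, 0.0)


def estimate_dispersion(
    m: CountMatrix,
    contrast: Contrast,
    factors: pd.Series | None = None,
) -> pd.Series:
    """Per-gene working NB dispersion for a contrast.

    Raw per-gene estimates pool the within-condition method-of-moments
    values (weighted by within-group degrees of freedom) so that real group
    differences do not inflate the dispersion.  A hyperbolic trend
    alpha_fit(mu) = a0 + a1/mu is least-squares fitted to the positive raw
    estimates and the working value is the conservative
    max(raw, trend(mean)).
    """
    pos = [s for s in m.sample_ids if s in contrast.positive_samples]
    neg = [s for s in m.sample_ids if s in contrast.negative_samples]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError(
            f"contrast {contrast.name!r}: need >= 2 samples per side for "
            f"dispersion estimation (got {len(pos)} vs {len(neg)})"
        )
    if factors is None:
        factors = size_factors(m)
    used = pos + neg
    norm = m.counts[used].to_numpy(dtype=float) / factors[used].to_numpy()
    n_pos, n_neg = len(pos), len(neg)
    a_pos = _mom_alpha(norm[:, :n_pos])
    a_neg = _mom_alpha(norm[:, n_pos:])
    w_pos, w_neg = n_pos - 1, n_neg - 1
    raw = (w_pos * a_pos + w_neg * a_neg) / (w_pos + w_neg)

    mu = norm.mean(axis=1)
    ok = (raw > 0) & (mu > 0)
    if ok.sum() >= 2:
        X = np.column_stack([np.ones(ok.sum()), 1.0 / mu[ok]])
        coef, *_ = np.linalg.lstsq(X, raw[ok], rcond=None)
        a0, a1 = coef
        with np.errstate(divide="ignore"):
            trend = a0 + a1 / np.where(mu > 0, mu, np.nan)
        trend = np.nan_to_num(np.maximum(trend, 0.0), nan=0.0)
    else:
        trend = np.zeros_like(raw)
    working = np.maximum(raw, trend)
    return pd.Series(working, index=m.counts.index, name="dispersion")


def nb_wald_test(
    m: CountMatrix,
    contrast: Contrast,
    factors: pd.Series | None = None,
    dispersions: pd.Series | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Wald test of subgroup vs rest on normalized counts, one row per gene.

    log2FC = log2((mean_pos + eps) / (mean_neg + eps)) with eps the
    pseudo-count.  The standard error propagates the NB variance
    mu + alpha*mu^2 of each group's mean through the log via the delta
    method, with the variance evaluated at the pseudo-count-offset mean
    (q + eps) — a group observed at zero still carries sampling variance,
    which keeps the p-value tail honest for scarce genes.  The Wald
    statistic is LFC / SE with a two-sided normal p-value.  Genes with zero
    counts in every used sample get p = 1 and LFC = 0.
    """
    pos = [s for s in m.sample_ids if s in contrast.positive_samples]
    neg = [s for s in m.sample_ids if s in contrast.negative_samples]
    if not pos or not neg:
        raise ValueError(f"contrast {contrast.name!r}: a side is empty")
    if factors is None:
        factors = size_factors(m)
    if dispersions is None:
        dispersions = estimate_dispersion(m, contrast, factors)
    alpha = dispersions.to_numpy()

    f_pos = factors[pos].to_numpy()
    f_neg = factors[neg].to_numpy()
    norm_pos = m.counts[pos].to_numpy(dtype=float) / f_pos
    norm_neg = m.counts[neg].to_numpy(dtype=float) / f_neg
    mean_pos = norm_pos.mean(axis=1)
    mean_neg = norm_neg.mean(axis=1)
    n_pos, n_neg = len(pos), len(neg)

    base_mean = np.concatenate([norm_pos, norm_neg], axis=1).mean(axis=1)
    eps = pseudocount
    lfc = np.log2((mean_pos + eps) / (mean_neg + eps))

    # Var(K/f) for K ~ NB(mean f*q, alpha): q/f + alpha*q^2, evaluated at
    # q + eps; averaged over the group's samples and divided by n for the
    # variance of the mean.
    def var_of_mean(q: np.ndarray, f: np.ndarray) -> np.ndarray:
        qe = q[:, None] + eps
        per_sample = qe / f[None, :] + alpha[:, None] * qe**2
        return per_sample.sum(axis=1) / len(f) ** 2

    v_pos = var_of_mean(mean_pos, f_pos)
    v_neg = var_of_mean(mean_neg, f_neg)
    ln2sq = np.log(2.0) ** 2
    var_lfc = v_pos / ((mean_pos + eps) ** 2 * ln2sq) + v_neg / (
        (mean_neg + eps) ** 2 * ln2sq
    )
    se = np.sqrt(var_lfc)

    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(se > 0, lfc / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(stat))

    allzero = (mean_pos == 0) & (mean_neg == 0)
    lfc = np.where(allzero, 0.0, lfc)
    stat = np.where(allzero, 0.0, stat)
    p = np.where(allzero | (se == 0), 1.0, p)

    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2_fold_change": lfc,
            "lfc_se": se,
            "wald_stat": stat,
            "p_value": p,
        },
        index=m.counts.index,
    )


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved.

    q_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        bad = p[(p < 0) | (p > 1) | np.isnan(p)][0]
        raise ValueError(f"p-value outside [0, 1]: {bad}")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _with_directions(table: pd.DataFrame, fdr: float) -> pd.DataFrame:
    table = table.copy()
    table["q_value"] = bh_adjust(table["p_value"].to_numpy())
    sig = table["q_value"] < fdr
    table["direction"] = np.where(
        sig & (table["log2_fold_change"] > 0),
        "UP",
        np.where(sig & (table["log2_fold_change"] < 0), "DW", "none"),
    )
    return table


def build_signatures(
    results: Mapping[str, pd.DataFrame], fdr: float = 0.01
) -> list[DESignature]:
    """Turn per-contrast Wald tables into up/down signatures at an FDR cut.

    Each value of *results* is a table as returned by :func:`nb_wald_test`
    (q-values are computed here if absent).
    """
    signatures: list[DESignature] = []
    for name, table in results.items():
        if table.empty:
            signatures.append(DESignature(contrast=name, fdr_threshold=fdr))
            continue
        if "direction" not in table.columns or "q_value" not in table.columns:
            table = _with_directions(table, fdr)
        up = list(table.index[table["direction"] == "UP"])
        down = list(table.index[table["direction"] == "DW"])
        signatures.append(
            DESignature(contrast=name, up=up, down=down, fdr_threshold=fdr)
        )
    return signatures


def signature_union(signatures: Iterable[DESignature]) -> list[str]:
    """Unique genes appearing in any signature, first-seen order."""
    seen: dict[str, None] = {}
    for sig in signatures:
        for g in sig.genes:
            seen.setdefault(g)
    return list(seen)


def contrasts_from_cohort(
    cohort: pd.DataFrame,
    features: Sequence[str] | None = None,
    min_group: int = DEFAULT_MIN_GROUP,
    mapk_genes: Sequence[str] = ("NRAS", "KRAS", "BRAF"),
) -> list[Contrast]:
    """Build one-vs-rest contrasts from a per-sample molecular table.

    *cohort* is samples x features with values "positive"/"negative"/"NA".
    A pooled "MAPK" contrast (positive if any of *mapk_genes* is positive,
    NA if all are NA) is appended when all its member columns are present.
    Features whose positive group is smaller than *min_group* are skipped.
    """
    if features is None:
        features = [c for c in cohort.columns if c not in mapk_genes]
    out: list[Contrast] = []

    def make(name: str, status: pd.Series) -> None:
        pos = frozenset(status.index[status == "positive"])
        neg = frozenset(status.index[status == "negative"])
        if len(pos) < min_group:
            return
        out.append(Contrast(name, pos, neg))

    for feat in features:
        make(feat, cohort[feat])
    if all(g in cohort.columns for g in mapk_genes):
        sub = cohort[list(mapk_genes)]
        any_pos = (sub == "positive").any(axis=1)
        all_na = (sub == "NA").all(axis=1)
        status = pd.Series(
            np.where(any_pos, "positive", np.where(all_na, "NA", "negative")),
            index=cohort.index,
        )
        make("MAPK", status)
    return out


class NBDifferential:
    """Negative-binomial one-vs-rest differential-expression model.

    Parameters
    ----------
    counts : CountMatrix
        Fragment counts, typically restricted to the lncRNA genes.
    contrast : Contrast
        The subgroup-vs-rest comparison to fit.
    pseudocount : float
        Normalized-count offset used in the log2 fold change.
    min_group : int
        Minimum size of the positive group; smaller groups are refused.
    """

    def __init__(
        self,
        counts: CountMatrix,
        contrast: Contrast,
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
        min_group: int = DEFAULT_MIN_GROUP,
    ) -> None:
        n_pos = len(contrast.positive_samples & set(counts.sample_ids))
        if n_pos < min_group:
            raise ValueError(
                f"contrast {contrast.name!r}: positive group has {n_pos} "
                f"samples, below the minimum of {min_group}"
            )
        self.counts = counts
        self.contrast = contrast
        self.pseudocount = pseudocount

    def fit(self, fdr: float = 0.01) -> "NBDifferentialResults":
        factors = size_factors(self.counts)
        dispersions = estimate_dispersion(self.counts, self.contrast, factors)
        table = nb_wald_test(
            self.counts, self.contrast, factors, dispersions, self.pseudocount
        )
        table = _with_directions(table, fdr)
        return NBDifferentialResults(self, table, factors, dispersions, fdr)


class NBDifferentialResults:
    """Fitted results: per-gene statistics, FDR calls and the signature."""

    def __init__(
        self,
        model: NBDifferential,
        table: pd.DataFrame,
        factors: pd.Series,
        dispersions: pd.Series,
        fdr: float,
    ) -> None:
        self.model = model
        self.table = table
        self.size_factors = factors
        self.dispersions = dispersions
        self.fdr = fdr

    @property
    def signature(self) -> DESignature:
        return build_signatures({self.model.contrast.name: self.table}, self.fdr)[0]

    @property
    def results(self) -> list[DEResult]:
        return [
            DEResult(
                gene_id=str(g),
                base_mean=float(r.base_mean),
                log2_fold_change=float(r.log2_fold_change),
                lfc_se=float(r.lfc_se),
                wald_stat=float(r.wald_stat),
                p_value=float(r.p_value),
                q_value=float(r.q_value),
                direction=str(r.direction),
            )
            for g, r in self.table.iterrows()
        ]

    def summary(self, top: int = 10) -> str:
        c = self.model.contrast
        sig = self.signature
        lines = [
            "NB one-vs-rest differential expression",
            "=" * 54,
            f"Contrast:        {c.name} "
            f"({len(c.positive_samples)} vs {len(c.negative_samples)} samples)",
            f"Genes tested:    {len(self.table)}",
            f"FDR threshold:   {self.fdr:g}",
            f"Significant:     {len(sig.up)} up, {len(sig.down)} down",
            "",
            f"Top {top} genes by Wald statistic magnitude:",
        ]
        ordered = self.table.reindex(
            self.table["wald_stat"].abs().sort_values(ascending=False).index
        ).head(top)
        lines.append(
            f"{'gene':<20}{'baseMean':>10}{'log2FC':>9}{'stat':>8}"
            f"{'pvalue':>10}{'padj':>10}  dir"
        )
        for g, r in ordered.iterrows():
            lines.append(
                f"{str(g):<20}{r.base_mean:>10.2f}{r.log2_fold_change:>9.2f}"
                f"{r.wald_stat:>8.2f}{r.p_value:>10.2e}{r.q_value:>10.2e}  "
                f"{r.direction}"
            )
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        out = self.table.rename(
            columns={
                "base_mean": "baseMean",
                "log2_fold_change": "log2FC",
                "wald_stat": "stat",
                "p_value": "pvalue",
                "q_value": "padj",
            }
        )
        out.to_csv(path, sep="\t", index_label="gene_id")
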