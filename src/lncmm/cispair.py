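"""Cis-proximity co-expression discovery: anchor-gene / lncRNA pairs.

The procedure mirrors the study's candidate-selection logic: every lncRNA
whose span lies within a genomic window (default 4 Mb, edge to edge) of an
anchor gene on the same chromosome is a candidate pair; each pair's
expression profiles are Pearson-correlated across samples, pairs passing
|r| > 0.4 and p < 0.01 are kept, and the surviving lncRNAs are annotated
with the differential-expression signatures they belong to.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .annotation import AnchorGeneList, GeneRecord
from .diffexp import DESignature

__all__ = [
    "CisPair",
    "neighbors_within",
    "correlate_pairs",
    "filter_pairs",
    "intersect_de",
    "pairs_to_frame",
    "write_pairs",
    "load_reference_pairs",
]

DEFAULT_WINDOW = 4_000_000
DEFAULT_R_MIN = 0.4
DEFAULT_P_MAX = 0.01


@dataclass(frozen=True)
class CisPair:
    """One anchor-gene / lncRNA candidate pair."""

    gene_id: str
    gene_symbol: str
    lnc_id: str
    lnc_symbol: str
    chrom: str
    distance: int  # edge-to-edge bp gap; 0 when the spans overlap
    r: float = np.nan
    p_value: float = np.nan
    de_contrast: str = "none"
    de_direction: str = "none"


def gene_gap(a: GeneRecord, b: GeneRecord) -> int:
    """Edge-to-edge gap between two gene spans; 0 if they overlap."""
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def neighbors_within(
    anchors: AnchorGeneList | Sequence[GeneRecord],
    lncs: Sequence[GeneRecord],
    window: int = DEFAULT_WINDOW,
) -> list[CisPair]:
    """All (anchor, lncRNA) pairs on the same chromosome within *window* bp.

    The gap is measured edge to edge between the gene spans (0 when they
    overlap); strand is ignored.  An interval index over the window-expanded
    lncRNA spans makes the scan near-linear.
    """
    if window <= 0:
        raise ValueError(f"window must be positive, got {window}")
    anchor_recs = (
        [anchors.resolved[s] for s in anchors.symbols if s in anchors.resolved]
        if isinstance(anchors, AnchorGeneList)
        else list(anchors)
    )
    trees: dict[str, IntervalTree] = {}
    for l in lncs:
        trees.setdefault(l.chrom_key, IntervalTree()).addi(
            l.start - window, l.end + window + 1, l
        )
    pairs: list[CisPair] = []
    for g in anchor_recs:
        tree = trees.get(g.chrom_key)
        if tree is None:
            continue
        hits = sorted(
            (h.data for h in tree.overlap(g.start, g.end + 1)),
            key=lambda l: (l.start, l.gene_id),
        )
        for l in hits:
            if l.gene_id == g.gene_id:
                continue
            gap = gene_gap(g, l)
            if gap <= window:
                pairs.append(
                    CisPair(
                        gene_id=g.gene_id,
                        gene_symbol=g.symbol,
                        lnc_id=l.gene_id,
                        lnc_symbol=l.symbol,
                        chrom=g.chrom,
                        distance=gap,
                    )
                )
    return pairs


def correlate_pairs(pairs: Iterable[CisPair], expr: pd.DataFrame) -> list[CisPair]:
    """Pearson r and two-sided p over samples for each candidate pair.

    *expr* is genes x samples on the scale correlations should be computed
    on (log2(FPKM+1) by default elsewhere).  p comes from the exact t
    transform t = r*sqrt(n-2)/sqrt(1-r^2) with n-2 df; |r| = 1 gives p = 0.
    Pairs with a member absent from *expr* or with zero variance are dropped
    with a warning.
    """
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples to correlate")
    out: list[CisPair] = []
    for pair in pairs:
        if pair.gene_id not in expr.index or pair.lnc_id not in expr.index:
            warnings.warn(
                f"pair {pair.gene_symbol}/{pair.lnc_symbol}: member missing "
                "from expression table; dropped"
            )
            continue
        x = expr.loc[pair.gene_id].to_numpy(dtype=float)
        y = expr.loc[pair.lnc_id].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            warnings.warn(
                f"pair {pair.gene_symbol}/{pair.lnc_symbol}: zero-variance "
                "member; dropped"
            )
            continue
        r, p = stats.pearsonr(x, y)
        if abs(r) >= 1.0 - 1e-15:
            p = 0.0
        out.append(replace(pair, r=float(r), p_value=float(p)))
    return out


def filter_pairs(
    pairs: Iterable[CisPair],
    r_min: float = DEFAULT_R_MIN,
    p_max: float = DEFAULT_P_MAX,
) -> list[CisPair]:
    """Keep pairs with |r| strictly above *r_min* and p strictly below *p_max*,
    ordered by (gene symbol, lncRNA symbol)."""
    kept = [
        p for p in pairs if np.isfinite(p.r) and abs(p.r) > r_min and p.p_value < p_max
    ]
    return sorted(kept, key=lambda p: (p.gene_symbol, p.lnc_symbol))


def intersect_de(
    pairs: Iterable[CisPair],
    signatures: Sequence[DESignature],
    keep_unannotated: bool = True,
) -> list[CisPair]:
    """Annotate each pair with the signature membership of its lncRNA.

    If the lncRNA is up or down in several contrasts, annotations are joined
    with ';' in signature order.  Pairs whose lncRNA is in no signature are
    kept with annotation "none" unless *keep_unannotated* is False.
    """
    out: list[CisPair] = []
    for pair in pairs:
        contrasts: list[str] = []
        directions: list[str] = []
        for sig in signatures:
            d = sig.direction_of(pair.lnc_id)
            if d != "none":
                contrasts.append(sig.contrast)
                directions.append(d)
        if contrasts:
            out.append(
                replace(
                    pair,
                    de_contrast=";".join(contrasts),
                    de_direction=";".join(directions),
                )
            )
        elif keep_unannotated:
            out.append(replace(pair, de_contrast="none", de_direction="none"))
    return out


_COLUMNS = [
    "gene_symbol", "gene_id", "chrom", "lnc_symbol", "lnc_id",
    "distance", "r", "p_value", "de_direction", "de_contrast",
]


def pairs_to_frame(pairs: Iterable[CisPair]) -> pd.DataFrame:
    rows = [
        {
            "gene_symbol": p.gene_symbol,
            "gene_id": p.gene_id,
            "chrom": p.chrom,
            "lnc_symbol": p.lnc_symbol,
            "lnc_id": p.lnc_id,
            "distance": p.distance,
            "r": p.r,
            "p_value": p.p_value,
            "de_direction": p.de_direction,
            "de_contrast": p.de_contrast,
        }
        for p in pairs
    ]
    return pd.DataFrame(rows, columns=_COLUMNS)


def write_pairs(pairs: Iterable[CisPair], path: str | Path) -> None:
    pairs_to_frame(pairs).to_csv(path, sep="\t", index=False)


def load_reference_pairs(path: str | Path | None = None) -> pd.DataFrame:
    """Load the packaged transcription of the published cis-pair table
    (43 anchor-gene/lncRNA rows with R, p and DE annotation).

    One row prints p as 0.00 in the source; it is stored as 0.0 and flagged
    in the ``note`` column as "<0.005 after rounding".
    """
    if path is None:
        ref = resources.files("lncmm").joinpath("data/reference_cispairs.tsv")
        with resources.as_file(ref) as fp:
            return pd.read_csv(fp, sep="\t")
    return pd.read_csv(path, sep="\t")
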